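"""The all-or-none statistic: distribution of the strong-affinity fraction.

Many germinal centers following the same development curve, each starting
at a random time, are equivalent to one center observed at random moments.
The fraction F of strong-affinity cells then spends most time near 0 or
near its terminal plateau — centers look either unmutated or matured.
"""

import math

import gcmature as g

params = g.ModelParams(
    p_mutated_daughter=0.5, b=0.7, N0=3000, X_star_offset_in=-0.59 * math.log(0.5)
)
traj = g.run(params, g.default_spectrum(), "recovery_unbounded")
dist = g.p_of_f(traj, n_bins=20)

print(f"terminal strong fraction F = {traj.strong_fraction[-1]:.2f}")
print("\nP(F) by decile of F:")
for d, mass in enumerate(dist.decile_masses()):
    bar = "#" * int(round(mass * 100))
    print(f"  {d/10:.1f}-{(d+1)/10:.1f}  {mass:5.3f}  {bar}")
# Mass piles up in the lowest and highest visited deciles — the
# all-or-none pattern: intermediate mixtures are short-lived.
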