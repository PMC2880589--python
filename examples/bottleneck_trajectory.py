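"""A single germinal-center run: bottleneck, recovery, affinity gain.

Starting one kcal/mol weaker than the neutral binding level, the
population shrinks while mutations explore stronger binders, bottoms out
at the bottleneck, then regrows carried by the beneficial-mutant wave.
"""

import numpy as np

import gcmature as g

params = g.ModelParams(p_mutated_daughter=0.5, b=0.7, N0=1e5, X_star_offset_in=1.0)
traj = g.run(params, g.default_spectrum(), "recovery_unbounded")

print("t (d)      N_tot    A/A0      F")
for t in range(0, int(traj.t_end) + 1, 2):
    i = np.argmin(np.abs(traj.times - t))
    print(
        f"{traj.times[i]:5.1f} {traj.n_tot[i]:10.0f} {traj.a_over_a0[i]:8.2f} "
        f"{traj.strong_fraction[i]:6.3f}"
    )
print(f"\nstatus: {traj.status} at t = {traj.t_end:.1f} d")
print(f"bottleneck: {traj.bottleneck_depth:.0f} cells at t = {traj.bottleneck_time:.1f} d")
print(f"total-affinity improvement A(t_end)/A(0) = {g.improvement(traj):.0f}-fold")
# N_tot dips ~three orders of magnitude before the strong-affinity wave
# (F -> 1) drives recovery; the improvement is the sum of Ka over all
# cells relative to its initial value.
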