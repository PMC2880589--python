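"""Optimal mutation load and germline binding for affinity improvement.

Sweeps the fraction of mutated daughter cells and the germline binding
ratio for the pooled-spleen (fast-migration) and isolated-GC limits, and
reports each optimum and the migration enhancement factor.
"""

from gcmature import default_spectrum
from gcmature.sweep import find_optimum, migration_comparison

spec = default_spectrum()
out = migration_comparison(spec, b=0.7)

p = out["pooled"]
i = out["isolated"]
print("pooled spleen (N0 = 1e5, 14-day window):")
print(
    f"  optimum {p['improvement']:.0f}-fold at {100*p['p']:.0f}% mutated daughters, "
    f"Ka_in/Ka* = {p['ka_in_ratio']:.2f}, finished in {p['t_end_days']:.1f} d"
)
print("isolated GC (N0 = 3000, recovery termination):")
print(
    f"  optimum {i['improvement']:.0f}-fold at {100*i['p']:.0f}% mutated daughters, "
    f"Ka_in/Ka* = {i['ka_in_ratio']:.2f}, finished in {i['t_end_days']:.1f} d"
)
print(f"migration enhancement factor: {out['ratio']:.1f}x")
# The pooled limit tolerates a weaker germline binding (deeper bottleneck,
# larger gain); the optimal mutation load sits near the observed ~50-60%
# of daughters mutated in both limits.
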