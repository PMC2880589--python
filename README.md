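# gcmature

A coarse-grained simulator of B-cell affinity maturation in germinal
centers (GCs), for computational immunologists and population-dynamics
modelers who want a minimal, fully explorable model of mutation–selection
dynamics during an antibody response.

## The model

B cells are tracked by the binding free energy `X` (kcal/mol) of their
antibody to the antigen, measured relative to the *neutral* level `X*`
at which birth exactly balances death. Lower `X` means stronger binding
(`Ka/Ka* = exp(-(X - X*)/kT)`, with `kT = 0.59 kcal/mol`). Cells divide
four times a day (`r = 4 ln 2 = 2.8/day`); of all mutations, ~50% are
silent, 30% lethal, and 20% affinity-affecting, so the fraction `p` of
mutated daughter cells fixes the per-day rates via a Poisson load
(`p = 0.5` gives the observed 0.55 affinity-affecting mutations per gene
per day). Selection enters as an apoptosis rate linear in `X`, giving the
net growth law

```
B(X) = min( -b (X - X*),  r - m_lethal )
```

with selection strength `b` (1/day per kcal/mol). Affinity-affecting
mutations shift `X` by a draw from an empirical mutation-effect spectrum
`W(δ)` in which only 4.9% of mutations improve binding (1.4% by ≥5-fold).
The package provides:

- an exact closed-form solution for the population in the linear regime
  (a product of Poisson mutation factors per spectrum class),
- the finite-population grid integrator with the "<1 expected cell"
  cutoff, which captures why small GCs go extinct at the population
  bottleneck,
- branching-process realizations for bottleneck-survival probabilities,
- parameter sweeps over mutation load × germline binding level
  (improvement landscapes, optimum finding, migration comparison),
- the "all-or-none" statistic: the time-weighted distribution `P(F)` of
  the strong-affinity fraction across an ensemble of GCs.

## Worked example

```python
import gcmature as g

params = g.ModelParams(p_mutated_daughter=0.5, b=0.7, N0=1e5,
                       X_star_offset_in=1.0)     # Ka_in/Ka* = 0.18
traj = g.run(params, g.default_spectrum(), "recovery_unbounded")
print(traj.status, round(traj.t_end, 1), round(g.improvement(traj)))
```

prints `recovered 17.9 294`: starting one kcal/mol weaker than neutral,
the population falls from 100 000 to a bottleneck of ~165 cells at day
8.3 while mutations explore stronger binders, then the beneficial-mutant
wave drives recovery by day 17.9 with a 294-fold gain in total affinity
`A = Σ Ka` relative to `A(0)`. The `examples/` directory has one short
script per capability (rates, spectrum, analytic-vs-numeric oracle,
bottleneck trajectory, optimization sweep, survival probability,
all-or-none distribution); each prints its numbers with a note on what
they mean. A thin CLI mirrors the library
(`gcmature simulate|sweep|survival|allornone|spectrum|analytic|fixtures`).

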