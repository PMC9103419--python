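# opa-mcdm

Group multiple-attribute decision making with the **Ordinal Priority
Approach (OPA)**: purely ordinal judgements — a prioritised panel of experts,
each expert's ranking of the decision attributes, and each expert's
per-attribute ranking of the alternatives — are turned into cardinal weights
by a max–min linear program, then aggregated into expert, attribute and
alternative significance scores.

The package is built around a health-technology appraisal: nine experts
(end-users/caregivers, therapists/physiotherapists, developers) selecting
among four at-home rehabilitation platform variants on six attributes
(usefulness, system cost, ease of use, ease of technical development, ease of
maintenance, privacy). That panel and attribute catalogue ship as a built-in
fixture; a synthetic-data module generates instances with controlled rank
noise, ties and missing rankings so every stage is testable at desk scale.

## The model

With experts at priority ranks `i = 1..p`, attribute ranks `j` (per expert)
and alternative ranks `r = 1..m` (per expert and attribute), the weights
`W_ijk` solve

```
max Z
s.t.  Z ≤ i·j·r·(W_ij(r) − W_ij(r+1))     for r < m
      Z ≤ i·j·m·W_ij(m)
      Σ W_ijk = 1,   W_ijk ≥ 0
```

Z is the minimum scaled adjacent-rank weight gap; marginal sums of the
solved tensor give the significance of each expert (`W_i = Σ_jk W_ijk`),
attribute (`W_j = Σ_ik`), and alternative (`W_k = Σ_ij`). For complete
strict rankings every inequality is tight at the optimum and the solution
has a closed form, `W_ij(r) = Z/(i·j) · Σ_{s=r..m} 1/s` with
`Z = 1/(m·Σ_ij 1/(i·j))`; in particular the rank-`i` expert always carries
marginal weight `(1/i)/H_p` (`H_p` the p-th harmonic number), independent of
which rankings the experts gave. Expert priority itself is derived
lexicographically from the panel profiles: role, then professional position,
years of experience and education, each on an ordinal scale.

## Worked example

```python
from opa_mcdm import aggregate, case_study_instance, solve
from opa_mcdm.io import round_half_up

instance = case_study_instance(seed=0)   # nine-expert panel, 6 attributes, 4 alternatives
agg = aggregate(solve(instance), instance)
for eid, rank in sorted(instance.expert_rank.items(), key=lambda kv: kv[1]):
    print(eid, round_half_up(agg.expert_weights[eid], 4), rank)
```

prints

```
E9 0.3535 1
E8 0.1767 2
E7 0.1178 3
E4 0.0884 4
E5 0.0707 5
E6 0.0589 6
E1 0.0505 7
E2 0.0442 8
E3 0.0393 9
```

— the significance of each panellist. The three end-users/caregivers (E7–E9)
outweigh the therapists (E4–E6), who outweigh the developers (E1–E3), and
weights decay as `1/rank` within the `(1/i)/H_9` law. Because the raw
attribute and alternative rankings of the original panel were never
published, `case_study_instance` fills them with seeded synthetic complete
strict rankings; the expert weights above are invariant to that choice.

The `examples/` directory holds one short script per capability: panel
ranking with decision traces, building and solving a tiny instance by hand
(with the LP text dump), noisy-panel recovery curves, and leave-one-expert-out
sensitivity analysis.

## Command line

```sh
opa simulate -p 9 -n 6 -m 4 --theta 2 --seed 7 --out panel.json
opa validate --instance panel.json
opa solve --instance panel.json --solver auto --out results/
opa rank-experts --instance panel.json --explain
```

`solve` writes the three significance tables as CSV, the expert-by-attribute
significance matrix, and a full-precision JSON report.

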