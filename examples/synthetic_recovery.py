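"""How reliably does the method recover a known alternative order from
noisy expert panels?

Panels of nine experts rank four alternatives with Mallows noise around a
reference order (theta controls concentration; 0 = uniform noise).  For each
theta we solve 50 simulated panels and count how often the aggregated
ranking equals the reference.
"""

from collections import Counter

from opa_mcdm import SyntheticSpec, aggregate, gen_instance, solve

REFERENCE = ("A1", "A2", "A3", "A4")

for theta in (0.0, 0.5, 1.0, 2.0):
    outcomes = Counter()
    for rep in range(50):
        inst = gen_instance(SyntheticSpec(p=9, n=6, m=4, noise_theta=theta,
                                          alt_reference=REFERENCE, seed=1000 * rep + 7))
        agg = aggregate(solve(inst), inst)
        ranking = tuple(sorted(agg.alternative_ranks, key=agg.alternative_ranks.__getitem__))
        outcomes[ranking] += 1
    frac = outcomes[REFERENCE] / 50
    print(f"theta = {theta:>4}: recovered reference in {frac:.0%} of 50 panels "
          f"(chance level is 1/24 = 4.2%)")
# With theta = 0 the rankings carry no signal and recovery sits near chance;
# already at theta = 2 the aggregation recovers the reference essentially always.
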