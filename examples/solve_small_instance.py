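"""Build a tiny instance by hand and solve it both ways.

One expert ranks one attribute and two alternatives: the max-min program
has rows Z <= W1 - W2 and Z <= 2*W2 under W1 + W2 = 1, both tight at the
optimum, giving W = (0.75, 0.25) and Z = 0.5.
"""

from opa_mcdm import (
    Alternative, Attribute, ExpertProfile, OPAInstance, RankVector,
    build_lp, solve_closed_form, solve_lp,
)

instance = OPAInstance(
    experts=(ExpertProfile(expert_id="E1", role="Developer",
                           position="Elementary occupations",
                           experience="1-5", education="Primary"),),
    attributes=(Attribute(attribute_id="c1", name="usability"),),
    alternatives=(Alternative(alternative_id="a1"), Alternative(alternative_id="a2")),
    expert_rank={"E1": 1},
    attr_ranking={"E1": RankVector(item_ids=("c1",), rank_of={"c1": 1})},
    alt_ranking={"E1": {"c1": RankVector(item_ids=("a1", "a2"),
                                         rank_of={"a1": 1, "a2": 2})}},
)

spec = build_lp(instance)
print(spec.to_lp_text())

lp = solve_lp(spec)
cf = solve_closed_form(instance)
print(f"\nLP:          W = {lp.w}, Z = {lp.z}")
print(f"closed form: W = {cf.w}, Z = {cf.z}")
# Both routes give (0.75, 0.25): the preferred alternative gets three times
# the weight of the other, and Z = 0.5 is the minimum scaled rank gap.
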