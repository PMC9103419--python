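from __future__ import annotations

import pytest

from opa_mcdm.schema import (
    Alternative,
    Attribute,
    ExpertProfile,
    OPAInstance,
    RankVector,
)


def make_instance(
    p: int,
    n: int,
    m: int,
    expert_ranks: dict[str, int] | None = None,
    attr_orders: dict[str, list[list[str]]] | None = None,
    alt_orders: dict[str, dict[str, list[list[str]]]] | None = None,
) -> OPAInstance:
    """Hand-built instance with identity (catalogue-order) rankings by default.

    Experts are E1..Ep (E1 at rank 1 unless overridden), attributes c1..cn,
    alternatives a1..am; orderings are tie-group lists, best first.
    """
    eids = [f"E{i}" for i in range(1, p + 1)]
    aids = [f"c{j}" for j in range(1, n + 1)]
    kids = [f"a{k}" for k in range(1, m + 1)]
    if expert_ranks is None:
        expert_ranks = {e: i for i, e in enumerate(eids, start=1)}

    def vector(universe, ordering):
        rank_of = {}
        for g, group in enumerate(ordering, start=1):
            for item in group:
                rank_of[item] = g
        return RankVector(item_ids=tuple(universe), rank_of=rank_of)

    attr_ranking = {}
    alt_ranking = {}
    for eid in eids:
        a_ord = (attr_orders or {}).get(eid, [[a] for a in aids])
        attr_ranking[eid] = vector(aids, a_ord)
        per = {}
        ranked_attrs = [x for group in a_ord for x in group]
        for aid in ranked_attrs:
            k_ord = ((alt_orders or {}).get(eid, {})).get(aid, [[k] for k in kids])
            per[aid] = vector(kids, k_ord)
        alt_ranking[eid] = per

    return OPAInstance(
        experts=tuple(
            ExpertProfile(
                expert_id=e,
                role="Developer",
                position="Elementary occupations",
                experience="1-5",
                education="Primary",
            )
            for e in eids
        ),
        attributes=tuple(Attribute(attribute_id=a, name=a) for a in aids),
        alternatives=tuple(Alternative(alternative_id=k, name=k) for k in kids),
        expert_rank=expert_ranks,
        attr_ranking=attr_ranking,
        alt_ranking=alt_ranking,
    )


@pytest.fixture
def micro_112() -> OPAInstance:
    """One expert, one attribute, two alternatives."""
    return make_instance(1, 1, 2)


@pytest.fixture
def micro_113() -> OPAInstance:
    return make_instance(1, 1, 3)


@pytest.fixture
def micro_211() -> OPAInstance:
    """Two ranked experts, one attribute, one alternative."""
    return make_instance(2, 1, 1)
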