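"""Marginal weights, significance matrix and sensitivity analysis."""

from __future__ import annotations

import numpy as np
import pytest

from opa_mcdm.aggregate import (
    aggregate,
    build_report,
    leave_one_expert_out,
    significance_matrix,
)
from opa_mcdm.core import solve, solve_lp, build_lp
from opa_mcdm.synth import SyntheticSpec, gen_consensus_instance, gen_instance
from conftest import make_instance


def test_micro_alternative_weights(micro_112):
    agg = aggregate(solve(micro_112), micro_112)
    assert agg.alternative_weights["a1"] == pytest.approx(0.75, abs=1e-9)
    assert agg.alternative_weights["a2"] == pytest.approx(0.25, abs=1e-9)
    assert agg.alternative_ranks == {"a1": 1, "a2": 2}


@pytest.mark.parametrize("seed", range(6))
def test_marginal_consistency(seed):
    """Each of the three marginal weight maps sums to one, also under ties
    and missing rankings."""
    inst = gen_instance(
        SyntheticSpec(p=4, n=3, m=4, tie_prob=0.25, missing_prob=0.25, seed=seed)
    )
    agg = aggregate(solve_lp(build_lp(inst)), inst)
    for weights in (agg.expert_weights, agg.attribute_weights, agg.alternative_weights):
        assert sum(weights.values()) == pytest.approx(1.0, abs=1e-9)


def test_significance_matrix_rows_and_columns():
    inst = make_instance(1, 2, 2)
    tensor = solve(inst)
    sig = significance_matrix(tensor, inst)
    assert sig.loc["E1", "c1"] == pytest.approx(2 / 3, abs=1e-9)
    assert sig.loc["E1", "c2"] == pytest.approx(1 / 3, abs=1e-9)
    agg = aggregate(tensor, inst)
    assert sig.sum(axis=1).to_dict() == pytest.approx(agg.expert_weights, abs=1e-9)
    assert sig.sum(axis=0).to_dict() == pytest.approx(agg.attribute_weights, abs=1e-9)


def test_significance_rows_proportional_to_inverse_attribute_rank():
    """Complete strict: each expert's row decays as 1/j over their own
    attribute ranking."""
    inst = gen_instance(SyntheticSpec(p=3, n=4, m=3, seed=11))
    sig = significance_matrix(solve(inst), inst)
    for eid in inst.expert_ids:
        rv = inst.attr_ranking[eid]
        row = sig.loc[eid]
        base = None
        for aid in rv.ranked_items:
            j = rv.rank_of[aid]
            if base is None:
                base = row[aid] * j
            assert row[aid] * j == pytest.approx(base, abs=1e-9)


def test_single_attribute_column_equals_expert_weights():
    inst = make_instance(3, 1, 2)
    tensor = solve(inst)
    sig = significance_matrix(tensor, inst)
    agg = aggregate(tensor, inst)
    assert sig["c1"].to_dict() == pytest.approx(agg.expert_weights, abs=1e-9)


def test_alternative_relabeling_is_equivariant():
    """Swapping two alternative labels everywhere permutes W_k identically."""
    inst = gen_instance(SyntheticSpec(p=3, n=3, m=3, seed=2))
    agg = aggregate(solve(inst), inst)

    swap = {"a1": "a2", "a2": "a1", "a3": "a3"}
    relabeled = inst.model_copy(
        update={
            "alternatives": tuple(
                a.model_copy(update={"alternative_id": swap[a.alternative_id]})
                for a in inst.alternatives
            ),
            "alt_ranking": {
                e: {
                    aid: rv.model_copy(
                        update={
                            "item_ids": tuple(swap[k] for k in rv.item_ids),
                            "rank_of": {swap[k]: r for k, r in rv.rank_of.items()},
                        }
                    )
                    for aid, rv in per.items()
                }
                for e, per in inst.alt_ranking.items()
            },
        }
    )
    agg2 = aggregate(solve(relabeled), relabeled)
    for k, w in agg.alternative_weights.items():
        assert agg2.alternative_weights[swap[k]] == pytest.approx(w, abs=1e-9)


def test_consensus_order_is_recovered():
    true_order = ["a3", "a1", "a4", "a2"]
    inst = gen_consensus_instance(true_order, p=5, n=3, seed=4)
    agg = aggregate(solve(inst), inst)
    recovered = sorted(agg.alternative_ranks, key=agg.alternative_ranks.__getitem__)
    assert recovered == true_order


def test_tensor_instance_mismatch_rejected(micro_112, micro_113):
    tensor = solve(micro_113)
    with pytest.raises(ValueError, match="does not belong"):
        aggregate(tensor, micro_112)


def test_leave_one_out_requires_two_experts(micro_112):
    with pytest.raises(ValueError, match="nothing to remove"):
        leave_one_expert_out(micro_112)


def test_leave_one_out_preserves_consensus():
    inst = gen_consensus_instance(["a2", "a1", "a3"], p=3, n=2, seed=9)
    results = leave_one_expert_out(inst)
    assert len(results) == 3
    assert not any(r.ranking_changed for r in results)
    for r in results:
        assert sum(r.alternative_weights.values()) == pytest.approx(1.0, abs=1e-9)
        assert r.z > 0


def test_leave_one_out_removing_dominant_expert_flips_order():
    """Two experts with opposed alternative orders: dropping the rank-1
    expert leaves the other's order in charge."""
    inst = make_instance(
        2, 1, 2,
        alt_orders={
            "E1": {"c1": [["a1"], ["a2"]]},
            "E2": {"c1": [["a2"], ["a1"]]},
        },
    )
    results = {r.removed_expert: r for r in leave_one_expert_out(inst)}
    assert results["E1"].alternative_ranks == {"a2": 1, "a1": 2}
    assert results["E2"].alternative_ranks == {"a1": 1, "a2": 2}


def test_report_structure_and_tie_flagging():
    inst = make_instance(
        1, 1, 2, alt_orders={"E1": {"c1": [["a1", "a2"]]}}
    )
    report = build_report(inst, solve(inst, solver="lp"))
    assert report.tied_alternatives == (("a1", "a2"),)
    assert report.final_ranking == ("a1", "a2")  # catalogue order, flagged as tied
    assert report.solver_tag == "scipy-highs"
    assert len(report.instance_digest) == 16


def test_equal_weights_share_a_rank():
    inst = make_instance(
        2, 1, 2,
        alt_orders={
            "E1": {"c1": [["a1"], ["a2"]]},
            "E2": {"c1": [["a2"], ["a1"]]},
        },
    )
    # ranks 1 and 2 pull in opposite directions but unequally; just check the
    # rank map is dense and descending in weight
    agg = aggregate(solve(inst), inst)
    ordered = sorted(agg.alternative_weights, key=agg.alternative_weights.__getitem__, reverse=True)
    ranks = [agg.alternative_ranks[k] for k in ordered]
    assert ranks == sorted(ranks)
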