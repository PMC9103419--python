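"""The max-min weight model: LP construction, solution, and closed form."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest
from scipy.optimize import linprog

from opa_mcdm.core import (
    ClosedFormInapplicableError,
    build_lp,
    solve,
    solve_closed_form,
    solve_lp,
)
from opa_mcdm.synth import SyntheticSpec, gen_instance
from conftest import make_instance


def brute_force_solve(instance):
    """Independent oracle: assemble the LP directly from the model statement
    (one block of rows per expert-attribute pair), without build_lp."""
    expert_rank = instance.expert_rank
    variables = []
    for eid in instance.expert_ids:
        for aid in instance.attr_ranking[eid].ranked_items:
            for kid in instance.alt_ranking[eid][aid].ranked_items:
                variables.append((eid, aid, kid))
    idx = {v: i for i, v in enumerate(variables)}
    nv = len(variables)
    rows, rhs = [], []
    for eid in instance.expert_ids:
        i = expert_rank[eid]
        av = instance.attr_ranking[eid]
        for aid in av.ranked_items:
            j = av.rank_of[aid]
            rv = instance.alt_ranking[eid][aid]
            by_rank = {}
            for kid in rv.ranked_items:
                by_rank.setdefault(rv.rank_of[kid], []).append(kid)
            positions = sorted(by_rank)
            for r_idx in range(len(positions)):
                row = np.zeros(nv + 1)
                row[nv] = 1.0
                r = r_idx + 1
                top = by_rank[positions[r_idx]][0]
                row[idx[(eid, aid, top)]] -= i * j * r
                if r_idx + 1 < len(positions):
                    nxt = by_rank[positions[r_idx + 1]][0]
                    row[idx[(eid, aid, nxt)]] += i * j * r
                rows.append(row)
                rhs.append(0.0)
    eq_rows = [np.concatenate([np.ones(nv), [0.0]])]
    eq_rhs = [1.0]
    for eid in instance.expert_ids:
        for aid in instance.attr_ranking[eid].ranked_items:
            rv = instance.alt_ranking[eid][aid]
            groups = {}
            for kid in rv.ranked_items:
                groups.setdefault(rv.rank_of[kid], []).append(kid)
            for members in groups.values():
                for other in members[1:]:
                    row = np.zeros(nv + 1)
                    row[idx[(eid, aid, members[0])]] = 1.0
                    row[idx[(eid, aid, other)]] = -1.0
                    eq_rows.append(row)
                    eq_rhs.append(0.0)
    c = np.zeros(nv + 1)
    c[nv] = -1.0
    res = linprog(
        c, A_ub=np.array(rows), b_ub=np.array(rhs),
        A_eq=np.array(eq_rows), b_eq=np.array(eq_rhs),
        bounds=[(0, None)] * nv + [(None, None)], method="highs",
    )
    assert res.success
    return {v: res.x[idx[v]] for v in variables}, res.x[nv]


# hand-derived optima: every inequality is tight at the optimum
MICRO_CASES = [
    # (p, n, m) -> weights in rank order, Z
    ((1, 1, 2), [Fraction(3, 4), Fraction(1, 4)], Fraction(1, 2)),
    ((1, 1, 3), [Fraction(11, 18), Fraction(5, 18), Fraction(2, 18)], Fraction(1, 3)),
    ((1, 1, 1), [Fraction(1, 1)], Fraction(1, 1)),
]


@pytest.mark.parametrize("dims, expected_w, expected_z", MICRO_CASES)
def test_micro_instances_match_hand_solution(dims, expected_w, expected_z):
    inst = make_instance(*dims)
    bf_w, bf_z = brute_force_solve(inst)
    tensor = solve_lp(build_lp(inst))
    cf = solve_closed_form(inst)
    for r, w in enumerate(expected_w, start=1):
        key = ("E1", "c1", f"a{r}")
        assert bf_w[key] == pytest.approx(float(w), abs=1e-9)
        assert tensor.w[key] == pytest.approx(float(w), abs=1e-9)
        assert cf.w[key] == pytest.approx(float(w), abs=1e-12)
    for z in (bf_z, tensor.z, cf.z):
        assert z == pytest.approx(float(expected_z), abs=1e-9)


def test_two_ranked_experts_single_alternative(micro_211):
    """Z <= 1*W1 and Z <= 2*W2 tight under W1 + W2 = 1 gives (2/3, 1/3)."""
    tensor = solve_lp(build_lp(micro_211))
    assert tensor.w[("E1", "c1", "a1")] == pytest.approx(2 / 3, abs=1e-9)
    assert tensor.w[("E2", "c1", "a1")] == pytest.approx(1 / 3, abs=1e-9)
    assert tensor.z == pytest.approx(2 / 3, abs=1e-9)


def test_lp_dimensions_on_full_scale_instance():
    spec = build_lp(make_instance(9, 6, 4))
    assert spec.n_vars == 216
    assert spec.n_rows == 216  # 3 chain rows + 1 last-rank row per expert-attribute
    assert spec.tie_pairs == ()


def test_unranked_attribute_contributes_no_variables():
    inst = make_instance(1, 2, 2, attr_orders={"E1": [["c1"]]})
    spec = build_lp(inst)
    assert all(v[1] == "c1" for v in spec.variables)


def test_missing_attribute_ranks_are_compacted():
    """An expert who ranks a single attribute — whatever raw rank label it
    carries — gets multiplier j = 1 for it after dense compaction."""
    from opa_mcdm.schema import RankVector

    full = make_instance(1, 1, 2)
    skipping = make_instance(1, 2, 2, attr_orders={"E1": [["c2"]]})
    # raw rank 2 with nothing above it: compaction renumbers it to 1
    odd = skipping.model_copy(
        update={
            "attr_ranking": {
                "E1": RankVector(item_ids=("c1", "c2"), rank_of={"c2": 2})
            }
        }
    )
    t_full = solve_lp(build_lp(full))
    t_skip = solve_lp(build_lp(odd))
    assert t_skip.w[("E1", "c2", "a1")] == pytest.approx(t_full.w[("E1", "c1", "a1")], abs=1e-9)
    assert t_skip.z == pytest.approx(t_full.z, abs=1e-9)


def test_tied_alternatives_share_weight():
    inst = make_instance(1, 1, 3, alt_orders={"E1": {"c1": [["a1", "a2"], ["a3"]]}})
    spec = build_lp(inst)
    assert len(spec.tie_pairs) == 1
    tensor = solve_lp(spec)
    assert tensor.w[("E1", "c1", "a1")] == pytest.approx(tensor.w[("E1", "c1", "a2")], abs=1e-9)
    assert tensor.w[("E1", "c1", "a1")] > tensor.w[("E1", "c1", "a3")]
    assert sum(tensor.w.values()) == pytest.approx(1.0, abs=1e-9)
    bf_w, bf_z = brute_force_solve(inst)
    for k in tensor.w:
        assert tensor.w[k] == pytest.approx(bf_w[k], abs=1e-8)


def test_empty_preference_structure_rejected():
    inst = make_instance(1, 1, 1)
    empty = inst.model_copy(update={"attr_ranking": {}, "alt_ranking": {}})
    with pytest.raises(ValueError, match="empty preference structure"):
        build_lp(empty)


def test_closed_form_refuses_ties():
    tied = make_instance(1, 1, 3, alt_orders={"E1": {"c1": [["a1", "a2"], ["a3"]]}})
    with pytest.raises(ClosedFormInapplicableError, match="solve_lp"):
        solve_closed_form(tied)


def test_rank_position_identity():
    """sum_{r=1..m} sum_{s=r..m} 1/s == m — the attribute share of each
    expert-attribute block is independent of the alternative count."""
    for m in range(1, 51):
        total = sum(sum(1.0 / s for s in range(r, m + 1)) for r in range(1, m + 1))
        assert total == pytest.approx(m, rel=1e-12)


def test_expert_weight_theorem():
    """Complete strict: the rank-i expert carries (1/i)/H_p whatever the
    attribute and alternative orders are."""
    rng = np.random.default_rng(7)
    for trial in range(10):
        p, n, m = rng.integers(1, 6, 3) + 1
        inst = gen_instance(SyntheticSpec(p=int(p), n=int(n), m=int(m), seed=int(trial)))
        tensor = solve_closed_form(inst)
        h_p = sum(1.0 / i for i in range(1, int(p) + 1))
        marg = {e: 0.0 for e in inst.expert_ids}
        for (e, _a, _k), w in tensor.w.items():
            marg[e] += w
        for eid in inst.expert_ids:
            i = inst.expert_rank[eid]
            assert marg[eid] == pytest.approx((1.0 / i) / h_p, abs=1e-9)


@pytest.mark.parametrize("seed", range(25))
def test_lp_and_closed_form_agree_on_random_instances(seed):
    rng = np.random.default_rng(seed)
    p, n, m = (int(x) for x in rng.integers(1, 7, 3))
    inst = gen_instance(SyntheticSpec(p=p, n=n, m=m, seed=seed + 1000))
    lp = solve_lp(build_lp(inst))
    cf = solve_closed_form(inst)
    assert max(abs(lp.w[k] - cf.w[k]) for k in cf.w) <= 1e-8
    assert lp.z == pytest.approx(cf.z, abs=1e-8)


@pytest.mark.parametrize("seed", range(8))
def test_solution_invariants(seed):
    """Normalisation, non-negativity, chain monotonicity and Z > 0 hold on
    solved instances with ties and missing attributes."""
    inst = gen_instance(
        SyntheticSpec(p=4, n=4, m=4, tie_prob=0.3, missing_prob=0.3, seed=seed)
    )
    tensor = solve_lp(build_lp(inst))
    assert sum(tensor.w.values()) == pytest.approx(1.0, abs=1e-9)
    assert all(w >= 0 for w in tensor.w.values())
    assert tensor.z > 0
    for eid in inst.expert_ids:
        for aid in inst.attr_ranking[eid].ranked_items:
            rv = inst.alt_ranking[eid][aid]
            ordered = sorted(rv.ranked_items, key=rv.rank_of.__getitem__)
            weights = [tensor.w[(eid, aid, k)] for k in ordered]
            for hi, lo, khi, klo in zip(weights, weights[1:], ordered, ordered[1:]):
                if rv.rank_of[khi] == rv.rank_of[klo]:
                    assert hi == pytest.approx(lo, abs=1e-9)
                else:
                    assert hi >= lo - 1e-9


def test_strict_chain_strictly_decreasing(micro_113):
    tensor = solve_lp(build_lp(micro_113))
    w = [tensor.w[("E1", "c1", f"a{r}")] for r in (1, 2, 3)]
    assert w[0] > w[1] > w[2] > 0


def test_solver_is_deterministic():
    inst = gen_instance(SyntheticSpec(p=3, n=3, m=3, tie_prob=0.2, seed=5))
    a = solve_lp(build_lp(inst))
    b = solve_lp(build_lp(inst))
    assert a.w == b.w and a.z == b.z


def test_auto_solver_routes_by_instance_shape():
    strict = make_instance(2, 2, 2)
    assert solve(strict, solver="auto").solver_tag == "closed-form"
    tied = make_instance(1, 1, 3, alt_orders={"E1": {"c1": [["a1", "a2"], ["a3"]]}})
    assert solve(tied, solver="auto").solver_tag == "scipy-highs"


def test_lp_text_dump_mentions_every_variable(micro_113):
    spec = build_lp(micro_113)
    text = spec.to_lp_text()
    assert "Maximize" in text and "norm:" in text
    assert text.count("w_") >= spec.n_vars
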