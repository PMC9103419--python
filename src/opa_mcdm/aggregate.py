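"""Marginal weights, significance decompositions and the decision report.

The solved tensor W_ijk is summed over two of its three axes to give the
significance of each expert (W_i), attribute (W_j) and alternative (W_k).
Attribute weights are keyed by attribute *identity*: each expert contributes
the weight they placed on that attribute at their own rank position for it,
so the per-attribute totals are comparable across experts even though rank
positions differ.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import pandas as pd

from .core import solve
from .schema import AggregateWeights, OPAInstance, WeightTensor

RANK_TIE_TOL = 1e-9


def dense_ranks_from_weights(weights: dict[str, float], tol: float = RANK_TIE_TOL) -> dict[str, int]:
    """Dense ranks, 1 for the largest weight; weights within *tol* share a rank."""
    items = sorted(weights, key=lambda k: -weights[k])
    ranks: dict[str, int] = {}
    rank = 0
    prev = None
    for it in items:
        if prev is None or prev - weights[it] > tol:
            rank += 1
            prev = weights[it]
        ranks[it] = rank
    return ranks


def _check_match(tensor: WeightTensor, instance: OPAInstance) -> None:
    eids = set(instance.expert_ids)
    aids = set(instance.attribute_ids)
    kids = set(instance.alternative_ids)
    for e, a, k in tensor.w:
        if e not in eids or a not in aids or k not in kids:
            raise ValueError(
                f"tensor entry ({e!r}, {a!r}, {k!r}) does not belong to this instance"
            )


def aggregate(tensor: WeightTensor, instance: OPAInstance) -> AggregateWeights:
    """Marginal sums over the tensor, with dense ranks attached.

    Identities that received no weight (an attribute nobody ranked, say) get
    weight zero so every map covers the full catalogue.
    """
    _check_match(tensor, instance)
    wi = {e: 0.0 for e in instance.expert_ids}
    wj = {a: 0.0 for a in instance.attribute_ids}
    wk = {k: 0.0 for k in instance.alternative_ids}
    for (e, a, k), w in tensor.w.items():
        wi[e] += w
        wj[a] += w
        wk[k] += w
    return AggregateWeights(
        expert_weights=wi,
        attribute_weights=wj,
        alternative_weights=wk,
        expert_ranks=dense_ranks_from_weights(wi),
        attribute_ranks=dense_ranks_from_weights(wj),
        alternative_ranks=dense_ranks_from_weights(wk),
    )


def significance_matrix(tensor: WeightTensor, instance: OPAInstance) -> pd.DataFrame:
    """Expert-by-attribute weight matrix W_ij = sum_k W_ijk.

    Row sums equal the expert weights; column sums the attribute weights.
    """
    _check_match(tensor, instance)
    df = pd.DataFrame(
        0.0, index=list(instance.expert_ids), columns=list(instance.attribute_ids)
    )
    for (e, a, _k), w in tensor.w.items():
        df.loc[e, a] += w
    return df


@dataclass(frozen=True)
class LeaveOneOutResult:
    removed_expert: str
    z: float
    alternative_weights: dict[str, float]
    alternative_ranks: dict[str, int]
    ranking_changed: bool


def leave_one_expert_out(
    instance: OPAInstance, solver: str = "auto"
) -> list[LeaveOneOutResult]:
    """Sensitivity of the alternative ranking to each individual expert.

    Each expert is removed in turn, the remaining experts are re-ranked
    densely (preserving their relative order), the model is re-solved and the
    new alternative ranking is compared with the full-panel one.
    """
    if instance.p < 2:
        raise ValueError("nothing to remove: leave-one-out needs at least two experts")
    expert_rank = instance.expert_rank
    if expert_rank is None:
        raise ValueError("instance has no expert ranks; derive them first")
    base = aggregate(solve(instance, solver=solver), instance)
    out = []
    for removed in instance.expert_ids:
        kept = [e for e in instance.experts if e.expert_id != removed]
        kept_ids = [e.expert_id for e in kept]
        order = sorted(kept_ids, key=lambda e: expert_rank[e])
        new_rank: dict[str, int] = {}
        rank = 0
        prev = None
        for eid in order:
            if expert_rank[eid] != prev:
                rank += 1
                prev = expert_rank[eid]
            new_rank[eid] = rank
        sub = instance.model_copy(
            update={
                "experts": tuple(kept),
                "expert_rank": new_rank,
                "attr_ranking": {e: v for e, v in instance.attr_ranking.items() if e != removed},
                "alt_ranking": {e: v for e, v in instance.alt_ranking.items() if e != removed},
            }
        )
        tensor = solve(sub, solver=solver)
        agg = aggregate(tensor, sub)
        out.append(
            LeaveOneOutResult(
                removed_expert=removed,
                z=tensor.z,
                alternative_weights=agg.alternative_weights,
                alternative_ranks=agg.alternative_ranks,
                ranking_changed=agg.alternative_ranks != base.alternative_ranks,
            )
        )
    return out


@dataclass(frozen=True)
class DecisionReport:
    """Everything the analysis produces, with provenance.

    ``final_ranking`` lists alternative ids best first in catalogue-order
    display tie-break; genuinely tied alternatives are reported in
    ``tied_alternatives`` rather than silently separated.
    """

    aggregates: AggregateWeights
    significance: pd.DataFrame
    final_ranking: tuple[str, ...]
    tied_alternatives: tuple[tuple[str, ...], ...]
    z: float
    instance_digest: str
    solver_tag: str
    tolerance: float


def instance_digest(instance: OPAInstance) -> str:
    payload = instance.model_dump(mode="json")
    blob = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def build_report(
    instance: OPAInstance, tensor: WeightTensor, tolerance: float = 1e-9
) -> DecisionReport:
    agg = aggregate(tensor, instance)
    ranks = agg.alternative_ranks
    # catalogue order breaks display ties deterministically
    final = tuple(sorted(instance.alternative_ids, key=lambda k: (ranks[k], instance.alternative_ids.index(k))))
    by_rank: dict[int, list[str]] = {}
    for k in final:
        by_rank.setdefault(ranks[k], []).append(k)
    tied = tuple(tuple(g) for g in by_rank.values() if len(g) > 1)
    return DecisionReport(
        aggregates=agg,
        significance=significance_matrix(tensor, instance),
        final_ranking=final,
        tied_alternatives=tied,
        z=tensor.z,
        instance_digest=instance_digest(instance),
        solver_tag=tensor.solver_tag,
        tolerance=tolerance,
    )
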