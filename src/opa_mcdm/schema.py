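"""Domain types and structural validation for an OPA decision instance.

An instance couples three finite sets — experts, attributes, alternatives —
with a purely ordinal preference structure: each expert ranks the attributes,
and, within every attribute they ranked, ranks the alternatives.  All ranks
are 1-based and *dense*: tied items share a rank and the next distinct rank is
the previous rank plus one (1,1,2 — never 1,1,3).  An item an expert did not
rank is simply absent from the corresponding rank vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from pydantic import BaseModel, ConfigDict, field_validator, model_validator


class OrdinalScale(BaseModel):
    """An ordered categorical scale, best level first."""

    model_config = ConfigDict(frozen=True)

    name: str
    levels: tuple[str, ...]

    @field_validator("levels")
    @classmethod
    def _levels_nonempty_unique(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        if not v:
            raise ValueError("scale must have at least one level")
        if len(set(v)) != len(v):
            raise ValueError("scale levels must be unique")
        return v

    def index_of(self, label: str) -> int:
        """Position of *label* on the scale (0 = best).

        Matching is insensitive to case, surrounding whitespace and the
        hyphen/en-dash distinction, so values transcribed from printed tables
        resolve without manual clean-up.
        """
        key = _canon(label)
        for idx, level in enumerate(self.levels):
            if _canon(level) == key:
                return idx
        raise KeyError(f"label {label!r} is not a level of scale {self.name!r}")


def _canon(label: str) -> str:
    return label.strip().casefold().replace("–", "-").replace("—", "-")


class ExpertProfile(BaseModel):
    """The four ordinal characteristics used to prioritise an expert."""

    model_config = ConfigDict(frozen=True)

    expert_id: str
    role: str
    position: str
    experience: str
    education: str


class RankVector(BaseModel):
    """Dense 1-based ranks over a set of items; unranked items are absent.

    ``item_ids`` fixes the universe (and a stable display order); ``rank_of``
    maps a subset of it to positive integer ranks.  Density is a *structural*
    property checked by :func:`validate_instance` rather than enforced at
    construction, so malformed elicitations can be loaded and reported.
    """

    model_config = ConfigDict(frozen=True)

    item_ids: tuple[str, ...]
    rank_of: dict[str, int]

    @model_validator(mode="after")
    def _basic_shape(self) -> "RankVector":
        if len(set(self.item_ids)) != len(self.item_ids):
            raise ValueError("duplicate item ids in rank vector")
        unknown = set(self.rank_of) - set(self.item_ids)
        if unknown:
            raise ValueError(f"ranked items not in item universe: {sorted(unknown)}")
        for item, r in self.rank_of.items():
            if not isinstance(r, int) or r < 1:
                raise ValueError(f"rank of {item!r} must be a positive integer, got {r!r}")
        return self

    @property
    def ranked_items(self) -> list[str]:
        return [i for i in self.item_ids if i in self.rank_of]

    @property
    def n_positions(self) -> int:
        """Number of distinct rank positions (0 for an empty vector)."""
        return len(set(self.rank_of.values()))

    @property
    def is_dense(self) -> bool:
        ranks = set(self.rank_of.values())
        return ranks == set(range(1, len(ranks) + 1))

    @property
    def is_strict(self) -> bool:
        return len(set(self.rank_of.values())) == len(self.rank_of)

    @property
    def is_complete(self) -> bool:
        return len(self.rank_of) == len(self.item_ids)

    def tie_groups(self) -> list[list[str]]:
        """Ranked items as tie groups, best group first.

        Within a group, items appear in ``item_ids`` order, so
        :func:`dense_ranks_from_ordering` round-trips.
        """
        groups: dict[int, list[str]] = {}
        for item in self.item_ids:
            if item in self.rank_of:
                groups.setdefault(self.rank_of[item], []).append(item)
        return [groups[r] for r in sorted(groups)]

    def findings(self, where: str = "rank vector") -> list[str]:
        out = []
        if self.rank_of and not self.is_dense:
            got = sorted(set(self.rank_of.values()))
            out.append(f"{where}: non-dense ranks {got} (expected 1..{len(got)} with no gaps)")
        return out


def dense_ranks_from_ordering(ordering: list[list[str]]) -> RankVector:
    """Build a :class:`RankVector` from tie groups listed best first.

    Group ``g`` (1-based) maps every member to rank ``g``; an empty ordering
    yields an explicitly empty vector.  A duplicated item signals a malformed
    elicitation and raises ``ValueError``.
    """
    items: list[str] = []
    rank_of: dict[str, int] = {}
    for g, group in enumerate(ordering, start=1):
        if not group:
            raise ValueError(f"tie group {g} is empty")
        for item in group:
            if item in rank_of:
                raise ValueError(f"item {item!r} appears in more than one tie group")
            rank_of[item] = g
            items.append(item)
    return RankVector(item_ids=tuple(items), rank_of=rank_of)


class Attribute(BaseModel):
    """Catalogue entry for one decision attribute (with optional sub-attribute)."""

    model_config = ConfigDict(frozen=True)

    attribute_id: str
    name: str
    sub: str = ""
    description: str = ""


class Alternative(BaseModel):
    model_config = ConfigDict(frozen=True)

    alternative_id: str
    name: str = ""


class OPAInstance(BaseModel):
    """A complete group-decision instance: panel, catalogue and preferences.

    ``expert_rank`` carries the priority index i of each expert (1 = most
    influential); it may be ``None`` when ranks are to be derived from the
    profiles by :func:`opa_mcdm.experts.rank_experts`.  ``attr_ranking`` gives
    each expert's rank vector over attribute ids (providing the index j) and
    ``alt_ranking`` each expert's per-attribute rank vector over alternative
    ids (providing the index r).
    """

    model_config = ConfigDict(frozen=True)

    experts: tuple[ExpertProfile, ...]
    attributes: tuple[Attribute, ...]
    alternatives: tuple[Alternative, ...]
    expert_rank: Optional[dict[str, int]] = None
    attr_ranking: dict[str, RankVector] = {}
    alt_ranking: dict[str, dict[str, RankVector]] = {}

    @property
    def p(self) -> int:
        return len(self.experts)

    @property
    def n(self) -> int:
        return len(self.attributes)

    @property
    def m(self) -> int:
        return len(self.alternatives)

    @property
    def expert_ids(self) -> list[str]:
        return [e.expert_id for e in self.experts]

    @property
    def attribute_ids(self) -> list[str]:
        return [a.attribute_id for a in self.attributes]

    @property
    def alternative_ids(self) -> list[str]:
        return [a.alternative_id for a in self.alternatives]

    def with_expert_rank(self, rank_of: dict[str, int]) -> "OPAInstance":
        return self.model_copy(update={"expert_rank": dict(rank_of)})

    def is_complete_strict(self) -> bool:
        """True when every expert strictly ranks everything (no ties, no gaps)
        and the expert ranks themselves are a strict permutation of 1..p."""
        if self.expert_rank is None:
            return False
        if sorted(self.expert_rank.values()) != list(range(1, self.p + 1)):
            return False
        for eid in self.expert_ids:
            av = self.attr_ranking.get(eid)
            if av is None or not (av.is_complete and av.is_strict and av.is_dense):
                return False
            for aid in self.attribute_ids:
                rv = self.alt_ranking.get(eid, {}).get(aid)
                if rv is None or not (rv.is_complete and rv.is_strict and rv.is_dense):
                    return False
        return True


@dataclass(frozen=True)
class WeightTensor:
    """Solved weights W_ijk keyed by (expert_id, attribute_id, alternative_id),
    plus the optimal objective Z (the minimum scaled adjacent-rank gap)."""

    w: dict[tuple[str, str, str], float]
    z: float
    solver_tag: str

    @property
    def total(self) -> float:
        return sum(self.w.values())


@dataclass(frozen=True)
class AggregateWeights:
    """Marginal significance of experts, attributes and alternatives.

    Each weight map sums to one; ranks are dense with 1 for the largest
    weight, and weights equal within tolerance share a rank.
    """

    expert_weights: dict[str, float]
    attribute_weights: dict[str, float]
    alternative_weights: dict[str, float]
    expert_ranks: dict[str, int] = field(default_factory=dict)
    attribute_ranks: dict[str, int] = field(default_factory=dict)
    alternative_ranks: dict[str, int] = field(default_factory=dict)


def validate_instance(instance: OPAInstance) -> list[str]:
    """Check every structural invariant; return findings (empty = valid).

    Pure and idempotent: the instance is never mutated and repeated calls
    return the same findings.
    """
    f: list[str] = []
    if instance.p < 1:
        f.append("instance: no experts (p must be >= 1)")
    if instance.n < 1:
        f.append("instance: no attributes (n must be >= 1)")
    if instance.m < 1:
        f.append("instance: no alternatives (m must be >= 1)")

    eids = instance.expert_ids
    if len(set(eids)) != len(eids):
        f.append("panel: duplicate expert ids")
    aids = set(instance.attribute_ids)
    kids = set(instance.alternative_ids)
    if len(aids) != instance.n:
        f.append("catalogue: duplicate attribute ids")
    if len(kids) != instance.m:
        f.append("catalogue: duplicate alternative ids")

    if instance.expert_rank is not None:
        if set(instance.expert_rank) != set(eids):
            f.append("expert_rank: keys do not match the panel")
        ranks = sorted(instance.expert_rank.values())
        dense = sorted(set(ranks)) == list(range(1, len(set(ranks)) + 1))
        if not dense or (ranks and ranks[0] != 1):
            f.append(f"expert_rank: ranks {ranks} are not dense from 1")

    for eid, av in instance.attr_ranking.items():
        if eid not in eids:
            f.append(f"attr_ranking: unknown expert {eid!r}")
            continue
        extra = set(av.rank_of) - aids
        if extra:
            f.append(f"attr_ranking[{eid}]: unknown attributes {sorted(extra)}")
        f.extend(av.findings(where=f"attr_ranking[{eid}]"))
        for aid in av.ranked_items:
            if aid in aids and instance.alt_ranking.get(eid, {}).get(aid) is None:
                f.append(
                    f"missing alternative ranking: expert {eid!r} ranked attribute "
                    f"{aid!r} but provides no alternative ranking for it"
                )

    for eid, per_attr in instance.alt_ranking.items():
        if eid not in eids:
            f.append(f"alt_ranking: unknown expert {eid!r}")
            continue
        for aid, rv in per_attr.items():
            if aid not in aids:
                f.append(f"alt_ranking[{eid}]: unknown attribute {aid!r}")
            extra = set(rv.rank_of) - kids
            if extra:
                f.append(f"alt_ranking[{eid}][{aid}]: unknown alternatives {sorted(extra)}")
            f.extend(rv.findings(where=f"alt_ranking[{eid}][{aid}]"))

    return f
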