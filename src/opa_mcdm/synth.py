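"""Synthetic decision instances with controlled ordinal noise.

Rankings are drawn from the Mallows model: the probability of a permutation
is proportional to exp(-theta * d_K), where d_K is the Kendall-tau distance
(number of discordant pairs) to a reference order.  theta = 0 gives uniform
random permutations; large theta concentrates mass on the reference.  The
sampler is the exact repeated-insertion construction: item t of the reference
is inserted at position s (1-based, s <= t) with probability proportional to
phi^(t-s), phi = exp(-theta), which adds exactly t-s discordant pairs.

On top of the sampled strict orders the generator can merge adjacent rank
positions into ties and drop attributes from an expert's ranking, emulating
panels where experts rank some attributes equally or skip ones they cannot
judge.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .experts import (
    EDUCATION_SCALE,
    EXPERIENCE_SCALE,
    POSITION_SCALE,
    ROLE_SCALE,
)
from .schema import (
    Alternative,
    Attribute,
    ExpertProfile,
    OPAInstance,
    RankVector,
    dense_ranks_from_ordering,
)

# cap on theta: exp(-20) ~ 2e-9 per discordant pair, indistinguishable from
# a point mass at the reference for any panel size used here
THETA_CAP = 50.0


class SyntheticSpec(BaseModel):
    """Generator parameters for one synthetic instance."""

    model_config = ConfigDict(frozen=True)

    p: int = Field(ge=1, description="number of experts")
    n: int = Field(ge=1, description="number of attributes")
    m: int = Field(ge=1, description="number of alternatives")
    tie_prob: float = Field(default=0.0, ge=0.0, le=1.0)
    missing_prob: float = Field(default=0.0, ge=0.0, le=1.0)
    noise_theta: float = Field(default=0.0, ge=0.0)
    attr_reference: Optional[tuple[str, ...]] = None
    alt_reference: Optional[tuple[str, ...]] = None
    seed: int = 0


def sample_mallows(
    reference: Sequence[str], theta: float, rng: np.random.Generator
) -> list[str]:
    """One permutation from the Mallows model around *reference*."""
    theta = min(theta, THETA_CAP)
    phi = math.exp(-theta)
    out: list[str] = []
    for t, item in enumerate(reference, start=1):
        # P(insert at position s) ∝ phi^(t-s), s = 1..t
        weights = np.array([phi ** (t - s) for s in range(1, t + 1)])
        s = rng.choice(t, p=weights / weights.sum())
        out.insert(int(s), item)
    return out


def gen_noisy_panel(
    reference: Sequence[str], theta: float, p: int, seed: int | np.random.Generator
) -> list[list[str]]:
    """p independent Mallows draws around a common reference order."""
    if theta < 0:
        raise ValueError("theta must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return [sample_mallows(reference, theta, rng) for _ in range(p)]


def _inject_ties(order: Sequence[str], tie_prob: float, rng: np.random.Generator) -> list[list[str]]:
    """Merge adjacent positions into tie groups, preserving the order."""
    groups = [[order[0]]]
    for item in order[1:]:
        if rng.random() < tie_prob:
            groups[-1].append(item)
        else:
            groups.append([item])
    return groups


def _random_profile(rng: np.random.Generator, expert_id: str) -> ExpertProfile:
    pick = lambda scale: scale.levels[rng.integers(len(scale.levels))]
    return ExpertProfile(
        expert_id=expert_id,
        role=pick(ROLE_SCALE),
        position=pick(POSITION_SCALE),
        experience=pick(EXPERIENCE_SCALE),
        education=pick(EDUCATION_SCALE),
    )


def _ranked_vector(
    universe: Sequence[str],
    order: Sequence[str],
    tie_prob: float,
    rng: np.random.Generator,
) -> RankVector:
    groups = _inject_ties(order, tie_prob, rng)
    rv = dense_ranks_from_ordering(groups)
    return RankVector(item_ids=tuple(universe), rank_of=rv.rank_of)


def gen_instance(spec: SyntheticSpec) -> OPAInstance:
    """Generate a reproducible instance under the given noise regime.

    With ``tie_prob = missing_prob = 0`` and ``noise_theta = 0`` the result is
    a complete strict instance with uniform-random rankings and a uniform
    random expert priority permutation.  Expert profiles are sampled
    uniformly over the panel category scales; they are descriptive context —
    the instance's priority order is the sampled permutation, so strictness
    is guaranteed regardless of profile collisions.
    """
    rng = np.random.default_rng(spec.seed)
    eids = [f"X{i+1}" for i in range(spec.p)]
    aids = spec.attr_reference or tuple(f"c{j+1}" for j in range(spec.n))
    kids = spec.alt_reference or tuple(f"a{k+1}" for k in range(spec.m))
    if len(aids) != spec.n or len(kids) != spec.m:
        raise ValueError("reference order length must match n / m")

    experts = tuple(_random_profile(rng, e) for e in eids)
    perm = rng.permutation(spec.p)
    expert_rank = {e: int(perm[i]) + 1 for i, e in enumerate(eids)}

    attr_ranking: dict[str, RankVector] = {}
    alt_ranking: dict[str, dict[str, RankVector]] = {}
    for eid in eids:
        kept = [a for a in aids if rng.random() >= spec.missing_prob]
        if not kept:  # every expert must express at least one preference
            kept = [aids[rng.integers(spec.n)]]
        kept_order = [a for a in sample_mallows(aids, spec.noise_theta, rng) if a in kept]
        attr_ranking[eid] = _ranked_vector(aids, kept_order, spec.tie_prob, rng)
        alt_ranking[eid] = {
            aid: _ranked_vector(
                kids, sample_mallows(kids, spec.noise_theta, rng), spec.tie_prob, rng
            )
            for aid in kept
        }

    return OPAInstance(
        experts=experts,
        attributes=tuple(Attribute(attribute_id=a, name=a) for a in aids),
        alternatives=tuple(Alternative(alternative_id=k, name=k) for k in kids),
        expert_rank=expert_rank,
        attr_ranking=attr_ranking,
        alt_ranking=alt_ranking,
    )


def gen_consensus_instance(
    true_order: Sequence[str], p: int, n: int, seed: int = 0
) -> OPAInstance:
    """All experts rank the alternatives identically (the consensus order)
    under every attribute; attribute rankings are uniform random strict."""
    rng = np.random.default_rng(seed)
    m = len(true_order)
    eids = [f"X{i+1}" for i in range(p)]
    aids = [f"c{j+1}" for j in range(n)]
    consensus = dense_ranks_from_ordering([[k] for k in true_order])
    consensus = RankVector(item_ids=tuple(true_order), rank_of=consensus.rank_of)

    experts = tuple(_random_profile(rng, e) for e in eids)
    perm = rng.permutation(p)
    expert_rank = {e: int(perm[i]) + 1 for i, e in enumerate(eids)}
    attr_ranking = {}
    alt_ranking = {}
    for eid in eids:
        order = [aids[i] for i in rng.permutation(n)]
        attr_ranking[eid] = _ranked_vector(aids, order, 0.0, rng)
        alt_ranking[eid] = {aid: consensus for aid in aids}
    return OPAInstance(
        experts=experts,
        attributes=tuple(Attribute(attribute_id=a, name=a) for a in aids),
        alternatives=tuple(Alternative(alternative_id=k, name=k) for k in true_order),
        expert_rank=expert_rank,
        attr_ranking=attr_ranking,
        alt_ranking=alt_ranking,
    )


def kendall_distance(a: Sequence[str], b: Sequence[str]) -> int:
    """Number of discordant pairs between two strict orders of the same items."""
    pos = {x: i for i, x in enumerate(b)}
    seq = [pos[x] for x in a]
    return sum(
        1 for i in range(len(seq)) for j in range(i + 1, len(seq)) if seq[i] > seq[j]
    )
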