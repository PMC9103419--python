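"""Lexicographic prioritisation of the expert panel.

Experts are ordered by comparing their profiles criterion by criterion — role
first, then professional position, years of experience and finally education —
each criterion being an ordinal scale with its best level first.  The first
criterion on which two profiles differ decides their order; profiles identical
on every criterion share a dense rank.
"""

from __future__ import annotations

from dataclasses import dataclass

from .schema import ExpertProfile, OrdinalScale

ROLE_SCALE = OrdinalScale(
    name="role",
    levels=(
        "End-user/Caregiver",
        "Therapist/Physiotherapist",
        "Developer",
    ),
)

# Occupational categories, highest professional position first.
POSITION_SCALE = OrdinalScale(
    name="position",
    levels=(
        "Professionals, scientists and intellectuals",
        "Technicians and mid-level and professionals",
        "Elementary occupations",
    ),
)

# Experience brackets compared by their lower bound, most experienced first.
EXPERIENCE_SCALE = OrdinalScale(
    name="experience",
    levels=("more than 20", "15-20", "10-15", "5-10", "1-5"),
)

# Conventional educational-attainment ordering, highest first.
EDUCATION_SCALE = OrdinalScale(
    name="education",
    levels=(
        "Doctorate (Ph.D.)",
        "Postgraduate",
        "Ordinary degree",
        "Technical/vocational",
        "Upper Secondary",
        "Lower Secondary",
        "Primary",
    ),
)


@dataclass(frozen=True)
class ExpertRankingPolicy:
    """Which profile fields to compare, in which order, on which scales."""

    criteria: tuple[str, ...] = ("role", "position", "experience", "education")
    scales: dict[str, OrdinalScale] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.scales is None:
            object.__setattr__(
                self,
                "scales",
                {
                    "role": ROLE_SCALE,
                    "position": POSITION_SCALE,
                    "experience": EXPERIENCE_SCALE,
                    "education": EDUCATION_SCALE,
                },
            )
        if len(set(self.criteria)) != len(self.criteria):
            raise ValueError("ranking criteria must be distinct")
        missing = [c for c in self.criteria if c not in self.scales]
        if missing:
            raise ValueError(f"no scale provided for criteria: {missing}")

    def key(self, profile: ExpertProfile) -> tuple[int, ...]:
        """Lexicographic sort key (smaller = higher priority)."""
        out = []
        for crit in self.criteria:
            value = getattr(profile, crit)
            try:
                out.append(self.scales[crit].index_of(value))
            except KeyError as exc:
                raise ValueError(
                    f"expert {profile.expert_id!r}: unknown {crit} value {value!r}"
                ) from exc
        return tuple(out)


DEFAULT_POLICY = ExpertRankingPolicy()


@dataclass(frozen=True)
class ExpertRankingResult:
    """Dense expert ranks plus the sorted order and any full-profile ties."""

    rank_of: dict[str, int]
    order: tuple[str, ...]
    tie_groups: tuple[tuple[str, ...], ...]

    @property
    def has_ties(self) -> bool:
        return any(len(g) > 1 for g in self.tie_groups)

    def __getitem__(self, expert_id: str) -> int:
        return self.rank_of[expert_id]


def rank_experts(
    panel: list[ExpertProfile], policy: ExpertRankingPolicy = DEFAULT_POLICY
) -> ExpertRankingResult:
    """Assign dense priority ranks i to a panel.

    The assigned ranks depend only on the profiles, never on the order in
    which the panel is listed; experts with identical profiles share a rank.
    """
    if not panel:
        raise ValueError("empty panel")
    ids = [e.expert_id for e in panel]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate expert ids in panel")
    keyed = sorted(panel, key=lambda e: (policy.key(e), e.expert_id))
    rank_of: dict[str, int] = {}
    groups: list[list[str]] = []
    prev_key = None
    rank = 0
    for e in keyed:
        k = policy.key(e)
        if k != prev_key:
            rank += 1
            groups.append([])
            prev_key = k
        rank_of[e.expert_id] = rank
        groups[-1].append(e.expert_id)
    order = tuple(e.expert_id for e in keyed)
    return ExpertRankingResult(
        rank_of=rank_of, order=order, tie_groups=tuple(tuple(g) for g in groups)
    )


def explain_ranking(
    panel: list[ExpertProfile], policy: ExpertRankingPolicy = DEFAULT_POLICY
) -> list[dict[str, str]]:
    """Decision trace: for each adjacent pair in the final order, the first
    criterion that separates them (or ``"tie"`` for identical profiles)."""
    result = rank_experts(panel, policy)
    by_id = {e.expert_id: e for e in panel}
    trace = []
    for above_id, below_id in zip(result.order, result.order[1:]):
        above, below = by_id[above_id], by_id[below_id]
        decided = "tie"
        for crit in policy.criteria:
            scale = policy.scales[crit]
            if scale.index_of(getattr(above, crit)) != scale.index_of(getattr(below, crit)):
                decided = crit
                break
        trace.append(
            {
                "higher": above_id,
                "lower": below_id,
                "decided_by": decided,
            }
        )
    return trace
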