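"""The at-home-rehabilitation case study bundled as a fixture.

Nine experts — three developers, three therapists/physiotherapists, three
end-users/caregivers — evaluate four incremental variants of a home
rehabilitation platform (no video; video calls only; RGB camera with pose
estimation and exercise supervision; depth camera with supervision) on six
attributes: usefulness, system cost, ease of use, ease of technical
development, ease of maintenance, and privacy.

The study published the expert panel and the attribute catalogue but not the
raw per-expert rankings, so :func:`case_study_instance` fills the preference
structure with synthetic complete strict rankings unless the caller supplies
real ones.  Expert marginal weights do not depend on that choice for
complete strict data, which is what makes the published expert-significance
table reproducible.
"""

from __future__ import annotations

from typing import Optional

from .experts import DEFAULT_POLICY, rank_experts
from .schema import Alternative, Attribute, ExpertProfile, OPAInstance, RankVector
from .synth import SyntheticSpec, gen_instance


def case_study_panel() -> list[ExpertProfile]:
    """The nine-expert panel with role, position, experience and education."""
    rows = [
        ("E1", "Developer", "Professionals, scientists and intellectuals", "15-20", "Doctorate (Ph.D.)"),
        ("E2", "Developer", "Professionals, scientists and intellectuals", "10-15", "Doctorate (Ph.D.)"),
        ("E3", "Developer", "Technicians and mid-level and professionals", "10-15", "Upper Secondary"),
        ("E4", "Therapist/Physiotherapist", "Professionals, scientists and intellectuals", "10-15", "Ordinary degree"),
        ("E5", "Therapist/Physiotherapist", "Professionals, scientists and intellectuals", "5-10", "Ordinary degree"),
        ("E6", "Therapist/Physiotherapist", "Technicians and mid-level and professionals", "5-10", "Postgraduate"),
        ("E7", "End-user/Caregiver", "Elementary occupations", "1-5", "Lower Secondary"),
        ("E8", "End-user/Caregiver", "Elementary occupations", "more than 20", "Primary"),
        ("E9", "End-user/Caregiver", "Technicians and mid-level and professionals", "more than 20", "Technical/vocational"),
    ]
    return [
        ExpertProfile(expert_id=i, role=r, position=p, experience=x, education=e)
        for i, r, p, x, e in rows
    ]


def case_study_attributes() -> list[Attribute]:
    return [
        Attribute(attribute_id="j1", name="Usefulness", sub="",
                  description="Importance given to the utility derived from its use."),
        Attribute(attribute_id="j2", name="Cost of system", sub="",
                  description="Importance given to the cost of the total system "
                              "considering the cost savings of each alternative."),
        Attribute(attribute_id="j3", name="Easiness", sub="Use",
                  description="Importance given to the ease of use of the system."),
        Attribute(attribute_id="j4", name="Easiness", sub="Technical Development",
                  description="Importance given to the ease of technical development of the system."),
        Attribute(attribute_id="j5", name="Easiness", sub="Maintenance",
                  description="Importance given to the ease of maintenance of the system."),
        Attribute(attribute_id="j6", name="Privacy", sub="",
                  description="Importance given to the use of different devices "
                              "that may invade privacy."),
    ]


def case_study_alternatives() -> list[Alternative]:
    return [
        Alternative(alternative_id="A1", name="Platform without video"),
        Alternative(alternative_id="A2", name="Platform with RGB camera, video calls only"),
        Alternative(alternative_id="A3", name="Platform with RGB camera and exercise supervision"),
        Alternative(alternative_id="A4", name="Platform with depth camera and exercise supervision"),
    ]


def case_study_instance(
    attr_ranking: Optional[dict[str, RankVector]] = None,
    alt_ranking: Optional[dict[str, dict[str, RankVector]]] = None,
    seed: int = 0,
) -> OPAInstance:
    """The case-study panel and catalogue as a solvable instance.

    Expert ranks are derived lexicographically from the profiles.  If the
    per-expert rankings are not supplied, synthetic complete strict rankings
    (seeded, uniform random) stand in for the unpublished originals.
    """
    panel = case_study_panel()
    attributes = case_study_attributes()
    alternatives = case_study_alternatives()
    ranks = rank_experts(panel, DEFAULT_POLICY)

    if attr_ranking is None or alt_ranking is None:
        synth = gen_instance(
            SyntheticSpec(
                p=len(panel),
                n=len(attributes),
                m=len(alternatives),
                attr_reference=tuple(a.attribute_id for a in attributes),
                alt_reference=tuple(a.alternative_id for a in alternatives),
                seed=seed,
            )
        )
        remap = dict(zip(synth.expert_ids, (e.expert_id for e in panel)))
        if attr_ranking is None:
            attr_ranking = {remap[e]: v for e, v in synth.attr_ranking.items()}
        if alt_ranking is None:
            alt_ranking = {remap[e]: v for e, v in synth.alt_ranking.items()}

    return OPAInstance(
        experts=tuple(panel),
        attributes=tuple(attributes),
        alternatives=tuple(alternatives),
        expert_rank=ranks.rank_of,
        attr_ranking=attr_ranking,
        alt_ranking=alt_ranking,
    )
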