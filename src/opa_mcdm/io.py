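"""Reading and writing instances, tensors and reports.

Two instance formats are supported and round-trip losslessly, including tie
groups and missing rankings:

* a single JSON document with the panel, catalogue, alternatives and all
  orderings (orderings encoded as lists of tie-group lists, best first);
* a CSV trio — ``experts.csv`` (panel), ``attr_ranks.csv`` (expert-by-
  attribute rank matrix, blank cell = attribute not ranked) and
  ``alt_ranks.csv`` (long format: expert, attribute, alternative, rank) —
  where tied items are encoded by equal integer ranks.

All CSV files are comma-separated UTF-8 with a header row.
"""

from __future__ import annotations

import csv
import json
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .schema import (
    Alternative,
    Attribute,
    ExpertProfile,
    OPAInstance,
    RankVector,
    WeightTensor,
    validate_instance,
)


def round_half_up(x: float, digits: int = 4) -> float:
    """Decimal half-up rounding (0.35345 -> 0.3535 at 4 digits)."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------- instances


def _ordering_of(rv: RankVector) -> list[list[str]]:
    return rv.tie_groups()


def instance_to_dict(instance: OPAInstance) -> dict:
    doc = {
        "experts": [
            {
                "id": e.expert_id,
                "role": e.role,
                "position": e.position,
                "experience": e.experience,
                "education": e.education,
            }
            for e in instance.experts
        ],
        "attributes": [
            {"id": a.attribute_id, "name": a.name, "sub": a.sub, "description": a.description}
            for a in instance.attributes
        ],
        "alternatives": [
            {"id": a.alternative_id, "name": a.name} for a in instance.alternatives
        ],
        "attr_rankings": {e: _ordering_of(v) for e, v in instance.attr_ranking.items()},
        "alt_rankings": {
            e: {a: _ordering_of(v) for a, v in per.items()}
            for e, per in instance.alt_ranking.items()
        },
    }
    if instance.expert_rank is not None:
        doc["expert_ranks"] = dict(instance.expert_rank)
    return doc


def _vector_from_ordering(ordering: list[list[str]], universe: Sequence[str]) -> RankVector:
    rank_of: dict[str, int] = {}
    for g, group in enumerate(ordering, start=1):
        for item in group:
            if item in rank_of:
                raise ValueError(f"item {item!r} appears in more than one tie group")
            rank_of[item] = g
    return RankVector(item_ids=tuple(universe), rank_of=rank_of)


def instance_from_dict(doc: dict) -> OPAInstance:
    attributes = tuple(
        Attribute(
            attribute_id=a["id"],
            name=a.get("name", a["id"]),
            sub=a.get("sub", ""),
            description=a.get("description", ""),
        )
        for a in doc["attributes"]
    )
    alternatives = tuple(
        Alternative(alternative_id=a["id"], name=a.get("name", "")) for a in doc["alternatives"]
    )
    aids = [a.attribute_id for a in attributes]
    kids = [a.alternative_id for a in alternatives]
    return OPAInstance(
        experts=tuple(
            ExpertProfile(
                expert_id=e["id"],
                role=e.get("role", ""),
                position=e.get("position", ""),
                experience=e.get("experience", ""),
                education=e.get("education", ""),
            )
            for e in doc["experts"]
        ),
        attributes=attributes,
        alternatives=alternatives,
        expert_rank={k: int(v) for k, v in doc["expert_ranks"].items()}
        if "expert_ranks" in doc
        else None,
        attr_ranking={
            e: _vector_from_ordering(o, aids) for e, o in doc.get("attr_rankings", {}).items()
        },
        alt_ranking={
            e: {a: _vector_from_ordering(o, kids) for a, o in per.items()}
            for e, per in doc.get("alt_rankings", {}).items()
        },
    )


def write_instance_json(instance: OPAInstance, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(instance_to_dict(instance), indent=2, sort_keys=True) + "\n"
    )


def read_instance_json(path: str | Path) -> OPAInstance:
    return instance_from_dict(json.loads(Path(path).read_text()))


def _parse_rank(raw: str, where: str) -> int:
    try:
        value = int(raw)
    except ValueError as exc:
        raise ValueError(f"{where}: rank {raw!r} is not an integer") from exc
    if value < 1:
        raise ValueError(f"{where}: rank {value} must be a positive integer")
    return value


def read_instance_csv(
    experts_csv: str | Path, attr_ranks_csv: str | Path, alt_ranks_csv: str | Path
) -> OPAInstance:
    """Assemble an instance from the CSV trio, cross-checking identifiers."""
    experts: list[ExpertProfile] = []
    expert_rank: dict[str, int] = {}
    with open(experts_csv, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            experts.append(
                ExpertProfile(
                    expert_id=row["expert_id"],
                    role=row.get("role", ""),
                    position=row.get("position", ""),
                    experience=row.get("experience", ""),
                    education=row.get("education", ""),
                )
            )
            if row.get("rank"):
                expert_rank[row["expert_id"]] = _parse_rank(
                    row["rank"], f"{experts_csv}: expert {row['expert_id']}"
                )
    eids = {e.expert_id for e in experts}

    attr_ranking: dict[str, RankVector] = {}
    with open(attr_ranks_csv, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        aids = [c for c in reader.fieldnames or [] if c != "expert_id"]
        for row in reader:
            eid = row["expert_id"]
            if eid not in eids:
                raise ValueError(f"{attr_ranks_csv}: unknown expert {eid!r}")
            rank_of = {
                a: _parse_rank(row[a], f"{attr_ranks_csv}: expert {eid}, attribute {a}")
                for a in aids
                if row.get(a, "").strip()
            }
            attr_ranking[eid] = RankVector(item_ids=tuple(aids), rank_of=rank_of)

    alt_ranking: dict[str, dict[str, dict[str, int]]] = {}
    kids: list[str] = []
    with open(alt_ranks_csv, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            eid, aid, kid = row["expert_id"], row["attribute_id"], row["alternative_id"]
            if eid not in eids:
                raise ValueError(f"{alt_ranks_csv}: unknown expert {eid!r}")
            if aid not in aids:
                raise ValueError(f"{alt_ranks_csv}: unknown attribute {aid!r}")
            if kid not in kids:
                kids.append(kid)
            alt_ranking.setdefault(eid, {}).setdefault(aid, {})[kid] = _parse_rank(
                row["rank"], f"{alt_ranks_csv}: {eid}/{aid}/{kid}"
            )

    return OPAInstance(
        experts=tuple(experts),
        attributes=tuple(Attribute(attribute_id=a, name=a) for a in aids),
        alternatives=tuple(Alternative(alternative_id=k, name=k) for k in kids),
        expert_rank=expert_rank or None,
        attr_ranking=attr_ranking,
        alt_ranking={
            e: {a: RankVector(item_ids=tuple(kids), rank_of=r) for a, r in per.items()}
            for e, per in alt_ranking.items()
        },
    )


def write_instance_csv(
    instance: OPAInstance,
    experts_csv: str | Path,
    attr_ranks_csv: str | Path,
    alt_ranks_csv: str | Path,
) -> None:
    """Write the CSV trio; inverse of :func:`read_instance_csv` up to the
    attribute/alternative display names, which the trio does not carry."""
    with open(experts_csv, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["expert_id", "role", "position", "experience", "education", "rank"])
        for e in instance.experts:
            rank = "" if instance.expert_rank is None else instance.expert_rank[e.expert_id]
            writer.writerow([e.expert_id, e.role, e.position, e.experience, e.education, rank])
    aids = instance.attribute_ids
    with open(attr_ranks_csv, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["expert_id", *aids])
        for eid in instance.expert_ids:
            rv = instance.attr_ranking.get(eid)
            writer.writerow(
                [eid, *["" if rv is None or a not in rv.rank_of else rv.rank_of[a] for a in aids]]
            )
    with open(alt_ranks_csv, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["expert_id", "attribute_id", "alternative_id", "rank"])
        for eid in instance.expert_ids:
            for aid, rv in instance.alt_ranking.get(eid, {}).items():
                for kid in rv.ranked_items:
                    writer.writerow([eid, aid, kid, rv.rank_of[kid]])


def read_instance(
    path: str | Path | None = None,
    experts_csv: str | Path | None = None,
    attr_ranks_csv: str | Path | None = None,
    alt_ranks_csv: str | Path | None = None,
    require_valid: bool = True,
) -> OPAInstance:
    """Load an instance from JSON or from the CSV trio and validate it."""
    if path is not None:
        instance = read_instance_json(path)
    elif experts_csv and attr_ranks_csv and alt_ranks_csv:
        instance = read_instance_csv(experts_csv, attr_ranks_csv, alt_ranks_csv)
    else:
        raise ValueError("provide either an instance JSON path or the CSV trio")
    if require_valid:
        findings = validate_instance(instance)
        if findings:
            raise ValueError("invalid instance:\n  " + "\n  ".join(findings))
    return instance


# ------------------------------------------------------------------ tensors


def write_tensor_csv(tensor: WeightTensor, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["expert_id", "attribute_id", "alternative_id", "weight"])
        for (e, a, k), w in sorted(tensor.w.items()):
            writer.writerow([e, a, k, repr(w)])


def write_tensor_json(tensor: WeightTensor, path: str | Path) -> None:
    doc = {
        "z": tensor.z,
        "solver_tag": tensor.solver_tag,
        "weights": [
            {"expert": e, "attribute": a, "alternative": k, "weight": w}
            for (e, a, k), w in sorted(tensor.w.items())
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


# ------------------------------------------------------------------ reports


def weight_table(
    weights: dict[str, float], ranks: dict[str, int], label: str, digits: Optional[int] = 4
) -> pd.DataFrame:
    """Two-column significance table (weight, rank) sorted by catalogue order."""
    rows = [
        {label: k, "Weight": round_half_up(w, digits) if digits is not None else w,
         "Rank": ranks[k]}
        for k, w in weights.items()
    ]
    return pd.DataFrame(rows)


def write_report(report, out_dir: str | Path, digits: int = 4) -> dict[str, Path]:
    """Write the three significance tables, the significance matrix and the
    full-precision JSON report; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    agg = report.aggregates
    paths = {}
    for name, weights, ranks, label in [
        ("experts", agg.expert_weights, agg.expert_ranks, "Expert"),
        ("attributes", agg.attribute_weights, agg.attribute_ranks, "Attribute"),
        ("alternatives", agg.alternative_weights, agg.alternative_ranks, "Alternative"),
    ]:
        p = out / f"{name}.csv"
        weight_table(weights, ranks, label, digits).to_csv(p, index=False)
        paths[name] = p
    p = out / "significance.csv"
    report.significance.round(10).to_csv(p, index_label="expert_id")
    paths["significance"] = p
    p = out / "report.json"
    p.write_text(
        json.dumps(
            {
                "z": report.z,
                "solver_tag": report.solver_tag,
                "tolerance": report.tolerance,
                "instance_digest": report.instance_digest,
                "expert_weights": agg.expert_weights,
                "attribute_weights": agg.attribute_weights,
                "alternative_weights": agg.alternative_weights,
                "expert_ranks": agg.expert_ranks,
                "attribute_ranks": agg.attribute_ranks,
                "alternative_ranks": agg.alternative_ranks,
                "final_ranking": list(report.final_ranking),
                "tied_alternatives": [list(g) for g in report.tied_alternatives],
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    paths["report"] = p
    return paths


def render_report(report, digits: int = 4) -> str:
    """Plain-text console rendering of the three significance tables."""
    agg = report.aggregates
    parts = []
    for title, weights, ranks, label in [
        ("Significance of the experts", agg.expert_weights, agg.expert_ranks, "Expert"),
        ("Significance of the attributes", agg.attribute_weights, agg.attribute_ranks, "Attribute"),
        ("Significance of the alternatives", agg.alternative_weights, agg.alternative_ranks, "Alternative"),
    ]:
        df = weight_table(weights, ranks, label, digits)
        parts.append(title + "\n" + df.to_string(index=False))
    parts.append(f"Best alternative: {report.final_ranking[0]}   (Z = {report.z:.6g})")
    if report.tied_alternatives:
        parts.append(f"Tied alternatives (reported, display order is catalogue order): "
                     f"{report.tied_alternatives}")
    return "\n\n".join(parts)
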