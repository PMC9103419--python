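"""The OPA max-min linear program and its closed-form counterpart.

For expert at priority rank i who placed an attribute at rank j and the
alternatives at ranks r = 1..m', the model maximises Z subject to

    Z <= i * j * r * (W_r - W_{r+1})   for r < m'   (adjacent-rank gaps)
    Z <= i * j * m' * W_{m'}                        (last rank)
    sum of all weights = 1,  W >= 0

where the multipliers are always *rank positions*, not identity indices.
Ties are handled by dense compaction: alternatives sharing a rank occupy one
position in the telescoping chain and their weights are constrained equal;
attributes an expert left unranked contribute no variables and that expert's
attribute ranks are compacted to 1..n_i.

For complete strict instances every inequality is tight at the optimum, which
yields the closed form

    W_ij(r) = Z / (i*j) * sum_{s=r..m} 1/s,      Z = 1 / (m * sum_ij 1/(i*j))

so the expert at rank i carries marginal weight (1/i)/H_p regardless of which
attribute and alternative orders the experts chose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .schema import OPAInstance, WeightTensor

Var = tuple[str, str, str]  # (expert_id, attribute_id, alternative_id)


@dataclass(frozen=True)
class DegeneracyPolicy:
    """How ties and missing attribute rankings enter the LP.

    ``tie_equalise`` binds the weights of alternatives sharing a rank;
    ``compact_missing`` drops unranked attributes and renumbers the remaining
    attribute ranks densely (the expert simply expresses no preference there).
    Both are the defaults and currently the only supported behaviours; the
    policy object exists so the choice is explicit at call sites.
    """

    tie_equalise: bool = True
    compact_missing: bool = True


@dataclass(frozen=True)
class ChainRow:
    """One inequality Z <= multiplier * (sum(plus) - sum(minus))."""

    label: str
    multiplier: int
    plus: tuple[Var, ...]
    minus: tuple[Var, ...] = ()


@dataclass(frozen=True)
class LPSpec:
    """Assembled constraint system in deterministic variable order."""

    variables: tuple[Var, ...]
    rows: tuple[ChainRow, ...]
    tie_pairs: tuple[tuple[Var, Var], ...] = ()

    @property
    def n_vars(self) -> int:
        return len(self.variables)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def to_lp_text(self) -> str:
        """Plain-text LP dump (CPLEX-LP-like) for debugging with any solver."""
        name = {v: f"w_{i}" for i, v in enumerate(self.variables)}
        lines = ["Maximize", " obj: z", "Subject To"]
        for idx, row in enumerate(self.rows):
            terms = [f"- {row.multiplier} {name[v]}" for v in row.plus]
            terms += [f"+ {row.multiplier} {name[v]}" for v in row.minus]
            lines.append(f" c{idx}: z {' '.join(terms)} <= 0")
        for idx, (a, b) in enumerate(self.tie_pairs):
            lines.append(f" t{idx}: {name[a]} - {name[b]} = 0")
        lines.append(" norm: " + " + ".join(name[v] for v in self.variables) + " = 1")
        lines.append("Bounds")
        lines.append(" z free")
        lines.append("End")
        lines.append("")
        lines.extend(f"\\ {name[v]} = W[{v[0]},{v[1]},{v[2]}]" for v in self.variables)
        return "\n".join(lines)


class ClosedFormInapplicableError(ValueError):
    """Raised when the closed form is asked about an instance with ties or
    missing rankings; use :func:`solve_lp` for those."""


def _require_ranked(instance: OPAInstance) -> dict[str, int]:
    if instance.expert_rank is None:
        raise ValueError(
            "instance has no expert ranks; derive them with rank_experts() "
            "or supply expert_rank explicitly"
        )
    return instance.expert_rank


def build_lp(instance: OPAInstance, policy: DegeneracyPolicy = DegeneracyPolicy()) -> LPSpec:
    """Assemble the constraint system for a validated instance.

    Variables are ordered by (expert rank, attribute rank, alternative rank),
    with catalogue order breaking ties, so the solved basis — and therefore
    the reported weights — are reproducible run to run.
    """
    expert_rank = _require_ranked(instance)
    attr_pos = {a: k for k, a in enumerate(instance.attribute_ids)}
    alt_pos = {a: k for k, a in enumerate(instance.alternative_ids)}

    variables: list[Var] = []
    rows: list[ChainRow] = []
    tie_pairs: list[tuple[Var, Var]] = []

    experts = sorted(
        instance.expert_ids, key=lambda e: (expert_rank[e], instance.expert_ids.index(e))
    )
    any_ranked = False
    for eid in experts:
        i = expert_rank[eid]
        av = instance.attr_ranking.get(eid)
        if av is None or not av.rank_of:
            continue
        any_ranked = True
        # dense compaction of this expert's attribute ranks onto 1..n_i
        distinct = sorted(set(av.rank_of.values()))
        j_of = {r: pos for pos, r in enumerate(distinct, start=1)}
        for aid in sorted(av.ranked_items, key=lambda a: (av.rank_of[a], attr_pos[a])):
            j = j_of[av.rank_of[aid]]
            rv = instance.alt_ranking.get(eid, {}).get(aid)
            if rv is None or not rv.rank_of:
                raise ValueError(
                    f"expert {eid!r} ranked attribute {aid!r} but provides no "
                    "alternative ranking for it"
                )
            groups = rv.tie_groups()
            groups = [sorted(g, key=alt_pos.__getitem__) for g in groups]
            m_prime = len(groups)
            reps: list[Var] = []
            for group in groups:
                rep = (eid, aid, group[0])
                reps.append(rep)
                for alt in group:
                    variables.append((eid, aid, alt))
                for alt in group[1:]:
                    tie_pairs.append((rep, (eid, aid, alt)))
            for r in range(1, m_prime):
                rows.append(
                    ChainRow(
                        label=f"{eid}/{aid}/r{r}",
                        multiplier=i * j * r,
                        plus=(reps[r - 1],),
                        minus=(reps[r],),
                    )
                )
            rows.append(
                ChainRow(
                    label=f"{eid}/{aid}/last",
                    multiplier=i * j * m_prime,
                    plus=(reps[m_prime - 1],),
                )
            )
    if not any_ranked:
        raise ValueError("empty preference structure: no expert ranked any attribute")
    return LPSpec(variables=tuple(variables), rows=tuple(rows), tie_pairs=tuple(tie_pairs))


def solve_lp(spec: LPSpec, tol: float = 1e-9) -> WeightTensor:
    """Maximise Z over the assembled system with HiGHS.

    The optimum is unique in the weights (the chain constraints plus the
    normalisation pin every variable once Z is fixed), so the result does not
    depend on variable ordering beyond round-off.
    """
    nv = spec.n_vars
    idx = {v: k for k, v in enumerate(spec.variables)}
    zi = nv  # objective variable is last

    a_ub = np.zeros((spec.n_rows, nv + 1))
    for r, row in enumerate(spec.rows):
        a_ub[r, zi] = 1.0
        for v in row.plus:
            a_ub[r, idx[v]] -= row.multiplier
        for v in row.minus:
            a_ub[r, idx[v]] += row.multiplier
    b_ub = np.zeros(spec.n_rows)

    n_eq = 1 + len(spec.tie_pairs)
    a_eq = np.zeros((n_eq, nv + 1))
    a_eq[0, :nv] = 1.0
    b_eq = np.zeros(n_eq)
    b_eq[0] = 1.0
    for k, (a, b) in enumerate(spec.tie_pairs, start=1):
        a_eq[k, idx[a]] = 1.0
        a_eq[k, idx[b]] = -1.0

    c = np.zeros(nv + 1)
    c[zi] = -1.0  # maximise Z
    bounds = [(0.0, None)] * nv + [(None, None)]
    res = linprog(c, A_ub=a_ub, b_ub=b_ub, A_eq=a_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(
            f"LP solve failed ({res.status}: {res.message}); this indicates a "
            "malformed constraint system, not a property of the instance"
        )
    w = {v: max(0.0, float(res.x[idx[v]])) for v in spec.variables}
    return WeightTensor(w=w, z=float(res.x[zi]), solver_tag="scipy-highs")


def solve_closed_form(instance: OPAInstance) -> WeightTensor:
    """Exact solution for complete strict instances (all inequalities tight).

    Applicable only when expert ranks are a strict permutation and every rank
    vector is complete, strict and dense; anything else raises
    :class:`ClosedFormInapplicableError`.
    """
    expert_rank = _require_ranked(instance)
    if not instance.is_complete_strict():
        raise ClosedFormInapplicableError(
            "closed form requires complete strict rankings everywhere; "
            "solve this instance with build_lp + solve_lp instead"
        )
    m = instance.m
    inv_ij = 0.0
    for eid in instance.expert_ids:
        i = expert_rank[eid]
        for j in instance.attr_ranking[eid].rank_of.values():
            inv_ij += 1.0 / (i * j)
    z = 1.0 / (m * inv_ij)
    # suffix sums of the harmonic tail: tail[r] = sum_{s=r..m} 1/s (1-based)
    tail = np.zeros(m + 2)
    for s in range(m, 0, -1):
        tail[s] = tail[s + 1] + 1.0 / s
    w: dict[tuple[str, str, str], float] = {}
    for eid in instance.expert_ids:
        i = expert_rank[eid]
        for aid, j in instance.attr_ranking[eid].rank_of.items():
            rv = instance.alt_ranking[eid][aid]
            for kid, r in rv.rank_of.items():
                w[(eid, aid, kid)] = float(z / (i * j) * tail[r])
    return WeightTensor(w=w, z=z, solver_tag="closed-form")


def solve(instance: OPAInstance, solver: str = "auto", tol: float = 1e-9) -> WeightTensor:
    """Solve an instance by the requested route.

    ``"auto"`` takes the closed form when the instance is complete and strict
    (fast and exact) and the LP otherwise; ``"lp"`` and ``"closed-form"``
    force a route.
    """
    if solver not in {"auto", "lp", "closed-form"}:
        raise ValueError(f"unknown solver {solver!r}")
    if solver == "closed-form":
        return solve_closed_form(instance)
    if solver == "auto" and instance.expert_rank is not None and instance.is_complete_strict():
        return solve_closed_form(instance)
    return solve_lp(build_lp(instance), tol=tol)
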