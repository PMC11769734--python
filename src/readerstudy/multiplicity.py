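"""Family-wise error control: Holm-Bonferroni and hierarchical gatekeeping.

The coprimary endpoints (AUROC, sensitivity and specificity at PI-RADS >=3)
are tested jointly; by default they form a single Holm family. A deeper
prespecified hierarchy can be configured: each family of sibling hypotheses
is tested (Holm within the family) only if its parent hypothesis was
rejected; hypotheses whose gate stays closed are reported as "not tested",
never as accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

REJECTED = "rejected"
NOT_REJECTED = "not_rejected"
NOT_TESTED = "not_tested"


@dataclass
class HolmResult:
    """Holm-adjusted p-values (original order) and rejection flags."""

    p_raw: np.ndarray
    p_adjusted: np.ndarray
    reject: np.ndarray
    alpha: float


def holm_adjust(p_values, alpha: float = 0.05) -> HolmResult:
    """Holm-Bonferroni step-down adjustment.

    Sort ascending; the k-th smallest p-value is multiplied by (m - k + 1),
    running maxima enforce monotonicity, and values are capped at 1.
    Rejection proceeds from the smallest p-value and stops at the first
    adjusted value above ``alpha``.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return HolmResult(p, p.copy(), np.zeros(0, dtype=bool), alpha)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepdown = p[order] * (m - np.arange(m))
    adjusted_sorted = np.minimum(np.maximum.accumulate(stepdown), 1.0)
    reject_sorted = np.zeros(m, dtype=bool)
    for k in range(m):
        if adjusted_sorted[k] <= alpha:
            reject_sorted[k] = True
        else:
            break
    p_adjusted = np.empty(m)
    reject = np.empty(m, dtype=bool)
    p_adjusted[order] = adjusted_sorted
    reject[order] = reject_sorted
    return HolmResult(p, p_adjusted, reject, alpha)


@dataclass
class HypothesisNode:
    """One hypothesis in the gatekeeping tree."""

    hypothesis_id: str
    p_raw: float
    parent: str | None = None
    family: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_raw <= 1:
            raise ValueError(f"{self.hypothesis_id}: p_raw must lie in [0, 1]")


@dataclass
class GatekeepingResult:
    decisions: dict[str, str]
    p_adjusted: dict[str, float]

    def rejected(self) -> list[str]:
        return [h for h, d in self.decisions.items() if d == REJECTED]


def gatekeep(nodes: list[HypothesisNode], alpha: float = 0.05) -> GatekeepingResult:
    """Hierarchical gatekeeping with Holm testing within each family.

    A family (group of siblings sharing a parent and family label) is
    tested only once its parent hypothesis is rejected; root families
    (parent ``None``) are always tested.
    """
    by_id = {n.hypothesis_id: n for n in nodes}
    if len(by_id) != len(nodes):
        raise ValueError("duplicate hypothesis ids")
    for n in nodes:
        if n.parent is not None and n.parent not in by_id:
            raise ValueError(f"{n.hypothesis_id}: unknown parent {n.parent!r}")
    # cycle check by walking each node's ancestry
    for n in nodes:
        seen = {n.hypothesis_id}
        cur = n.parent
        while cur is not None:
            if cur in seen:
                raise ValueError(f"cycle in hypothesis tree through {cur!r}")
            seen.add(cur)
            cur = by_id[cur].parent

    families: dict[tuple[str | None, str | None], list[HypothesisNode]] = {}
    for n in nodes:
        families.setdefault((n.parent, n.family), []).append(n)

    decisions: dict[str, str] = {n.hypothesis_id: NOT_TESTED for n in nodes}
    p_adjusted: dict[str, float] = {}
    resolved: set[str] = set()
    pending = dict(families)
    progress = True
    while pending and progress:
        progress = False
        for key in list(pending):
            parent, _ = key
            if parent is not None and parent not in resolved:
                continue  # gate not resolved yet
            members = pending.pop(key)
            resolved.update(n.hypothesis_id for n in members)
            progress = True
            if parent is not None and decisions[parent] != REJECTED:
                continue  # gate closed: members stay "not tested"
            res = holm_adjust([n.p_raw for n in members], alpha=alpha)
            for n, padj, rej in zip(members, res.p_adjusted, res.reject):
                p_adjusted[n.hypothesis_id] = float(padj)
                decisions[n.hypothesis_id] = REJECTED if rej else NOT_REJECTED
    return GatekeepingResult(decisions=decisions, p_adjusted=p_adjusted)


def coprimary_family(p_auroc: float, p_sens: float, p_spec: float) -> list[HypothesisNode]:
    """Default single Holm family over the three coprimary endpoints."""
    return [
        HypothesisNode("auroc", p_auroc, family="coprimary"),
        HypothesisNode("sensitivity_p3", p_sens, family="coprimary"),
        HypothesisNode("specificity_p3", p_spec, family="coprimary"),
    ]
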