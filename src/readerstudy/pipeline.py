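"""High-level orchestration: run every endpoint of the paired analysis."""

from __future__ import annotations

import logging

from .metrics import RULES
from .multiplicity import GatekeepingResult, coprimary_family, gatekeep
from .ormrmc import ObuchowskiRockette, ORResult
from .study import Study

logger = logging.getLogger(__name__)

SUBGROUPS = ("all", "expert", "nonexpert")


def analyze_all(study: Study, margin: float = 0.05, alpha: float = 0.05,
                interval: str = "wald", alternative: str = "noninferiority",
                subgroups=SUBGROUPS) -> dict[tuple[str, str | None, str], ORResult]:
    """OR analysis for AUROC and sens/spec under all rules and subgroups.

    Returns ``{(metric, rule_id or None, subgroup): ORResult}``; the AUROC
    ignores positivity rules and appears once per subgroup.
    """
    results: dict[tuple[str, str | None, str], ORResult] = {}
    for subgroup in subgroups:
        est = ObuchowskiRockette(metric="auroc", margin=margin, alpha=alpha,
                                 interval=interval, alternative=alternative)
        est.fit(study, subgroup=subgroup)
        results[("auroc", None, subgroup)] = est.result_
        for rule_id in RULES:
            for metric in ("sensitivity", "specificity"):
                est = ObuchowskiRockette(metric=metric, rule=rule_id, margin=margin,
                                         alpha=alpha, interval=interval,
                                         alternative=alternative)
                est.fit(study, subgroup=subgroup)
                results[(metric, rule_id, subgroup)] = est.result_
        logger.info("analysis done for subgroup %s", subgroup)
    return results


def coprimary_decisions(results: dict, alpha: float = 0.05) -> GatekeepingResult:
    """Holm decisions over the three coprimary noninferiority endpoints.

    The coprimary family is AUROC plus sensitivity and specificity at
    PI-RADS >= 3, all-readers analysis.
    """
    nodes = coprimary_family(
        results[("auroc", None, "all")].p_value,
        results[("sensitivity", "p3", "all")].p_value,
        results[("specificity", "p3", "all")].p_value,
    )
    return gatekeep(nodes, alpha=alpha)
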