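"""Per-reader diagnostic accuracy for paired reader studies.

Two families of endpoints are supported:

* the empirical AUROC of the 0-100 patient-level suspicion score,
  computed as the Mann-Whitney statistic (tied scores get half credit),
  equivalently the trapezoidal area under the empirical ROC curve; and
* sensitivity/specificity of the patient-level PI-RADS category binarized
  under one of three positivity rules:

  - ``p3``     : PI-RADS >= 3
  - ``p4psad`` : PI-RADS >= 4, or PI-RADS 3 with PSA density >= 0.15 ng/ml^2
  - ``p4``     : PI-RADS >= 4
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DegenerateInputError
from .study import Study

METRICS = ("auroc", "sensitivity", "specificity")
RULE_IDS = ("p3", "p4psad", "p4")


@dataclass(frozen=True)
class PositivityRule:
    """Binarization rule mapping (patient category, PSA density) -> call.

    ``p4psad`` implements the PSAd-conditional threshold: category 4-5
    exams are positive, and category 3 exams are positive when PSA density
    is at or above ``psad_threshold`` (inclusive). A missing PSA density is
    treated as below threshold (with a warning at call sites that see one).
    """

    rule_id: str
    psad_threshold: float = 0.15

    def __post_init__(self) -> None:
        if self.rule_id not in RULE_IDS:
            raise ValueError(f"rule_id must be one of {RULE_IDS}, got {self.rule_id!r}")
        if self.psad_threshold <= 0:
            raise ValueError("psad_threshold must be > 0")

    def is_positive(self, patient_category, psad=None):
        """Vectorized binary call; scalars in, scalar out."""
        cat = np.asarray(patient_category)
        if not np.isin(cat, (2, 3, 4, 5)).all():
            raise ValueError("patient category outside {2, 3, 4, 5}")
        if self.rule_id == "p3":
            pos = cat >= 3
        elif self.rule_id == "p4":
            pos = cat >= 4
        else:
            psad_arr = np.asarray(np.nan if psad is None else psad, dtype=float)
            psad_arr = np.broadcast_to(psad_arr, cat.shape) if cat.shape else psad_arr
            missing_relevant = (cat == 3) & np.isnan(psad_arr)
            if np.any(missing_relevant):
                warnings.warn(
                    "missing PSA density on category-3 exam(s): treated as below threshold"
                )
            elevated = np.where(np.isnan(psad_arr), False, psad_arr >= self.psad_threshold)
            pos = (cat >= 4) | ((cat == 3) & elevated)
        if np.isscalar(patient_category):
            return bool(pos)
        return pos


PIRADS3 = PositivityRule("p3")
PIRADS4_PSAD = PositivityRule("p4psad")
PIRADS4 = PositivityRule("p4")
RULES = {"p3": PIRADS3, "p4psad": PIRADS4_PSAD, "p4": PIRADS4}


def apply_positivity_rule(patient_category, psad, rule: PositivityRule | str):
    """Binary biopsy call for one exam (or an array of exams)."""
    if isinstance(rule, str):
        rule = RULES[rule]
    return rule.is_positive(patient_category, psad)


def _check_two_classes(labels: np.ndarray, context: str = "") -> None:
    if labels.min() == labels.max():
        raise DegenerateInputError(
            f"single-class input{f' for {context}' if context else ''}:"
            " need at least one positive and one negative case"
        )


def empirical_auroc(scores, labels) -> float:
    """Empirical AUROC as the normalized Mann-Whitney U statistic.

    Counts score pairs in which a diseased case outranks a benign case,
    with half credit for ties; identical to the trapezoidal area under
    the empirical ROC curve.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-d arrays of equal length")
    _check_two_classes(y)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def sens_spec(patient_categories, labels, psad, rule: PositivityRule | str) -> tuple[float, float]:
    """Sensitivity and specificity of one reader-modality under a rule."""
    y = np.asarray(labels)
    _check_two_classes(y)
    calls = apply_positivity_rule(np.asarray(patient_categories), psad, rule)
    calls = np.asarray(calls, dtype=bool)
    sens = float(calls[y == 1].mean())
    spec = float((~calls[y == 0]).mean())
    return sens, spec


@dataclass
class AccuracyTable:
    """Per reader x modality values of one accuracy metric.

    ``values`` has one row per reader (index ``reader_id``) and columns
    ``bp``/``mp``; ``reader_info`` carries block and expertise, and
    ``n_cases`` the per-reader paired case count (used by the jackknife).
    """

    metric: str
    values: pd.DataFrame
    reader_info: pd.DataFrame
    n_cases: pd.Series
    rule: PositivityRule | None = None

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        vals = self.values[list(self.values.columns)].to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("accuracy values must lie in [0, 1]")

    def to_csv(self, path) -> None:
        self.values.to_csv(path)


def per_reader_metric_table(
    study: Study,
    metric: str,
    rule: PositivityRule | str | None = None,
    subgroup: str | None = None,
) -> AccuracyTable:
    """Compute one accuracy metric per (modality, reader).

    AUROC uses the suspicion score and ignores ``rule``; sensitivity and
    specificity binarize the patient category under ``rule``. ``subgroup``
    restricts to ``"expert"`` or ``"nonexpert"`` readers.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if metric != "auroc":
        if rule is None:
            raise ValueError("sensitivity/specificity require a positivity rule")
        if isinstance(rule, str):
            rule = RULES[rule]
    else:
        rule = None
    paired = study.paired_readings(warn_unpaired=False)
    if subgroup and subgroup != "all":
        paired = paired[paired["expertise"] == subgroup]
        if paired.empty:
            raise ValueError(f"no readers in subgroup {subgroup!r}")
    rows = {}
    n_cases = {}
    for reader_id, grp in paired.groupby("reader_id", sort=True):
        rows[reader_id] = {}
        n_cases[reader_id] = len(grp)
        for modality in ("bp", "mp"):
            try:
                if metric == "auroc":
                    val = empirical_auroc(grp[f"{modality}_suspicion"], grp["label"])
                else:
                    s, sp = sens_spec(grp[f"{modality}_category"], grp["label"],
                                      grp["psad"], rule)
                    val = s if metric == "sensitivity" else sp
            except DegenerateInputError as exc:
                raise DegenerateInputError(f"reader {reader_id} ({modality}): {exc}") from exc
            rows[reader_id][modality] = val
    values = pd.DataFrame.from_dict(rows, orient="index")[["bp", "mp"]]
    values.index.name = "reader_id"
    info = study.readers.set_index("reader_id").loc[values.index, ["block_id", "expertise"]]
    return AccuracyTable(
        metric=metric, values=values, reader_info=info,
        n_cases=pd.Series(n_cases, name="n_cases"), rule=rule,
    )
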