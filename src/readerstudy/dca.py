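"""Decision curve analysis for MRI-directed biopsy strategies.

At a threshold probability ``p_t`` (the csPCa risk at which a patient or
clinician is willing to biopsy), the net benefit of a strategy with ``tp``
true positives and ``fp`` false positives among ``n`` patients is

    NB = tp/n - (fp/n) * p_t / (1 - p_t)

i.e. true positives per patient penalized by false positives weighted by
the odds of the threshold. "Treat all" biopsies everyone, "treat none"
no one (NB identically 0). Rule-based strategies binarize a modality's
patient-level PI-RADS category under a positivity rule; in a reader study
each reader contributes one confusion table per strategy and curves are
averaged over readers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .metrics import RULES, PositivityRule, apply_positivity_rule
from .study import Study

DEFAULT_THRESHOLDS = np.round(np.arange(0.05, 0.30 + 1e-9, 0.005), 4)


@dataclass(frozen=True)
class Strategy:
    """A biopsy-selection strategy: a (modality, rule) pair or a constant."""

    name: str
    kind: str = "rule"               # "rule" | "treat_all" | "treat_none"
    modality: str | None = None
    rule: PositivityRule | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("rule", "treat_all", "treat_none"):
            raise ValueError(f"unknown strategy kind {self.kind!r}")
        if self.kind == "rule" and (self.modality not in ("bp", "mp") or self.rule is None):
            raise ValueError(f"strategy {self.name!r}: rule-based strategies need a modality and a rule")


def default_strategies() -> list[Strategy]:
    """The six modality x rule pathways plus treat-all / treat-none."""
    out = []
    for modality in ("bp", "mp"):
        for rule_id, rule in RULES.items():
            out.append(Strategy(f"{modality}_{rule_id}", "rule", modality, rule))
    out.append(Strategy("treat_all", "treat_all"))
    out.append(Strategy("treat_none", "treat_none"))
    return out


def net_benefit(tp: float, fp: float, n: float, p_t: float) -> float:
    """Net benefit of a classification at threshold probability ``p_t``."""
    if not 0 < p_t < 1:
        raise ValueError(f"threshold probability must lie in (0, 1), got {p_t}")
    if tp + fp > n:
        raise ValueError("tp + fp cannot exceed n")
    return tp / n - (fp / n) * (p_t / (1.0 - p_t))


def net_reduction_interventions(nb_strategy: float, nb_all: float, p_t: float) -> float:
    """Net reduction in interventions per 100 patients vs treat-all."""
    if not 0 < p_t < 1:
        raise ValueError(f"threshold probability must lie in (0, 1), got {p_t}")
    return 100.0 * (nb_strategy - nb_all) / (p_t / (1.0 - p_t))


def exams_per_additional_case(delta_nb: float) -> float:
    """Examinations needed per additional true positive between strategies.

    The reciprocal of a net-benefit difference: e.g. a difference of 0.002
    means 1/0.002 = 500 examinations per extra case found.
    """
    if delta_nb == 0:
        warnings.warn("zero net-benefit difference: examinations per additional case is infinite")
        return math.inf
    return 1.0 / delta_nb


@dataclass
class DecisionCurve:
    """Tidy net-benefit curves: one row per (strategy, threshold)."""

    table: pd.DataFrame            # columns: strategy, threshold, net_benefit, net_reduction
    n_readers: int

    def nb(self, strategy: str, p_t: float) -> float:
        t = self.table
        row = t[(t["strategy"] == strategy) & (np.isclose(t["threshold"], p_t))]
        if row.empty:
            raise KeyError(f"no curve point for ({strategy!r}, {p_t})")
        return float(row["net_benefit"].iloc[0])

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["net_benefit"] = out["net_benefit"].round(4)
        out["net_reduction"] = out["net_reduction"].round(2)
        out.to_csv(path, index=False)


def _reader_counts(paired: pd.DataFrame, strategy: Strategy) -> pd.DataFrame:
    """Per-reader (tp, fp, n) confusion counts for one strategy."""
    df = paired
    if strategy.kind == "treat_all":
        calls = np.ones(len(df), dtype=bool)
    elif strategy.kind == "treat_none":
        calls = np.zeros(len(df), dtype=bool)
    else:
        cats = df[f"{strategy.modality}_category"].to_numpy()
        calls = np.asarray(apply_positivity_rule(cats, df["psad"].to_numpy(), strategy.rule))
    tmp = pd.DataFrame({
        "reader_id": df["reader_id"].to_numpy(),
        "tp": calls & (df["label"].to_numpy() == 1),
        "fp": calls & (df["label"].to_numpy() == 0),
    })
    counts = tmp.groupby("reader_id").agg(tp=("tp", "sum"), fp=("fp", "sum"))
    counts["n"] = df.groupby("reader_id").size()
    return counts


def decision_curve(study: Study, strategies: list[Strategy] | None = None,
                   thresholds=None) -> DecisionCurve:
    """Mean-over-readers net benefit for each strategy across thresholds."""
    strategies = strategies if strategies is not None else default_strategies()
    thresholds = DEFAULT_THRESHOLDS if thresholds is None else np.asarray(thresholds, dtype=float)
    paired = study.paired_readings(warn_unpaired=False)
    names = [s.name for s in strategies]
    if len(set(names)) != len(names):
        raise ValueError("duplicate strategy names")
    all_counts = {s.name: _reader_counts(paired, s) for s in strategies}
    treat_all_counts = _reader_counts(paired, Strategy("treat_all", "treat_all"))
    rows = []
    for s in strategies:
        counts = all_counts[s.name]
        for p_t in thresholds:
            odds = p_t / (1.0 - p_t)
            nb_readers = counts["tp"] / counts["n"] - odds * counts["fp"] / counts["n"]
            nb = float(nb_readers.mean())
            nb_all = float((treat_all_counts["tp"] / treat_all_counts["n"]
                            - odds * treat_all_counts["fp"] / treat_all_counts["n"]).mean())
            rows.append({
                "strategy": s.name, "threshold": float(p_t), "net_benefit": nb,
                "net_reduction": net_reduction_interventions(nb, nb_all, float(p_t)),
            })
    n_readers = paired["reader_id"].nunique()
    return DecisionCurve(table=pd.DataFrame(rows), n_readers=n_readers)


def plot_decision_curves(curve: DecisionCurve, path) -> None:
    """Plot net-benefit curves for all strategies to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for name, grp in curve.table.groupby("strategy"):
        ax.plot(grp["threshold"], grp["net_benefit"], label=name)
    ax.set_xlabel("threshold probability")
    ax.set_ylabel("net benefit")
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


class DecisionCurveAnalysis(BaseEstimator):
    """Estimator facade: fit a study, expose the fitted curve as ``curve_``."""

    def __init__(self, strategies=None, thresholds=None):
        self.strategies = strategies
        self.thresholds = thresholds

    def fit(self, study: Study) -> "DecisionCurveAnalysis":
        self.curve_ = decision_curve(study, self.strategies, self.thresholds)
        return self

    def transform(self, study: Study = None) -> pd.DataFrame:
        return self.curve_.table
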