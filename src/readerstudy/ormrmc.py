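"""Obuchowski-Rockette MRMC analysis of variance for paired split-plot studies.

The accuracy of reader ``j`` under modality ``i`` is modeled as

    theta_ij = mu + tau_i + R_j + (tau R)_ij + eps_ij

with an exchangeable error covariance structure estimated by the
leave-one-case-out jackknife:

* ``cov1`` - same reader, different modality,
* ``cov2`` - different readers, same modality,
* ``cov3`` - different readers, different modality,

all within a block; readers in different blocks share no cases, so
cross-block error covariances are structurally zero and blocks combine as
independent sub-studies (reader-count-weighted means, summed variances).

For two modalities the random-reader variance of the modality difference
in block ``b`` is

    Var_b = (2 / J_b) * (MS(T*R)_b + J_b * max(cov2_b - cov3_b, 0))

and noninferiority of the first modality at margin ``delta`` is tested
one-sided via ``T = (diff + delta) / se`` (H0: true difference <= -delta).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import DegenerateInputError, PairingError
from .metrics import (METRICS, RULES, AccuracyTable, PositivityRule,
                      apply_positivity_rule, per_reader_metric_table)
from .study import Study


# ---------------------------------------------------------------------------
# jackknife
# ---------------------------------------------------------------------------

def jackknife_accuracies(values, labels, metric: str,
                         psad=None, rule: PositivityRule | str | None = None) -> np.ndarray:
    """Leave-one-case-out accuracy values for one reader-modality.

    ``values`` are suspicion scores for ``metric="auroc"`` and patient
    categories for sensitivity/specificity. Element ``k`` is the metric
    recomputed with case ``k`` removed; the order follows the input case
    order. Requires >= 3 cases and both classes present after any single
    deletion.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    n = len(y)
    if n < 3:
        raise DegenerateInputError("jackknife needs at least 3 cases")
    n_pos = int(y.sum())
    n_neg = n - n_pos
    if min(n_pos, n_neg) < 1:
        raise DegenerateInputError("single-class input")
    if metric == "auroc" and min(n_pos, n_neg) < 2:
        bad = np.where(y == (1 if n_pos == 1 else 0))[0][0]
        raise DegenerateInputError(
            f"deleting case index {bad} would leave a single-class sample"
        )
    if metric == "auroc":
        return _auroc_jackknife(v, y)
    if metric in ("sensitivity", "specificity"):
        if rule is None:
            raise ValueError("sensitivity/specificity jackknife requires a rule")
        calls = np.asarray(apply_positivity_rule(v.astype(int), psad, rule), dtype=float)
        if metric == "sensitivity":
            if n_pos < 2:
                raise DegenerateInputError("deleting the only positive case leaves sensitivity undefined")
            tp = calls[y == 1].sum()
            out = np.where(y == 1, (tp - calls) / (n_pos - 1), tp / n_pos)
        else:
            if n_neg < 2:
                raise DegenerateInputError("deleting the only negative case leaves specificity undefined")
            tn = (1.0 - calls)[y == 0].sum()
            out = np.where(y == 0, (tn - (1.0 - calls)) / (n_neg - 1), tn / n_neg)
        return out.astype(float)
    raise ValueError(f"metric must be one of {METRICS}")


def _auroc_jackknife(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """O(n log n) exact leave-one-out Mann-Whitney AUROC."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    n_pos, n_neg = len(pos), len(neg)
    neg_sorted = np.sort(neg)
    pos_sorted = np.sort(pos)
    # per-positive credit against all negatives (ties half)
    lo = np.searchsorted(neg_sorted, pos, side="left")
    hi = np.searchsorted(neg_sorted, pos, side="right")
    w = lo + 0.5 * (hi - lo)
    # per-negative credit against all positives
    lo_p = np.searchsorted(pos_sorted, neg, side="right")
    hi_p = np.searchsorted(pos_sorted, neg, side="left")
    v = (n_pos - lo_p) + 0.5 * (lo_p - hi_p)
    u = w.sum()
    out = np.empty(len(y), dtype=float)
    out[y == 1] = (u - w) / ((n_pos - 1) * n_neg)
    out[y == 0] = (u - v) / (n_pos * (n_neg - 1))
    return out


# ---------------------------------------------------------------------------
# covariance components
# ---------------------------------------------------------------------------

@dataclass
class BlockComponents:
    """OR covariance components for one split-plot block (two modalities)."""

    block_id: str
    reader_ids: list[str]
    case_ids: list[str]
    theta: np.ndarray              # shape (2, J): rows bp, mp
    var_error: float
    cov1: float
    cov2: float
    cov3: float
    ms_tr: float
    ms_r: np.ndarray               # per-modality MS(R), shape (2,)
    cov2_by_modality: np.ndarray   # per-modality cov2, shape (2,)
    raw: dict = field(default_factory=dict)

    @property
    def n_readers(self) -> int:
        return len(self.reader_ids)

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)

    @property
    def diff(self) -> float:
        return float(self.theta[0].mean() - self.theta[1].mean())

    def var_diff(self, reader_effects: str = "random") -> float:
        """Variance of the modality-difference mean within this block."""
        j = self.n_readers
        pair = max(self.cov2 - self.cov3, 0.0)
        if reader_effects == "random":
            return (2.0 / j) * (self.ms_tr + j * pair)
        if reader_effects == "fixed":
            return (2.0 / j) * (max(self.var_error - self.cov1, 0.0) + (j - 1) * pair)
        raise ValueError("reader_effects must be 'random' or 'fixed'")

    def var_mean(self, modality_index: int, reader_effects: str = "random") -> float:
        """Variance of one modality's accuracy mean within this block."""
        j = self.n_readers
        c2 = max(self.cov2_by_modality[modality_index], 0.0)
        if reader_effects == "random":
            return (self.ms_r[modality_index] + (j - 1) * c2) / j
        return (self.var_error + (j - 1) * c2) / j

    def ddf(self) -> float:
        """Hillis denominator degrees of freedom for the difference test."""
        j = self.n_readers
        num = (self.ms_tr + j * max(self.cov2 - self.cov3, 0.0)) ** 2
        den = self.ms_tr ** 2 / (j - 1)
        if den == 0:
            return np.inf
        return num / den


@dataclass
class ORComponents:
    """Per-block components plus the paired accuracy table they came from."""

    blocks: list[BlockComponents]
    metric: str
    rule: PositivityRule | None = None

    @property
    def n_readers(self) -> int:
        return sum(b.n_readers for b in self.blocks)


def compute_jackknife_vectors(study: Study, metric: str,
                              rule: PositivityRule | str | None = None,
                              subgroup: str | None = None) -> dict[str, dict]:
    """Leave-one-case-out accuracy vectors for every (modality, reader).

    Returns ``{block_id: {"case_ids": [...], "reader_ids": [...],
    "loo": array (2, J_b, n_b)}}`` with modality axis ordered (bp, mp) and
    the case axis aligned to ``case_ids``.
    """
    if isinstance(rule, str):
        rule = RULES[rule]
    paired = study.paired_readings(warn_unpaired=False)
    if subgroup and subgroup != "all":
        paired = paired[paired["expertise"] == subgroup]
    out: dict[str, dict] = {}
    for block_id, block_df in paired.groupby("block_id", sort=True):
        case_ids = sorted(block_df["case_id"].unique())
        reader_ids = sorted(block_df["reader_id"].unique())
        case_pos = {c: k for k, c in enumerate(case_ids)}
        loo = np.full((2, len(reader_ids), len(case_ids)), np.nan)
        for jr, reader_id in enumerate(reader_ids):
            grp = block_df[block_df["reader_id"] == reader_id]
            if len(grp) != len(case_ids):
                raise PairingError(
                    f"reader {reader_id} read {len(grp)} of {len(case_ids)} cases in"
                    f" block {block_id}; jackknife vectors require a common case list"
                )
            grp = grp.set_index("case_id").loc[case_ids]
            for im, modality in enumerate(("bp", "mp")):
                col = f"{modality}_suspicion" if metric == "auroc" else f"{modality}_category"
                vec = jackknife_accuracies(grp[col].to_numpy(), grp["label"].to_numpy(),
                                           metric, psad=grp["psad"].to_numpy(), rule=rule)
                loo[im, jr, [case_pos[c] for c in grp.index]] = vec
        out[block_id] = {"case_ids": case_ids, "reader_ids": reader_ids, "loo": loo}
    return out


def covariance_components(table: AccuracyTable, jackknife: dict[str, dict],
                          metric: str | None = None) -> ORComponents:
    """Estimate Cov1-Cov3, error variance and MS(T*R) per block.

    Pairwise jackknife covariances use the standard (n-1)/n scaling and are
    averaged over qualifying (modality, reader) pairs within each block;
    negative component means are truncated to zero (raw values kept in
    ``raw``).
    """
    metric = metric or table.metric
    blocks = []
    for block_id, jk in sorted(jackknife.items()):
        reader_ids = jk["reader_ids"]
        loo = jk["loo"]
        n_mod, j, n = loo.shape
        if j < 2:
            warnings.warn(f"block {block_id} has {j} reader(s); excluded from OR analysis")
            continue
        missing = [r for r in reader_ids if r not in table.values.index]
        if missing:
            raise PairingError(f"block {block_id}: readers {missing} missing from the accuracy table")
        theta = table.values.loc[reader_ids, ["bp", "mp"]].to_numpy().T  # (2, J)
        centered = loo - loo.mean(axis=2, keepdims=True)
        m = centered.reshape(n_mod * j, n)
        cmat = (n - 1) / n * (m @ m.T)
        idx = np.arange(n_mod * j)
        mod_of = idx // j
        rdr_of = idx % j
        same_mod = mod_of[:, None] == mod_of[None, :]
        same_rdr = rdr_of[:, None] == rdr_of[None, :]
        diag = np.eye(n_mod * j, dtype=bool)
        var_error = float(cmat[diag].mean())
        raw_cov1 = float(cmat[~same_mod & same_rdr].mean())
        raw_cov2 = float(cmat[same_mod & ~same_rdr].mean())
        raw_cov3 = float(cmat[~same_mod & ~same_rdr].mean())
        cov2_by_mod = np.array([
            float(cmat[same_mod & ~same_rdr & (mod_of[:, None] == im)].mean())
            for im in range(n_mod)
        ])
        # two-way interaction mean square from the theta table
        resid = (theta - theta.mean(axis=1, keepdims=True)
                 - theta.mean(axis=0, keepdims=True) + theta.mean())
        ms_tr = float((resid ** 2).sum() / ((n_mod - 1) * (j - 1)))
        ms_r = ((theta - theta.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) / (j - 1)
        clip = lambda x: float(np.clip(x, 0.0, var_error))
        blocks.append(BlockComponents(
            block_id=block_id, reader_ids=list(reader_ids), case_ids=list(jk["case_ids"]),
            theta=theta, var_error=var_error,
            cov1=clip(raw_cov1), cov2=clip(raw_cov2), cov3=clip(raw_cov3),
            ms_tr=ms_tr, ms_r=ms_r.astype(float),
            cov2_by_modality=np.clip(cov2_by_mod, 0.0, var_error),
            raw={"cov1": raw_cov1, "cov2": raw_cov2, "cov3": raw_cov3},
        ))
    if not blocks:
        raise DegenerateInputError("no block with >= 2 readers")
    return ORComponents(blocks=blocks, metric=metric, rule=table.rule)


def estimate_components(study: Study, metric: str,
                        rule: PositivityRule | str | None = None,
                        subgroup: str | None = None) -> ORComponents:
    """Accuracy table + jackknife + covariance components in one call."""
    table = per_reader_metric_table(study, metric, rule=rule, subgroup=subgroup)
    jk = compute_jackknife_vectors(study, metric, rule=rule, subgroup=subgroup)
    return covariance_components(table, jk)


# ---------------------------------------------------------------------------
# pooling and testing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ORResult:
    """Pooled OR estimates and the noninferiority (or difference) test."""

    metric: str
    mean_bp: float
    mean_mp: float
    diff: float
    se_diff: float
    ci_low: float
    ci_high: float
    ddf: float
    p_value: float
    margin: float
    alpha: float
    alternative: str
    n_readers: int
    ci_mean_bp: tuple[float, float]
    ci_mean_mp: tuple[float, float]

    @property
    def reject(self) -> bool:
        return self.p_value <= self.alpha

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "metric", "mean_bp", "mean_mp", "diff", "se_diff", "ci_low", "ci_high",
            "ddf", "p_value", "margin", "alpha", "alternative", "n_readers")}
        d["ci_mean_bp_low"], d["ci_mean_bp_high"] = self.ci_mean_bp
        d["ci_mean_mp_low"], d["ci_mean_mp_high"] = self.ci_mean_mp
        return d


def pool_blocks(components: ORComponents, reader_effects: str = "random") -> dict:
    """Combine independent blocks: reader-count-weighted means, summed variances."""
    blocks = components.blocks
    j_total = sum(b.n_readers for b in blocks)
    w = np.array([b.n_readers / j_total for b in blocks])
    means = np.array([[b.theta[i].mean() for b in blocks] for i in range(2)])  # (2, B)
    mean_bp, mean_mp = (means * w).sum(axis=1)
    diff = float(mean_bp - mean_mp)
    var_b = np.array([b.var_diff(reader_effects) for b in blocks])
    var_diff = float((w ** 2 * var_b).sum())
    var_means = [float((w ** 2 * np.array([b.var_mean(i, reader_effects) for b in blocks])).sum())
                 for i in range(2)]
    # Satterthwaite combination of per-block Hillis df
    ddf_b = np.array([b.ddf() for b in blocks])
    contrib = (w ** 4) * (var_b ** 2) / ddf_b
    ddf = float(var_diff ** 2 / contrib.sum()) if var_diff > 0 and contrib.sum() > 0 else np.inf
    return {
        "mean_bp": float(mean_bp), "mean_mp": float(mean_mp), "diff": diff,
        "var_diff": var_diff, "var_mean_bp": var_means[0], "var_mean_mp": var_means[1],
        "ddf": ddf, "n_readers": j_total,
    }


def or_test(components: ORComponents, margin: float = 0.05, alpha: float = 0.05,
            alternative: str = "noninferiority", interval: str = "wald",
            ci_level: float = 0.95, reader_effects: str = "random") -> ORResult:
    """Pooled modality means, Wald CI for the difference, and the test.

    ``alternative='noninferiority'`` tests H0: true difference <= -margin
    (one-sided; the accuracy metric is oriented so larger is better and the
    difference is first minus second modality). ``interval`` selects the
    normal ("wald") or t ("t", Hillis denominator df) reference.
    """
    pooled = pool_blocks(components, reader_effects)
    diff, se = pooled["diff"], float(np.sqrt(pooled["var_diff"]))
    ddf = pooled["ddf"] if interval == "t" else np.inf
    dist = stats.t(ddf) if np.isfinite(ddf) else stats.norm()
    q = dist.ppf(1 - (1 - ci_level) / 2)

    if se == 0.0:
        warnings.warn("zero standard error for the modality difference; degenerate data")
        if alternative == "noninferiority" and np.isclose(diff, -margin):
            p = 0.5
        elif alternative == "noninferiority":
            p = 0.0 if diff > -margin else 1.0
        else:
            p = 0.0 if diff != 0 else 1.0
        ci_low = ci_high = diff
    else:
        ci_low, ci_high = diff - q * se, diff + q * se
        if alternative == "noninferiority":
            p = float(dist.sf((diff + margin) / se))
        elif alternative == "superiority":
            p = float(dist.sf(diff / se))
        elif alternative == "two_sided":
            p = float(2 * dist.sf(abs(diff) / se))
        else:
            raise ValueError("alternative must be noninferiority, superiority or two_sided")

    def mean_ci(mean, var):
        s = float(np.sqrt(var))
        return (mean - q * s, mean + q * s)

    return ORResult(
        metric=components.metric,
        mean_bp=pooled["mean_bp"], mean_mp=pooled["mean_mp"], diff=diff, se_diff=se,
        ci_low=float(ci_low), ci_high=float(ci_high), ddf=float(ddf), p_value=p,
        margin=margin, alpha=alpha, alternative=alternative,
        n_readers=pooled["n_readers"],
        ci_mean_bp=mean_ci(pooled["mean_bp"], pooled["var_mean_bp"]),
        ci_mean_mp=mean_ci(pooled["mean_mp"], pooled["var_mean_mp"]),
    )


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class ObuchowskiRockette(BaseEstimator):
    """Obuchowski-Rockette MRMC estimator for a paired split-plot study.

    Parameters
    ----------
    metric : {"auroc", "sensitivity", "specificity"}
    rule : positivity rule id or PositivityRule, required for sens/spec.
    margin : noninferiority margin on the accuracy scale (default 0.05).
    alpha : one-sided significance level for the test (default 0.05).
    alternative : {"noninferiority", "superiority", "two_sided"}.
    interval : {"wald", "t"} - normal-quantile Wald intervals (default) or
        t intervals with Hillis denominator degrees of freedom.
    reader_effects : {"random", "fixed"} - generalize to the reader
        population (default) or condition on the observed readers.
    ci_level : two-sided confidence level for reported intervals.

    After ``fit`` the estimates are available as ``result_`` (an
    :class:`ORResult`) plus the scalar conveniences ``mean_bp_``,
    ``mean_mp_``, ``diff_``, ``se_``, ``ci_``, ``p_value_`` and the
    covariance diagnostics ``components_``.
    """

    def __init__(self, metric: str = "auroc", rule=None, margin: float = 0.05,
                 alpha: float = 0.05, alternative: str = "noninferiority",
                 interval: str = "wald", reader_effects: str = "random",
                 ci_level: float = 0.95):
        self.metric = metric
        self.rule = rule
        self.margin = margin
        self.alpha = alpha
        self.alternative = alternative
        self.interval = interval
        self.reader_effects = reader_effects
        self.ci_level = ci_level

    def fit(self, study: Study, subgroup: str | None = None) -> "ObuchowskiRockette":
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        self.table_ = per_reader_metric_table(study, self.metric, rule=self.rule,
                                              subgroup=subgroup)
        jk = compute_jackknife_vectors(study, self.metric, rule=self.rule,
                                       subgroup=subgroup)
        self.components_ = covariance_components(self.table_, jk)
        self.result_ = or_test(
            self.components_, margin=self.margin, alpha=self.alpha,
            alternative=self.alternative, interval=self.interval,
            ci_level=self.ci_level, reader_effects=self.reader_effects,
        )
        r = self.result_
        self.mean_bp_, self.mean_mp_ = r.mean_bp, r.mean_mp
        self.diff_, self.se_ = r.diff, r.se_diff
        self.ci_ = (r.ci_low, r.ci_high)
        self.p_value_ = r.p_value
        self.n_readers_ = r.n_readers
        return self
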