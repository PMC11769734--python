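"""Concordance flow accounting, result tables and run manifests.

The flow table cross-tabulates each paired read's patient-level category
under bpMRI (rows) against mpMRI (columns); the diagonal holds concordant
reads, cells above the diagonal are upgrades after seeing contrast imaging,
cells below are downgrades. Each cell also carries its csPCa fraction.
All rounding happens at the reporting boundary; internal values keep full
precision.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dca import DecisionCurve
from .errors import PairingError
from .ormrmc import ORResult
from .study import CATEGORIES, Study

logger = logging.getLogger(__name__)


@dataclass
class FlowTable:
    """4x4 bp-to-mp category transition counts over paired reads."""

    counts: pd.DataFrame          # index: bp category, columns: mp category
    cspca_fraction: pd.DataFrame  # same shape; NaN where the cell is empty

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def n_concordant(self) -> int:
        return int(np.trace(self.counts.to_numpy()))

    @property
    def concordant_fraction(self) -> float:
        return self.n_concordant / self.total

    def transition_count(self, bp_category: int, mp_category: int) -> int:
        return int(self.counts.loc[bp_category, mp_category])

    def transition_fraction(self, bp_category: int, mp_category: int) -> float:
        return self.transition_count(bp_category, mp_category) / self.total

    def to_csv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "bp_category"
        out.to_csv(path)


def concordance_flow(paired: pd.DataFrame | Study) -> FlowTable:
    """Build the bp-to-mp flow table from paired readings.

    Accepts a :class:`Study` or a paired-readings frame with
    ``bp_category``/``mp_category`` and ``label`` columns.
    """
    if isinstance(paired, Study):
        unpaired = paired.readings.groupby(["reader_id", "case_id"])["modality"].nunique()
        offenders = unpaired[unpaired < 2]
        if len(offenders):
            raise PairingError(
                f"{len(offenders)} assessment(s) present under one modality only,"
                f" e.g. {list(offenders.index[:3])}"
            )
        paired = paired.paired_readings(warn_unpaired=False)
    cats = list(CATEGORIES)
    counts = pd.DataFrame(0, index=cats, columns=cats, dtype=int)
    cs = pd.DataFrame(np.nan, index=cats, columns=cats, dtype=float)
    grouped = paired.groupby(["bp_category", "mp_category"])
    for (b, m), grp in grouped:
        counts.loc[b, m] = len(grp)
        cs.loc[b, m] = float(grp["label"].mean())
    return FlowTable(counts=counts, cspca_fraction=cs)


def or_results_table(results: dict[tuple[str, str | None, str], ORResult]) -> pd.DataFrame:
    """Tidy frame of OR results keyed by (metric, rule, subgroup)."""
    rows = []
    for (metric, rule, subgroup), res in results.items():
        d = res.to_dict()
        d.update({"metric": metric, "rule": rule or "", "subgroup": subgroup})
        rows.append(d)
    cols = ["metric", "rule", "subgroup", "n_readers", "mean_bp", "mean_mp",
            "ci_mean_bp_low", "ci_mean_bp_high", "ci_mean_mp_low", "ci_mean_mp_high",
            "diff", "se_diff", "ci_low", "ci_high", "ddf", "p_value", "margin",
            "alpha", "alternative"]
    return pd.DataFrame(rows)[cols]


def _round_results(df: pd.DataFrame) -> pd.DataFrame:
    """Percent-style rounding (1 decimal on the percent scale) for reports."""
    out = df.copy()
    for c in ("mean_bp", "mean_mp", "ci_mean_bp_low", "ci_mean_bp_high",
              "ci_mean_mp_low", "ci_mean_mp_high", "diff", "ci_low", "ci_high"):
        out[c] = (100 * out[c]).round(1)
    out["se_diff"] = (100 * out["se_diff"]).round(2)
    out["p_value"] = out["p_value"].round(4)
    out["ddf"] = out["ddf"].round(1)
    return out


def write_report(out_dir, *, study: Study | None = None,
                 or_results: dict | None = None,
                 flow: FlowTable | None = None,
                 curve: DecisionCurve | None = None,
                 config_digest: str | None = None,
                 seed: int | None = None) -> Path:
    """Emit result tables plus a JSON run manifest; gaps are flagged, not fatal."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "config_sha256": config_digest, "stages": {}}
    import readerstudy
    manifest["versions"] = {
        "readerstudy": readerstudy.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    if study is not None:
        manifest["stages"]["study"] = {
            "n_readings": int(len(study.readings)),
            "n_cases": int(len(study.cases)),
            "n_readers": int(len(study.readers)),
            "n_blocks": len(study.design.blocks),
        }
    if or_results:
        table = or_results_table(or_results)
        table.to_csv(out / "or_results_full_precision.csv", index=False)
        _round_results(table).to_csv(out / "or_results.csv", index=False)
        manifest["stages"]["analysis"] = {"n_rows": int(len(table))}
    else:
        manifest["stages"]["analysis"] = "not run"
    if flow is not None:
        flow.to_csv(out / "flow_table.csv")
        manifest["stages"]["flow"] = {
            "total": flow.total,
            "concordant_pct": round(100 * flow.concordant_fraction, 1),
        }
    else:
        manifest["stages"]["flow"] = "not run"
    if curve is not None:
        curve.to_csv(out / "decision_curve.csv")
        manifest["stages"]["dca"] = {"n_rows": int(len(curve.table))}
    else:
        manifest["stages"]["dca"] = "not run"
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("report written to %s", out)
    return path


def config_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
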