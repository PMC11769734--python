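"""Data model, CSV I/O and validation for paired split-plot reader studies.

A study consists of three long-format tables:

``readings``
    one row per reader x case x modality, carrying the patient-level
    PI-RADS category (2 encodes "PI-RADS <=2 / negative exam"), a 0-100
    suspicion score and optionally the lesion-level PI-RADS categories.
``cases``
    the case manifest: disease label (1 = clinically significant prostate
    cancer, Gleason grade group >=2), grade group, center, block and the
    clinical covariates (PSA density, PSA, prostate volume, age).
``readers``
    the reader manifest: block membership and expertise group.

Readers and cases are partitioned into blocks (split-plot design): every
reader interprets exactly the cases of its own block, under both the
biparametric ("bp") and multiparametric ("mp") MRI protocol.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CrossReferenceError, IntegrityError, PairingError, SchemaError

logger = logging.getLogger(__name__)

MODALITIES: tuple[str, str] = ("bp", "mp")
CATEGORIES: tuple[int, ...] = (2, 3, 4, 5)
LESION_CATEGORIES: tuple[int, ...] = (3, 4, 5)
EXPERTISE_LEVELS: tuple[str, str] = ("expert", "nonexpert")

READINGS_COLUMNS = ["reader_id", "case_id", "modality", "patient_pirads", "suspicion", "lesions"]
CASES_COLUMNS = ["case_id", "center", "block_id", "label", "gg", "psad", "psa", "volume", "age"]
READERS_COLUMNS = ["reader_id", "block_id", "expertise"]


# ---------------------------------------------------------------------------
# record-level types
# ---------------------------------------------------------------------------

def aggregate_patient_category(lesion_categories: Sequence[int]) -> int:
    """Patient-level PI-RADS category: the highest lesion category.

    An exam with no suspicious lesions is negative and reported as
    category 2 (the "PI-RADS <=2" bucket). Lesion categories must lie in
    {3, 4, 5}: readers only assign PI-RADS 3-5 to suspicious lesions.
    """
    cats = list(lesion_categories)
    if not cats:
        return 2
    for c in cats:
        if c not in LESION_CATEGORIES:
            raise ValueError(f"lesion category {c!r} outside {{3, 4, 5}}")
    return max(cats)


@dataclass(frozen=True)
class CaseRecord:
    """One case in the cohort, with its reference-standard label."""

    case_id: str
    center: str
    block_id: str
    label: int
    gg: int
    psad: float | None = None
    psa: float | None = None
    volume: float | None = None
    age: float | None = None

    def __post_init__(self) -> None:
        if self.gg not in range(6):
            raise ValueError(f"case {self.case_id}: gg must be 0-5, got {self.gg}")
        if self.label != int(self.gg >= 2):
            raise ValueError(
                f"case {self.case_id}: label {self.label} inconsistent with gg {self.gg}"
                " (label must be 1 iff gg >= 2)"
            )
        for name in ("psad", "psa", "volume", "age"):
            v = getattr(self, name)
            if v is not None and not np.isnan(v) and v < 0:
                raise ValueError(f"case {self.case_id}: {name} must be nonnegative, got {v}")


@dataclass(frozen=True)
class ReaderRecord:
    """One reader, with block membership and ESUR/ESUI expertise group."""

    reader_id: str
    block_id: str
    expertise: str

    def __post_init__(self) -> None:
        if self.expertise not in EXPERTISE_LEVELS:
            raise ValueError(
                f"reader {self.reader_id}: expertise must be one of {EXPERTISE_LEVELS},"
                f" got {self.expertise!r}"
            )


@dataclass(frozen=True)
class ReadingRecord:
    """One reader's interpretation of one case under one modality."""

    reader_id: str
    case_id: str
    modality: str
    patient_category: int
    suspicion: int
    lesion_categories: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        ident = f"reading ({self.reader_id}, {self.case_id}, {self.modality})"
        if self.modality not in MODALITIES:
            raise ValueError(f"{ident}: modality must be in {MODALITIES}")
        if self.patient_category not in CATEGORIES:
            raise ValueError(f"{ident}: patient category must be in {CATEGORIES}")
        if not 0 <= self.suspicion <= 100:
            raise ValueError(f"{ident}: suspicion must lie in [0, 100], got {self.suspicion}")
        if self.lesion_categories is not None:
            expected = aggregate_patient_category(self.lesion_categories)
            if expected != self.patient_category:
                raise ValueError(
                    f"{ident}: patient category {self.patient_category} does not equal the"
                    f" aggregate of lesion categories {self.lesion_categories} ({expected})"
                )


@dataclass(frozen=True)
class StudyDesign:
    """Split-plot allocation: block -> (reader ids, case ids)."""

    blocks: Mapping[str, tuple[frozenset[str], frozenset[str]]]
    modalities: tuple[str, str] = MODALITIES

    @classmethod
    def from_manifests(cls, cases: pd.DataFrame, readers: pd.DataFrame) -> "StudyDesign":
        blocks = {}
        block_ids = sorted(set(cases["block_id"]) | set(readers["block_id"]))
        for b in block_ids:
            r = frozenset(readers.loc[readers["block_id"] == b, "reader_id"])
            c = frozenset(cases.loc[cases["block_id"] == b, "case_id"])
            blocks[b] = (r, c)
        return cls(blocks=blocks)

    @property
    def block_ids(self) -> list[str]:
        return sorted(self.blocks)

    def readers_of(self, block_id: str) -> frozenset[str]:
        return self.blocks[block_id][0]

    def cases_of(self, block_id: str) -> frozenset[str]:
        return self.blocks[block_id][1]


# ---------------------------------------------------------------------------
# the study container
# ---------------------------------------------------------------------------

@dataclass
class Study:
    """In-memory paired reader study: three tables plus the inferred design."""

    readings: pd.DataFrame
    cases: pd.DataFrame
    readers: pd.DataFrame
    design: StudyDesign = field(init=False)

    def __post_init__(self) -> None:
        self.readings = _normalize_readings(self.readings)
        self.cases = _normalize_cases(self.cases)
        self.readers = _normalize_readers(self.readers)
        _validate_study(self.readings, self.cases, self.readers)
        self.design = StudyDesign.from_manifests(self.cases, self.readers)

    # -- record views -------------------------------------------------------
    def reading_records(self) -> set[ReadingRecord]:
        out = set()
        for row in self.readings.itertuples(index=False):
            lesions = _parse_lesions(row.lesions)
            out.add(
                ReadingRecord(
                    row.reader_id, row.case_id, row.modality,
                    int(row.patient_pirads), int(row.suspicion), lesions,
                )
            )
        return out

    def case_records(self) -> set[CaseRecord]:
        def opt(v):
            return None if pd.isna(v) else float(v)

        return {
            CaseRecord(r.case_id, r.center, r.block_id, int(r.label), int(r.gg),
                       opt(r.psad), opt(r.psa), opt(r.volume), opt(r.age))
            for r in self.cases.itertuples(index=False)
        }

    def reader_records(self) -> set[ReaderRecord]:
        return {
            ReaderRecord(r.reader_id, r.block_id, r.expertise)
            for r in self.readers.itertuples(index=False)
        }

    # -- paired view --------------------------------------------------------
    def paired_readings(self, warn_unpaired: bool = True) -> pd.DataFrame:
        """Wide table of complete (reader, case) pairs.

        Columns: reader_id, case_id, bp_category, mp_category, bp_suspicion,
        mp_suspicion, plus the case label, psad and the reader block and
        expertise. Assessments missing one modality are dropped (pairing
        contract); a warning reports how many.
        """
        wide = self.readings.pivot_table(
            index=["reader_id", "case_id"], columns="modality",
            values=["patient_pirads", "suspicion"], aggfunc="first",
        )
        wide.columns = [f"{m}_{'category' if v == 'patient_pirads' else 'suspicion'}"
                        for v, m in wide.columns]
        complete = wide.dropna()
        n_dropped = len(wide) - len(complete)
        if n_dropped and warn_unpaired:
            warnings.warn(f"dropped {n_dropped} unpaired (reader, case) assessments")
        out = complete.reset_index().astype(
            {c: int for c in complete.columns if c.endswith(("category", "suspicion"))}
        )
        out = out.merge(self.cases[["case_id", "label", "psad"]], on="case_id")
        out = out.merge(self.readers[["reader_id", "block_id", "expertise"]], on="reader_id")
        return out

    def subset_readers(self, reader_ids: Iterable[str]) -> "Study":
        """Restrict the study to a subset of readers (e.g. an expertise group)."""
        keep = set(reader_ids)
        return Study(
            readings=self.readings[self.readings["reader_id"].isin(keep)].copy(),
            cases=self.cases.copy(),
            readers=self.readers[self.readers["reader_id"].isin(keep)].copy(),
        )

    # -- I/O ----------------------------------------------------------------
    def write(self, out_dir: str | Path) -> dict[str, Path]:
        return write_study(self, out_dir)


# ---------------------------------------------------------------------------
# normalization & validation
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: Sequence[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing column(s) {', '.join(missing)}")


def _normalize_readings(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "lesions" not in df.columns:
        df["lesions"] = ""
    _require_columns(df, READINGS_COLUMNS[:-1], "readings")
    df = df[READINGS_COLUMNS]
    df["reader_id"] = df["reader_id"].astype(str)
    df["case_id"] = df["case_id"].astype(str)
    df["modality"] = df["modality"].astype(str)
    try:
        df["patient_pirads"] = df["patient_pirads"].astype(int)
        df["suspicion"] = df["suspicion"].astype(int)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"readings: non-numeric category/suspicion value ({exc})") from exc
    df["lesions"] = df["lesions"].fillna("").astype(str)
    bad = ~df["modality"].isin(MODALITIES)
    if bad.any():
        raise SchemaError(f"readings: unknown modality value(s) {sorted(df.loc[bad, 'modality'].unique())}")
    if (~df["patient_pirads"].isin(CATEGORIES)).any():
        raise SchemaError("readings: patient_pirads outside {2, 3, 4, 5}")
    if ((df["suspicion"] < 0) | (df["suspicion"] > 100)).any():
        raise SchemaError("readings: suspicion outside [0, 100]")
    return df.sort_values(["reader_id", "case_id", "modality"], kind="stable").reset_index(drop=True)


def _normalize_cases(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, ["case_id", "center", "block_id", "label", "gg"], "cases")
    df = df.copy()
    for c in ("psad", "psa", "volume", "age"):
        if c not in df.columns:
            df[c] = np.nan
    df = df[CASES_COLUMNS]
    for c in ("case_id", "center", "block_id"):
        df[c] = df[c].astype(str)
    df["label"] = df["label"].astype(int)
    df["gg"] = df["gg"].astype(int)
    for c in ("psad", "psa", "volume", "age"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    if (~df["label"].isin((0, 1))).any() or (~df["gg"].isin(range(6))).any():
        raise SchemaError("cases: label must be 0/1 and gg in 0..5")
    if (df["label"] != (df["gg"] >= 2).astype(int)).any():
        bad = df.loc[df["label"] != (df["gg"] >= 2).astype(int), "case_id"].tolist()
        raise IntegrityError(f"cases: label/gg mismatch (label==1 iff gg>=2) for {bad[:5]}")
    neg = df[["psad", "psa", "volume", "age"]].lt(0).any(axis=1)
    if neg.any():
        raise SchemaError(f"cases: negative covariate(s) for {df.loc[neg, 'case_id'].tolist()[:5]}")
    return df.sort_values("case_id", kind="stable").reset_index(drop=True)


def _normalize_readers(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, READERS_COLUMNS, "readers")
    df = df[READERS_COLUMNS].copy()
    for c in READERS_COLUMNS:
        df[c] = df[c].astype(str)
    bad = ~df["expertise"].isin(EXPERTISE_LEVELS)
    if bad.any():
        raise SchemaError(f"readers: unknown expertise value(s) {sorted(df.loc[bad, 'expertise'].unique())}")
    return df.sort_values("reader_id", kind="stable").reset_index(drop=True)


def _parse_lesions(cell: str) -> tuple[int, ...] | None:
    cell = (cell or "").strip()
    if not cell:
        return ()
    try:
        return tuple(int(tok) for tok in cell.split(";"))
    except ValueError as exc:
        raise SchemaError(f"readings: malformed lesions cell {cell!r}") from exc


def _validate_study(readings: pd.DataFrame, cases: pd.DataFrame, readers: pd.DataFrame) -> None:
    if cases["case_id"].duplicated().any():
        raise IntegrityError("cases: duplicate case_id")
    if readers["reader_id"].duplicated().any():
        raise IntegrityError("readers: duplicate reader_id")
    dup = readings.duplicated(["reader_id", "case_id", "modality"])
    if dup.any():
        rows = readings.loc[dup, ["reader_id", "case_id", "modality"]].head().values.tolist()
        raise IntegrityError(f"readings: duplicate (reader, case, modality) rows, e.g. {rows}")
    unknown_cases = set(readings["case_id"]) - set(cases["case_id"])
    if unknown_cases:
        raise CrossReferenceError(f"readings reference unknown case(s): {sorted(unknown_cases)[:5]}")
    unknown_readers = set(readings["reader_id"]) - set(readers["reader_id"])
    if unknown_readers:
        raise CrossReferenceError(f"readings reference unknown reader(s): {sorted(unknown_readers)[:5]}")
    # lesion-aggregation invariant per row
    for row in readings.itertuples(index=False):
        lesions = _parse_lesions(row.lesions)
        if lesions:
            agg = aggregate_patient_category(lesions)
            if agg != row.patient_pirads:
                raise IntegrityError(
                    f"reading ({row.reader_id}, {row.case_id}, {row.modality}):"
                    f" patient_pirads {row.patient_pirads} != max(lesions) {agg}"
                )
    # split-plot contract: a reader only reads cases of its own block
    merged = readings.merge(readers[["reader_id", "block_id"]], on="reader_id")
    merged = merged.merge(cases[["case_id", "block_id"]], on="case_id", suffixes=("_reader", "_case"))
    off_block = merged["block_id_reader"] != merged["block_id_case"]
    if off_block.any():
        rows = merged.loc[off_block, ["reader_id", "case_id"]].head().values.tolist()
        raise IntegrityError(f"readings cross block boundaries, e.g. {rows}")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def load_study(readings_path: str | Path, cases_path: str | Path,
               readers_path: str | Path) -> Study:
    """Load and validate a study from its three CSV files."""
    for p in (readings_path, cases_path, readers_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    readings = pd.read_csv(readings_path, dtype={"reader_id": str, "case_id": str, "lesions": str})
    cases = pd.read_csv(cases_path, dtype={"case_id": str, "center": str, "block_id": str})
    readers = pd.read_csv(readers_path, dtype=str)
    study = Study(readings=readings, cases=cases, readers=readers)
    logger.info(
        "loaded study: %d readings, %d cases, %d readers, %d blocks",
        len(study.readings), len(study.cases), len(study.readers), len(study.design.blocks),
    )
    return study


def write_study(study: Study, out_dir: str | Path) -> dict[str, Path]:
    """Write the three study tables as CSV; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "readings": out / "readings.csv",
        "cases": out / "cases.csv",
        "readers": out / "readers.csv",
    }
    study.readings.to_csv(paths["readings"], index=False)
    study.cases.to_csv(paths["cases"], index=False)
    study.readers.to_csv(paths["readers"], index=False)
    return paths


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExclusionReport:
    """Bookkeeping for noncompliant-assessment exclusion.

    Counts are patient assessments, i.e. (reader, case) pairs; dropping an
    assessment removes both modality rows so pairing is preserved.
    """

    n_assessments: int
    n_excluded: int

    @property
    def n_retained(self) -> int:
        return self.n_assessments - self.n_excluded

    @property
    def retained_pct(self) -> float:
        if self.n_assessments == 0:
            return 0.0
        return round(100.0 * self.n_retained / self.n_assessments, 1)


def exclude_noncompliant(
    readings: pd.DataFrame,
    exclusion_list: Iterable[tuple[str, str]],
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop noncompliant (reader, case) assessments from both modalities."""
    pairs = set(readings.groupby(["reader_id", "case_id"]).groups)
    requested = {(str(r), str(c)) for r, c in exclusion_list}
    unknown = requested - pairs
    if unknown:
        warnings.warn(f"{len(unknown)} exclusion pair(s) not present in readings, e.g. {sorted(unknown)[:3]}")
    excluded = requested & pairs
    key = list(zip(readings["reader_id"], readings["case_id"]))
    mask = np.array([k not in excluded for k in key])
    retained = readings[mask].reset_index(drop=True)
    report = ExclusionReport(n_assessments=len(pairs), n_excluded=len(excluded))
    logger.info(
        "exclusions: %d of %d assessments dropped (%.1f%% retained)",
        report.n_excluded, report.n_assessments, report.retained_pct,
    )
    return retained, report
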