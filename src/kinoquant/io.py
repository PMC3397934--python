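"""Readers and writers for the pipeline's interchange formats.

Formats
-------
* MGF (Mascot Generic Format) spectra, read through :mod:`pyteomics.mgf`
  after a light structural validation that can name the offending line.
* Peptide identification / evidence tables: tab-separated, UTF-8, ``.``
  decimals on output.  Decimal commas and the typographic minus sign (as
  found in transcribed publication tables) are accepted on input.
* Truth tables from the simulator and differential-call result tables.

The evidence table is the pipeline's canonical interchange object: a
:class:`pandas.DataFrame` with columns ``spectrum_id, peptide_sequence,
protein_id, score, is_unique, intensity_114 .. intensity_117, stage``
where ``stage`` is one of ``raw``, ``corrected``, ``normalized``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mgf as _pymgf

from . import constants as C
from .errors import ParseError, SchemaError, ValidationError

EVIDENCE_STAGES = ("raw", "corrected", "normalized")
INTENSITY_COLS = tuple(f"intensity_{ch}" for ch in C.CHANNELS)
ID_COLUMNS = ("spectrum_id", "peptide_sequence", "protein_id", "score", "is_unique")
EVIDENCE_COLUMNS = ID_COLUMNS + INTENSITY_COLS + ("stage",)
TRUTH_COLUMNS = ("protein_id", "is_kinase", "kinase_group", "true_signed_rf")


# ---------------------------------------------------------------------------
# spectra


@dataclass
class ReporterSpectrum:
    """One MS/MS spectrum reduced to what quantification needs."""

    spectrum_id: str
    peaks: np.ndarray  # shape (n, 2): m/z (Da), intensity
    precursor_mz: float
    charge: int = 2

    def __post_init__(self) -> None:
        self.peaks = np.atleast_2d(np.asarray(self.peaks, dtype=float))
        if self.peaks.size == 0:
            self.peaks = np.empty((0, 2))
        if self.peaks.shape[1] != 2:
            raise ValidationError(f"{self.spectrum_id}: peaks must be (n, 2)")
        if (self.peaks[:, 0] <= 0).any():
            raise ValidationError(f"{self.spectrum_id}: non-positive m/z")
        if (self.peaks[:, 1] < 0).any():
            raise ValidationError(f"{self.spectrum_id}: negative intensity")
        order = np.argsort(self.peaks[:, 0], kind="stable")
        self.peaks = self.peaks[order]


def _validate_mgf_text(path: Path) -> None:
    """Structural scan so parse errors can name the line."""
    in_block = False
    begin_line = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            if s == "BEGIN IONS":
                if in_block:
                    raise ParseError(f"{path}:{lineno}: nested BEGIN IONS")
                in_block, begin_line = True, lineno
            elif s == "END IONS":
                if not in_block:
                    raise ParseError(f"{path}:{lineno}: END IONS without BEGIN IONS")
                in_block = False
            elif in_block and "=" not in s:
                parts = s.split()
                try:
                    float(parts[0]), float(parts[1])
                except (ValueError, IndexError):
                    raise ParseError(
                        f"{path}:{lineno}: malformed peak line {s!r}"
                    ) from None
    if in_block:
        raise ParseError(
            f"{path}: block starting at line {begin_line} is missing END IONS"
        )


def read_mgf(path) -> list[ReporterSpectrum]:
    """Read an MGF file into :class:`ReporterSpectrum` objects.

    Peaks are returned sorted ascending by m/z regardless of file order.
    """
    path = Path(path)
    _validate_mgf_text(path)
    spectra: list[ReporterSpectrum] = []
    with _pymgf.MGF(str(path), convert_arrays=1) as reader:
        for entry in reader:
            params = entry["params"]
            title = str(params.get("title", f"spectrum_{len(spectra)}"))
            pepmass = params.get("pepmass", (0.0,))
            precursor = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            charge = params.get("charge", [2])
            charge = int(charge[0]) if hasattr(charge, "__len__") else int(charge)
            peaks = np.column_stack([entry["m/z array"], entry["intensity array"]])
            spectra.append(
                ReporterSpectrum(
                    spectrum_id=title, peaks=peaks,
                    precursor_mz=precursor, charge=charge,
                )
            )
    return spectra


def write_mgf(spectra, path, provenance: dict | None = None) -> None:
    """Write spectra as MGF.  Deterministic: fixed float formats, no clock."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}={value}\n")
        for sp in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={sp.spectrum_id}\n")
            fh.write(f"PEPMASS={sp.precursor_mz:.4f}\n")
            fh.write(f"CHARGE={sp.charge}+\n")
            for mz, inten in sp.peaks:
                fh.write(f"{mz:.4f} {inten:.4f}\n")
            fh.write("END IONS\n")


# ---------------------------------------------------------------------------
# tabular helpers


def parse_number(text) -> float:
    """Parse a number accepting decimal commas and the typographic minus."""
    if isinstance(text, (int, float)) and not isinstance(text, bool):
        return float(text)
    s = str(text).strip().replace("−", "-").replace(",", ".")
    try:
        return float(s)
    except ValueError:
        raise ValidationError(f"cannot parse number {text!r}") from None


def _parse_bool(text) -> bool:
    if isinstance(text, (bool, np.bool_)):
        return bool(text)
    s = str(text).strip().lower()
    if s in ("true", "1", "yes", "t"):
        return True
    if s in ("false", "0", "no", "f"):
        return False
    raise ValidationError(f"cannot parse boolean {text!r}")


def _read_tsv(path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                         keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file, expected columns {list(required)}")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return df


def _write_tsv(df: pd.DataFrame, path, provenance: dict | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# identification / evidence tables


def read_identifications(path) -> pd.DataFrame:
    """Read a peptide identification table (no intensities)."""
    df = _read_tsv(path, ID_COLUMNS)
    out = pd.DataFrame(
        {
            "spectrum_id": df["spectrum_id"],
            "peptide_sequence": df["peptide_sequence"],
            "protein_id": df["protein_id"],
            "score": [parse_number(x) for x in df["score"]],
            "is_unique": [_parse_bool(x) for x in df["is_unique"]],
        }
    )
    bad = out.index[out["score"] < 0]
    if len(bad):
        raise ValidationError(f"{path}: negative score at row {bad[0] + 2}")
    return out


def write_identifications(ids: pd.DataFrame, path, provenance=None) -> None:
    _write_tsv(ids.loc[:, list(ID_COLUMNS)], path, provenance)


def read_evidence(path) -> pd.DataFrame:
    """Read a peptide-evidence table with reporter intensities.

    Rows are typed and validated; the table's ``stage`` defaults to ``raw``
    when the column is absent.  Negative intensities are rejected with the
    (1-based, header-inclusive) row number.
    """
    df = _read_tsv(path, ID_COLUMNS + INTENSITY_COLS)
    out = pd.DataFrame(
        {
            "spectrum_id": df["spectrum_id"],
            "peptide_sequence": df["peptide_sequence"],
            "protein_id": df["protein_id"],
            "score": [parse_number(x) for x in df["score"]],
            "is_unique": [_parse_bool(x) for x in df["is_unique"]],
        }
    )
    for col in INTENSITY_COLS:
        vals = np.array([parse_number(x) for x in df[col]], dtype=float)
        neg = np.nonzero(vals < 0)[0]
        if neg.size:
            raise ValidationError(
                f"{path}: negative intensity in {col} at row {neg[0] + 2}"
            )
        out[col] = vals
    if (out["score"] < 0).any():
        row = int(out.index[out["score"] < 0][0])
        raise ValidationError(f"{path}: negative score at row {row + 2}")
    if "stage" in df.columns and len(df):
        stages = set(df["stage"])
        if len(stages) > 1:
            raise ValidationError(f"{path}: mixed stages {sorted(stages)}")
        stage = stages.pop()
        if stage not in EVIDENCE_STAGES:
            raise ValidationError(f"{path}: unknown stage {stage!r}")
    else:
        stage = "raw"
    out["stage"] = stage
    # optional pass-through columns written by the quantification step
    for extra in ("signed_rf", "rel_likelihood_at_unity"):
        if extra in df.columns:
            out[extra] = [
                parse_number(x) if x not in ("", "NA") else math.nan
                for x in df[extra]
            ]
    for extra in ("excludes_unity", "boundary", "clipped"):
        if extra in df.columns:
            out[extra] = [_parse_bool(x) if x not in ("", "NA") else False
                          for x in df[extra]]
    return out


def write_evidence(evidence: pd.DataFrame, path, provenance=None) -> None:
    cols = [c for c in evidence.columns if c in EVIDENCE_COLUMNS]
    cols += [c for c in evidence.columns if c not in EVIDENCE_COLUMNS]
    df = evidence.loc[:, cols].copy()
    for col in df.columns:
        if df[col].dtype == float:
            df[col] = df[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    _write_tsv(df, path, provenance)


# ---------------------------------------------------------------------------
# truth tables


def write_truth_table(truth, path, provenance=None) -> None:
    """Write simulator ground truth (accepts TruthRecords or a DataFrame)."""
    if isinstance(truth, pd.DataFrame):
        df = truth.loc[:, list(TRUTH_COLUMNS)].copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "protein_id": t.protein_id,
                    "is_kinase": t.is_kinase,
                    "kinase_group": t.kinase_group,
                    "true_signed_rf": t.true_signed_rf,
                }
                for t in truth
            ],
            columns=list(TRUTH_COLUMNS),
        )
    df["true_signed_rf"] = df["true_signed_rf"].map(lambda v: repr(float(v)))
    _write_tsv(df, path, provenance)


def read_truth_table(path) -> pd.DataFrame:
    df = _read_tsv(path, TRUTH_COLUMNS)
    out = pd.DataFrame(
        {
            "protein_id": df["protein_id"],
            "is_kinase": [_parse_bool(x) for x in df["is_kinase"]],
            "kinase_group": df["kinase_group"],
            "true_signed_rf": [parse_number(x) for x in df["true_signed_rf"]],
        }
    )
    bad = out.index[out["true_signed_rf"].abs() < 1]
    if len(bad):
        raise ValidationError(
            f"{path}: signed RF in (-1, 1) at row {int(bad[0]) + 2}"
        )
    return out


# ---------------------------------------------------------------------------
# result tables


def write_results(calls, path, annotation: dict | None = None,
                  provenance=None) -> None:
    """Write differential calls as a TSV.

    One row per protein: per-experiment signed RF and symbol, the median
    signed RF, and the up/down/unchanged call.  Missing experiments are
    written as ``NA``.  ``annotation`` optionally maps protein_id to a
    kinase group.
    """
    calls = list(calls)
    n_exp = max((len(c.per_experiment_rf) for c in calls), default=0)
    rows = []
    for c in calls:
        row = {
            "protein_id": c.protein_id,
            "kinase_group": (annotation or {}).get(c.protein_id, "unknown"),
        }
        for i in range(n_exp):
            rf = c.per_experiment_rf[i] if i < len(c.per_experiment_rf) else None
            sym = c.per_experiment_symbol[i] if i < len(c.per_experiment_symbol) else None
            row[f"rf_exp{i + 1}"] = "NA" if rf is None or pd.isna(rf) else repr(float(rf))
            row[f"sym_exp{i + 1}"] = "NA" if sym is None else sym
        row["median_rf"] = repr(float(c.median_rf))
        row["call"] = c.call
        row["n_regulated_experiments"] = c.n_regulated_experiments
        rows.append(row)
    cols = ["protein_id", "kinase_group"]
    cols += [f"rf_exp{i + 1}" for i in range(n_exp)]
    cols += [f"sym_exp{i + 1}" for i in range(n_exp)]
    cols += ["median_rf", "call", "n_regulated_experiments"]
    _write_tsv(pd.DataFrame(rows, columns=cols), path, provenance)


def read_results(path) -> pd.DataFrame:
    df = _read_tsv(path, ("protein_id", "kinase_group", "median_rf", "call"))
    out = df.copy()
    for col in out.columns:
        if col.startswith("rf_exp") or col == "median_rf":
            out[col] = [
                math.nan if x == "NA" else parse_number(x) for x in out[col]
            ]
        elif col == "n_regulated_experiments":
            out[col] = [int(x) for x in out[col]]
    return out
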