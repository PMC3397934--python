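"""Reporter-ion extraction, isotope-impurity correction and normalization.

The quantitative signal of a 4-plex experiment sits in four reporter ions
(nominal m/z 114–117).  Three corrections happen before any ratio is
estimated:

1. **Extraction** — sum all peaks within ±tolerance of each canonical
   reporter m/z (tolerance 0.02–0.05 Da depending on instrument).
2. **Impurity correction** — isotope envelopes of the label reagents leak
   a few percent of each channel into its neighbours.  With a purity
   matrix P (row = true label, column = observed channel) the observed
   vector is Pᵀ·true; the correction solves that linear system and clips
   (flagged) small negative solutions to zero.
3. **Normalization** — equalize the total signal of the active channels
   so that unequal sample loading does not masquerade as regulation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import constants as C
from .errors import ConfigError, NormalizationError, ValidationError
from .io import INTENSITY_COLS, ReporterSpectrum

_MIN_REPORTER_SPACING = min(np.diff(sorted(C.REPORTER_MZ.values())))


def extract_reporters(
    spectrum: ReporterSpectrum,
    tolerance: float = C.DEFAULT_REPORTER_TOLERANCE_DA,
    reporter_mz: dict[int, float] | None = None,
) -> dict[int, float]:
    """Summed intensity within ±``tolerance`` Da of each reporter m/z."""
    if not 0 < tolerance <= 0.5:
        raise ConfigError(f"tolerance must lie in (0, 0.5], got {tolerance}")
    mz_map = reporter_mz or C.REPORTER_MZ
    if tolerance >= _MIN_REPORTER_SPACING / 2:
        raise ConfigError(
            f"tolerance {tolerance} Da makes reporter windows overlap "
            f"(inter-reporter spacing {_MIN_REPORTER_SPACING:.4f} Da)"
        )
    mz = spectrum.peaks[:, 0] if spectrum.peaks.size else np.empty(0)
    inten = spectrum.peaks[:, 1] if spectrum.peaks.size else np.empty(0)
    out = {}
    for ch in C.CHANNELS:
        center = mz_map[ch]
        mask = np.abs(mz - center) <= tolerance
        out[ch] = float(inten[mask].sum())
    return out


def correct_impurity(
    observed: dict[int, float] | np.ndarray, purity: np.ndarray
) -> tuple[dict[int, float], bool]:
    """Unmix label cross-contamination.

    Solves ``purityᵀ · true = observed``.  Returns the corrected channel
    map and a flag that is True when any negative solution was clipped
    to zero (slightly inconsistent observations, e.g. from noise).
    """
    purity = np.asarray(purity, dtype=float)
    if isinstance(observed, dict):
        vec = np.array([observed[ch] for ch in C.CHANNELS], dtype=float)
    else:
        vec = np.asarray(observed, dtype=float)
    if (vec < 0).any():
        raise ValidationError("observed intensities must be non-negative")
    try:
        true = np.linalg.solve(purity.T, vec)
    except np.linalg.LinAlgError as err:
        raise ConfigError(f"purity matrix not invertible: {err}") from None
    clipped = bool((true < -1e-12).any())
    true = np.clip(true, 0.0, None)
    return {ch: float(true[i]) for i, ch in enumerate(C.CHANNELS)}, clipped


def correct_evidence(
    evidence: pd.DataFrame, purity: np.ndarray
) -> pd.DataFrame:
    """Apply :func:`correct_impurity` to every row of a raw evidence table."""
    if len(evidence) and evidence["stage"].iloc[0] != "raw":
        raise ValidationError(
            f"expected stage 'raw', got {evidence['stage'].iloc[0]!r}"
        )
    mat = evidence.loc[:, list(INTENSITY_COLS)].to_numpy(dtype=float)
    try:
        true = np.linalg.solve(np.asarray(purity, dtype=float).T, mat.T).T
    except np.linalg.LinAlgError as err:
        raise ConfigError(f"purity matrix not invertible: {err}") from None
    clipped = (true < -1e-12).any(axis=1)
    true = np.clip(true, 0.0, None)
    out = evidence.copy()
    out.loc[:, list(INTENSITY_COLS)] = true
    out["clipped"] = clipped
    out["stage"] = "corrected"
    return out


def normalize_channels(
    evidence: pd.DataFrame,
    labels: dict[str, int],
    method: str = "total",
    score_min: float = C.DEFAULT_SCORE_MIN,
) -> pd.DataFrame:
    """Scale active channels onto a common total.

    Only the experiment's active channels (those carrying Treg or Teff)
    are rescaled, and only unique peptides above the identification score
    threshold contribute to the scale factors — but the factors are then
    applied to every row.  ``method='total'`` equalizes channel totals to
    their grand mean; ``method='median'`` equalizes the median per-peptide
    log-ratio to zero (scale anchored on the grand mean of totals);
    ``method='none'`` only advances the stage marker.
    """
    # re-normalizing an already-normalized table is a no-op by construction,
    # so any stage is accepted
    active = sorted({labels["Treg"], labels["Teff"]})
    cols = [f"intensity_{ch}" for ch in active]
    out = evidence.copy()
    if method == "none" or not len(evidence):
        out["stage"] = "normalized"
        return out

    contributing = evidence["is_unique"] & (evidence["score"] > score_min)
    basis = evidence.loc[contributing, cols]
    if not len(basis):
        basis = evidence.loc[:, cols]
    totals = basis.to_numpy(dtype=float).sum(axis=0)
    for ch, tot in zip(active, totals):
        if tot <= 0:
            raise NormalizationError(
                f"channel {ch} has zero total intensity; cannot normalize"
            )
    if method == "total":
        scalars = totals.mean() / totals
    elif method == "median":
        a = basis.to_numpy(dtype=float)
        ok = (a > 0).all(axis=1)
        logs = np.log(a[ok])
        center = np.median(logs - logs.mean(axis=1, keepdims=True), axis=0)
        scalars = np.exp(-center)
        scalars *= totals.mean() / float((totals * scalars).mean())
    else:
        raise ConfigError(f"unknown normalization method {method!r}")
    for col, s in zip(cols, scalars):
        out[col] = evidence[col].to_numpy(dtype=float) * s
    out["stage"] = "normalized"
    return out
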