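"""Protein-level rollup and replicate-consistent differential calling.

Peptide-level signed regulation factors of one protein in one experiment
are combined two ways:

* the **point estimate** is the arithmetic mean of the signed peptide
  RFs (reported to one decimal in summaries);
* the **significance** comes from the combined likelihood curve — the
  product (log-sum) of the peptide curves, renormalized — and its
  separation from RF = 1.

Across experiments a protein is called differentially expressed only if
(i) its per-experiment |RF| reaches the threshold (default 1.5, inclusive)
in at least ``min_experiments`` experiments (default 2), and (ii) the
median signed RF over the experiments it was quantified in reaches the
same threshold.  Optionally a regulated experiment must also have a
combined curve excluding unity.  Sign conflicts are flagged, never
silently averaged away.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import constants as C
from .errors import AggregationError
from .likelihood import LikelihoodCurve, signed_to_ratio


def _snap_to_convention(value: float) -> tuple[float, bool]:
    """Map a signed mean/median falling in (-1, 1) to the nearer boundary.

    Ties at 0 break positive.  Returns (snapped value, was_snapped).
    """
    if abs(value) >= 1.0:
        return float(value), False
    return (1.0 if value >= 0.0 else -1.0), True


@dataclass
class ProteinRegulation:
    """One protein's regulation in one experiment."""

    protein_id: str
    experiment_index: int
    peptide_rfs: list[float]
    protein_rf: float
    combined_curve: LikelihoodCurve | None
    n_peptides: int
    total_score: float
    sign_conflict: bool = False

    @property
    def excludes_unity(self) -> bool:
        return bool(self.combined_curve and self.combined_curve.excludes_unity)


@dataclass
class DifferentialCall:
    """Cross-experiment classification of one protein."""

    protein_id: str
    per_experiment_rf: list[float | None]
    per_experiment_symbol: list[str | None]
    median_rf: float
    call: str  # "down" | "up" | "unchanged"
    n_regulated_experiments: int
    median_snapped: bool = False
    sign_conflict: bool = False


def combine_curves(
    curves: list[LikelihoodCurve],
    alpha: float = C.DEFAULT_EXCLUSION_ALPHA,
) -> LikelihoodCurve:
    """Product of peptide likelihood curves, renormalized to max 1.

    All curves must share a grid.  The combined maximum is located with
    3-point parabolic refinement, so the reported combined ``mle_ratio``
    need not sit exactly on a grid point.
    """
    if not curves:
        raise AggregationError("cannot combine zero curves")
    grid = curves[0].grid
    total = np.zeros_like(grid)
    log_at_unity = 0.0
    for cv in curves:
        if cv.grid.shape != grid.shape or not np.allclose(cv.grid, grid):
            raise AggregationError("curves must share one ratio grid")
        total = total + cv.log_rel
        log_at_unity += float(np.log(max(cv.rel_at_unity, 1e-300)))

    j = int(np.argmax(total))
    log_rhos = np.log(grid)
    if 0 < j < len(grid) - 1:
        f0, f1, f2 = total[j - 1], total[j], total[j + 1]
        denom = f0 - 2.0 * f1 + f2
        if denom < 0:
            off = float(np.clip(0.5 * (f0 - f2) / denom, -0.5, 0.5))
            peak = float(f1 - 0.125 * (f0 - f2) ** 2 / denom)
        else:
            off, peak = 0.0, float(f1)
        mle = float(np.exp(log_rhos[j] + off * (log_rhos[1] - log_rhos[0])))
        boundary = any(cv.boundary for cv in curves)
    else:
        mle, peak = float(grid[j]), float(total[j])
        boundary = True
    log_rel = np.minimum(total - peak, 0.0)
    rel_at_unity = float(min(np.exp(log_at_unity - peak), 1.0))
    return LikelihoodCurve(
        grid=grid,
        log_rel=log_rel,
        mle_ratio=mle,
        loglik_max=peak,
        rel_at_unity=rel_at_unity,
        excludes_unity=bool(rel_at_unity < alpha),
        boundary=boundary,
    )


def aggregate_protein(
    protein_id: str,
    peptide_rfs: list[float],
    curves: list[LikelihoodCurve] | None = None,
    scores: list[float] | None = None,
    experiment_index: int = 0,
    alpha: float = C.DEFAULT_EXCLUSION_ALPHA,
) -> ProteinRegulation:
    """Roll peptide signed RFs (and curves) up to one protein regulation.

    The protein point estimate is the arithmetic mean of the signed
    peptide RFs.  A mean inside (-1, 1) violates the signed-RF
    convention; it is snapped to the nearer boundary (+1 on ties) and
    the record is flagged as a sign conflict.
    """
    rfs = [float(r) for r in peptide_rfs]
    if not rfs:
        raise AggregationError(f"{protein_id}: no peptides to aggregate")
    if any(abs(r) < 1 for r in rfs):
        raise AggregationError(f"{protein_id}: peptide RF inside (-1, 1)")
    mean = float(np.mean(rfs))
    protein_rf, snapped = _snap_to_convention(mean)
    conflict = snapped or (min(rfs) < 0 < max(rfs))
    combined = combine_curves(curves, alpha=alpha) if curves else None
    return ProteinRegulation(
        protein_id=protein_id,
        experiment_index=experiment_index,
        peptide_rfs=rfs,
        protein_rf=protein_rf,
        combined_curve=combined,
        n_peptides=len(rfs),
        total_score=float(np.sum(scores)) if scores is not None else float("nan"),
        sign_conflict=conflict,
    )


def _symbol(rf: float, threshold: float) -> str:
    if rf <= -threshold:
        return "-"
    if rf >= threshold:
        return "+"
    return "0"


def signed_median(values: list[float]) -> tuple[float, bool]:
    """Median of signed RFs: on even counts, the mean of the two central
    signed values, snapped (flagged) to ±1 if it lands inside (-1, 1)."""
    v = sorted(float(x) for x in values)
    n = len(v)
    if n == 0:
        raise AggregationError("median of zero experiments")
    if n % 2:
        return v[n // 2], False
    mid = 0.5 * (v[n // 2 - 1] + v[n // 2])
    return _snap_to_convention(mid)


def call_differential(
    per_experiment,
    threshold: float = C.DEFAULT_RF_THRESHOLD,
    min_experiments: int = C.DEFAULT_MIN_REGULATED_EXPERIMENTS,
    require_exclusion: bool = False,
    n_experiments: int | None = None,
) -> DifferentialCall:
    """Classify one protein as up / down / unchanged across experiments.

    ``per_experiment`` is a list of :class:`ProteinRegulation` (or plain
    signed RFs) with ``None`` for experiments the protein was not
    quantified in.  Symbols follow the inclusive threshold rule
    (RF <= -threshold -> '-', RF >= +threshold -> '+', else '0'); the
    median is taken over present experiments only, on the signed scale.
    A '-'/'+' symbol counts toward ``n_regulated_experiments`` only if,
    when ``require_exclusion`` is set and a combined curve is available,
    that experiment's curve excludes unity.
    """
    regs: list[ProteinRegulation | None] = []
    for item in per_experiment:
        if item is None or isinstance(item, ProteinRegulation):
            regs.append(item)
        else:
            regs.append(
                ProteinRegulation(
                    protein_id="", experiment_index=len(regs),
                    peptide_rfs=[float(item)], protein_rf=float(item),
                    combined_curve=None, n_peptides=1, total_score=float("nan"),
                )
            )
    if n_experiments is not None:
        regs += [None] * (n_experiments - len(regs))
    present = [r for r in regs if r is not None]
    if not present:
        raise AggregationError("protein quantified in zero experiments")

    protein_id = next((r.protein_id for r in present if r.protein_id), "")
    rfs = [None if r is None else r.protein_rf for r in regs]
    symbols = [None if rf is None else _symbol(rf, threshold) for rf in rfs]

    def _counts(sym: str) -> int:
        n = 0
        for r, s in zip(regs, symbols):
            if s != sym:
                continue
            if require_exclusion and r.combined_curve is not None and not r.excludes_unity:
                continue
            n += 1
        return n

    n_down, n_up = _counts("-"), _counts("+")
    median, snapped = signed_median([r.protein_rf for r in present])
    if n_down >= min_experiments and median <= -threshold:
        call, n_reg = "down", n_down
    elif n_up >= min_experiments and median >= threshold:
        call, n_reg = "up", n_up
    else:
        call, n_reg = "unchanged", max(n_down, n_up)
    return DifferentialCall(
        protein_id=protein_id,
        per_experiment_rf=rfs,
        per_experiment_symbol=symbols,
        median_rf=median,
        call=call,
        n_regulated_experiments=n_reg,
        median_snapped=snapped,
        sign_conflict=any(r.sign_conflict for r in present),
    )


# ---------------------------------------------------------------------------
# kinome summaries


def summarize_kinome(
    calls: list[DifferentialCall],
    annotation: pd.DataFrame,
    scores: dict[str, float] | None = None,
) -> dict:
    """Catalog-level summary: kinase fraction, score contrast, group counts.

    ``annotation`` needs columns ``protein_id, is_kinase, kinase_group``
    (a truth table works).  Proteins missing from the annotation are
    grouped under ``unknown``.
    """
    ann = annotation.set_index("protein_id")
    group_counts: dict[str, int] = {}
    call_counts = {"up": 0, "down": 0, "unchanged": 0}
    kin_flags, kin_scores, other_scores = [], [], []
    for c in calls:
        call_counts[c.call] += 1
        if c.protein_id in ann.index:
            row = ann.loc[c.protein_id]
            is_kin = bool(row["is_kinase"])
            group = str(row["kinase_group"]) if is_kin else "none"
        else:
            is_kin, group = False, "unknown"
        kin_flags.append(is_kin)
        group_counts[group] = group_counts.get(group, 0) + 1
        if scores and c.protein_id in scores:
            (kin_scores if is_kin else other_scores).append(scores[c.protein_id])
    n = len(calls)
    return {
        "n_proteins": n,
        "fraction_kinases": (sum(kin_flags) / n) if n else float("nan"),
        "mean_score_kinases": float(np.mean(kin_scores)) if kin_scores else float("nan"),
        "mean_score_others": float(np.mean(other_scores)) if other_scores else float("nan"),
        "group_counts": dict(sorted(group_counts.items())),
        "call_counts": call_counts,
    }


def rf_distribution(
    calls: list[DifferentialCall], bins=None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """log2 of the median Treg/Teff ratio per protein, binned.

    Returns ``(values, counts, bin_edges)`` where values are
    ``log2(signed_to_ratio(median_rf))`` — the natural symmetric scale on
    which an unregulated catalog centers at 0.
    """
    if not calls:
        raise AggregationError("rf_distribution of zero calls")
    values = np.array(
        [np.log2(signed_to_ratio(c.median_rf)) for c in calls], dtype=float
    )
    if bins is None:
        span = max(1.0, float(np.ceil(np.abs(values).max() * 2) / 2))
        bins = np.arange(-span - 0.25, span + 0.5, 0.5)
    counts, edges = np.histogram(values, bins=bins)
    return values, counts, edges
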