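"""Likelihood curves for peptide regulation factors.

For one peptide the two active reporter channels give intensities
``t`` (Treg) and ``e`` (Teff).  Both are noisy observations of latent
true signals ``rho * mu`` and ``mu``, where ``rho = Treg/Teff`` is the
regulation ratio of interest and ``mu > 0`` the latent Teff abundance.
Reporter noise is Gaussian with an intensity-dependent standard
deviation

    sigma(I) = sigma0 + c * I

— an additive floor plus a proportional term, the simplest family that
captures both the detector noise at low signal and the multiplicative
behaviour of ion statistics at high signal.

The relative likelihood of ``rho`` is the profile likelihood

    L(rho) = max_{mu > 0}  N(e; mu, sigma(mu)) * N(t; rho*mu, sigma(rho*mu))

normalized to its maximum, so every curve peaks at 1 at the
maximum-likelihood ratio.  A protein is "significantly regulated" in an
experiment when the (combined) curve at ``rho = 1`` falls below a level
``alpha``: the curve is separated from RF = 1.

Signed regulation factors write ratios below one as negative
reciprocals (ratio 0.27 -> -3.7) so that fold changes in the two
directions are symmetric around ±1; no signed RF lies in (-1, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import constants as C
from .errors import CalibrationError, ValidationError

_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# noise model and ratio grid


@dataclass(frozen=True)
class NoiseModel:
    """Affine intensity-dependent Gaussian noise: sd(I) = sigma0 + c*I."""

    sigma0: float
    c: float

    def __post_init__(self) -> None:
        if self.sigma0 < 0 or self.c < 0:
            raise ValidationError("noise parameters must be >= 0")
        if self.sigma0 == 0 and self.c == 0:
            raise ValidationError("sigma0 and c cannot both be 0")

    def sigma(self, intensity):
        return self.sigma0 + self.c * np.asarray(intensity, dtype=float)


@dataclass(frozen=True)
class RatioGrid:
    """Log-spaced ratio grid on which likelihood curves are evaluated."""

    lo: float = 1.0 / 50.0
    hi: float = 50.0
    n: int = 400

    def __post_init__(self) -> None:
        if not (0 < self.lo < 1 < self.hi) or self.n < 10:
            raise ValidationError("ratio grid must bracket 1 with >= 10 points")

    @property
    def values(self) -> np.ndarray:
        return np.geomspace(self.lo, self.hi, self.n)


DEFAULT_GRID = RatioGrid()


# ---------------------------------------------------------------------------
# signed-RF convention


def to_signed_rf(ratio: float) -> float:
    """Plain ratio -> signed RF: rho >= 1 maps to rho, rho < 1 to -1/rho."""
    if not np.isfinite(ratio) or ratio <= 0:
        raise ValidationError(f"ratio must be positive and finite, got {ratio}")
    return float(ratio) if ratio >= 1.0 else float(-1.0 / ratio)


def signed_to_ratio(signed_rf: float) -> float:
    """Signed RF -> plain Treg/Teff ratio."""
    if abs(signed_rf) < 1:
        raise ValidationError(f"invalid signed RF {signed_rf}: |RF| must be >= 1")
    return float(signed_rf) if signed_rf >= 1.0 else float(-1.0 / signed_rf)


# ---------------------------------------------------------------------------
# likelihood curve


@dataclass
class LikelihoodCurve:
    """Relative likelihood of the Treg/Teff ratio for one peptide."""

    grid: np.ndarray
    log_rel: np.ndarray  # log relative likelihood on the grid, max ~ 0
    mle_ratio: float
    loglik_max: float  # absolute profile log-likelihood at mle_ratio
    rel_at_unity: float
    excludes_unity: bool
    boundary: bool = False

    @property
    def rel_likelihood(self) -> np.ndarray:
        return np.exp(self.log_rel)

    @property
    def signed_rf(self) -> float:
        return to_signed_rf(self.mle_ratio)

    def to_frame(self) -> pd.DataFrame:
        """Curve as a (ratio, rel_likelihood) table for plotting/export."""
        return pd.DataFrame(
            {"ratio": self.grid, "rel_likelihood": self.rel_likelihood}
        )


def _loglik(t, e, rho, mu, noise: NoiseModel):
    """Joint log-density of the two observed intensities (vectorized)."""
    se = noise.sigma(mu)
    st = noise.sigma(rho * mu)
    return (
        -0.5 * ((e - mu) / se) ** 2
        - np.log(se)
        - 0.5 * ((t - rho * mu) / st) ** 2
        - np.log(st)
        - _LOG_2PI
    )


def profile_loglik(t: float, e: float, rho: float, noise: NoiseModel) -> float:
    """Profile log-likelihood at one ratio: exact 1-D maximization over mu."""
    ref = max(t / rho, e, 1e-9)
    lo = max(min(t / rho, e) * 0.2, ref * 1e-5, 1e-12)
    hi = ref * 5.0

    def neg(logmu):
        return -_loglik(t, e, rho, np.exp(logmu), noise)

    res = minimize_scalar(neg, bounds=(np.log(lo), np.log(hi)), method="bounded",
                          options={"xatol": 1e-10})
    return float(-res.fun)


def _parabolic_peak(f: np.ndarray, axis: int = -1):
    """Argmax with 3-point parabolic refinement along ``axis``.

    Returns (refined max value, fractional index offset in [-0.5, 0.5]).
    """
    f = np.moveaxis(f, axis, -1)
    idx = np.argmax(f, axis=-1)
    n = f.shape[-1]
    inner = np.clip(idx, 1, n - 2)
    take = np.take_along_axis
    f0 = take(f, (inner - 1)[..., None], -1)[..., 0]
    f1 = take(f, inner[..., None], -1)[..., 0]
    f2 = take(f, (inner + 1)[..., None], -1)[..., 0]
    denom = f0 - 2.0 * f1 + f2
    with np.errstate(divide="ignore", invalid="ignore"):
        offset = np.where(denom < -1e-300, 0.5 * (f0 - f2) / denom, 0.0)
        value = np.where(denom < -1e-300, f1 - 0.125 * (f0 - f2) ** 2 / denom, f1)
    at_edge = (idx == 0) | (idx == n - 1)
    value = np.where(at_edge, np.max(f, axis=-1), value)
    offset = np.where(at_edge, 0.0, np.clip(offset, -0.5, 0.5))
    return value, offset, idx


def _profile_on_grid(t, e, rhos, noise: NoiseModel, n_mu: int = 161):
    """Vectorized profile log-likelihood over a ratio grid.

    For each ratio the latent mu is profiled on a per-ratio geometric grid
    spanning the two naive estimates (e and t/rho) with generous margins,
    refined by parabolic interpolation.
    """
    rhos = np.asarray(rhos, dtype=float)
    est = np.stack([np.full_like(rhos, e), t / rhos])
    mx = np.maximum(est[0], est[1])
    mn = np.minimum(est[0], est[1])
    mx = np.maximum(mx, 1e-9)
    mn = np.maximum(mn, mx * 1e-4)
    lo = mn * 0.3
    hi = mx * 3.0
    w = np.linspace(0.0, 1.0, n_mu)
    mu = lo[:, None] * (hi / lo)[:, None] ** w[None, :]
    ll = _loglik(t, e, rhos[:, None], mu, noise)
    value, _, _ = _parabolic_peak(ll, axis=-1)
    return value


def ratio_likelihood(
    t: float,
    e: float,
    noise: NoiseModel,
    grid: RatioGrid = DEFAULT_GRID,
    alpha: float = C.DEFAULT_EXCLUSION_ALPHA,
) -> LikelihoodCurve:
    """Likelihood curve of rho = Treg/Teff from one peptide's intensities."""
    t, e = float(t), float(e)
    if t < 0 or e < 0:
        raise ValidationError("intensities must be non-negative")
    if t == 0 and e == 0:
        raise ValidationError("both channel intensities are zero: ratio undefined")
    boundary = t == 0 or e == 0
    rhos = grid.values
    prof = _profile_on_grid(t, e, rhos, noise)

    peak_val, offset, idx = _parabolic_peak(prof[None, :], axis=-1)
    j = int(idx[0])
    at_edge = j == 0 or j == len(rhos) - 1
    boundary = boundary or at_edge
    log_rhos = np.log(rhos)
    step = log_rhos[1] - log_rhos[0]
    jj = min(max(j, 1), len(rhos) - 2)
    rho_hat_parab = float(np.exp(log_rhos[jj] + float(offset[0]) * step))

    # exact profile at both candidate peaks; keep the better one so the
    # curve's maximum is, by construction, its value at mle_ratio
    cand = {float(rhos[j]): profile_loglik(t, e, float(rhos[j]), noise)}
    if not at_edge:
        cand[rho_hat_parab] = profile_loglik(t, e, rho_hat_parab, noise)
    mle_ratio, loglik_max = max(cand.items(), key=lambda kv: kv[1])
    loglik_max = max(loglik_max, float(prof.max()))

    log_rel = np.minimum(prof - loglik_max, 0.0)
    l1 = profile_loglik(t, e, 1.0, noise)
    rel_at_unity = float(min(np.exp(l1 - loglik_max), 1.0))
    return LikelihoodCurve(
        grid=rhos,
        log_rel=log_rel,
        mle_ratio=float(mle_ratio),
        loglik_max=float(loglik_max),
        rel_at_unity=rel_at_unity,
        excludes_unity=bool(rel_at_unity < alpha),
        boundary=bool(boundary),
    )


def peptide_likelihood(
    evidence_row,
    labels: dict[str, int],
    noise: NoiseModel,
    grid: RatioGrid = DEFAULT_GRID,
    alpha: float = C.DEFAULT_EXCLUSION_ALPHA,
) -> LikelihoodCurve:
    """Curve for one evidence row given the experiment's label map."""
    t = float(evidence_row[f"intensity_{labels['Treg']}"])
    e = float(evidence_row[f"intensity_{labels['Teff']}"])
    return ratio_likelihood(t, e, noise, grid=grid, alpha=alpha)


def attach_likelihoods(
    evidence: pd.DataFrame,
    labels: dict[str, int],
    noise: NoiseModel,
    grid: RatioGrid = DEFAULT_GRID,
    alpha: float = C.DEFAULT_EXCLUSION_ALPHA,
    score_min: float = C.DEFAULT_SCORE_MIN,
) -> tuple[pd.DataFrame, dict]:
    """Compute curves for all eligible rows of a normalized evidence table.

    Eligible rows are unique peptides above the identification score
    threshold with at least one non-zero active channel.  Returns the
    table with ``signed_rf``, ``rel_likelihood_at_unity``,
    ``excludes_unity`` and ``boundary`` columns added (NaN/False on
    ineligible rows) and a dict mapping row index -> LikelihoodCurve.
    """
    out = evidence.copy()
    out["signed_rf"] = np.nan
    out["rel_likelihood_at_unity"] = np.nan
    out["excludes_unity"] = False
    out["boundary"] = False
    curves: dict = {}
    tcol = f"intensity_{labels['Treg']}"
    ecol = f"intensity_{labels['Teff']}"
    eligible = (
        out["is_unique"]
        & (out["score"] > score_min)
        & ((out[tcol] > 0) | (out[ecol] > 0))
    )
    for ix in out.index[eligible]:
        curve = ratio_likelihood(
            float(out.at[ix, tcol]), float(out.at[ix, ecol]),
            noise, grid=grid, alpha=alpha,
        )
        curves[ix] = curve
        out.at[ix, "signed_rf"] = curve.signed_rf
        out.at[ix, "rel_likelihood_at_unity"] = curve.rel_at_unity
        out.at[ix, "excludes_unity"] = curve.excludes_unity
        out.at[ix, "boundary"] = curve.boundary
    return out, curves


# ---------------------------------------------------------------------------
# noise calibration


def fit_noise_from_unregulated(
    evidence: pd.DataFrame,
    labels: dict[str, int],
    score_min: float = C.DEFAULT_SCORE_MIN,
    min_peptides: int = 50,
    n_bins: int = 8,
) -> NoiseModel:
    """Calibrate (sigma0, c) from peptides near the global ratio mode.

    For unregulated peptides the two active channels carry the same true
    signal (up to the global loading ratio), so the spread of their
    difference as a function of intensity traces the noise law.  The
    global mode is estimated by the median log-ratio; peptides within
    three robust standard deviations of it are kept, the Treg channel is
    rescaled onto the Teff channel, and the per-intensity-bin standard
    deviation of ``(t' - e)/sqrt(2)`` is regressed linearly on the bin
    mean intensity: intercept = sigma0, slope = c.
    """
    tcol = f"intensity_{labels['Treg']}"
    ecol = f"intensity_{labels['Teff']}"
    sel = (
        evidence["is_unique"]
        & (evidence["score"] > score_min)
        & (evidence[tcol] > 0)
        & (evidence[ecol] > 0)
    )
    t = evidence.loc[sel, tcol].to_numpy(dtype=float)
    e = evidence.loc[sel, ecol].to_numpy(dtype=float)
    if len(t) < min_peptides:
        raise CalibrationError(
            f"noise calibration needs >= {min_peptides} peptides, got {len(t)}"
        )
    logr = np.log(t / e)
    med = float(np.median(logr))
    mad = float(np.median(np.abs(logr - med)))
    if mad > 0:
        keep = np.abs(logr - med) <= 3.0 * 1.4826 * mad
    else:
        keep = np.ones_like(logr, dtype=bool)
    tp = t[keep] / np.exp(med)
    ep = e[keep]
    d = (tp - ep) / np.sqrt(2.0)
    intensity = (tp + ep) / 2.0

    order = np.argsort(intensity)
    d, intensity = d[order], intensity[order]
    bins = np.array_split(np.arange(len(d)), min(n_bins, max(2, len(d) // 10)))
    xs, ys = [], []
    for b in bins:
        if len(b) < 3:
            continue
        xs.append(float(intensity[b].mean()))
        ys.append(float(d[b].std(ddof=1)))
    if len(xs) < 2:
        raise CalibrationError("too few intensity bins for noise calibration")
    slope, intercept = np.polyfit(xs, ys, 1)
    sigma0 = max(float(intercept), 0.0)
    c = max(float(slope), 0.0)
    if sigma0 == 0.0 and c == 0.0:
        sigma0 = 1e-9  # degenerate noise-free limit; keep the model valid
    return NoiseModel(sigma0=sigma0, c=c)
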