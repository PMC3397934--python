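"""Profile-likelihood curves: MLE accuracy against a dense-grid oracle,
signed-RF conventions, separation-from-unity behavior, noise calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinoquant.datasets import cdk6_evidence, cdk6_peptides
from kinoquant.errors import CalibrationError, ValidationError
from kinoquant.likelihood import (
    NoiseModel,
    RatioGrid,
    attach_likelihoods,
    fit_noise_from_unregulated,
    profile_loglik,
    ratio_likelihood,
    signed_to_ratio,
    to_signed_rf,
)

from conftest import make_null_evidence

NOISE = NoiseModel(1.0, 0.05)


def dense_grid_mle(t, e, noise, n=1200):
    """Brute-force 2-D grid search over (ratio, latent intensity)."""
    center = max(t, 1e-3) / max(e, 1e-3)
    rhos = np.geomspace(center / 6, center * 6, n)
    mus = np.geomspace(max(min(t, e), 1e-2) * 0.05, max(t, e) * 8, n)
    R, M = rhos[:, None], mus[None, :]
    se = noise.sigma0 + noise.c * M
    st_ = noise.sigma0 + noise.c * R * M
    ll = (-0.5 * ((e - M) / se) ** 2 - np.log(se)
          - 0.5 * ((t - R * M) / st_) ** 2 - np.log(st_))
    i, _ = np.unravel_index(np.argmax(ll), ll.shape)
    return float(rhos[i])


# -- curve shape ------------------------------------------------------------


def test_equal_intensities_give_unit_ratio():
    curve = ratio_likelihood(1000.0, 1000.0, NOISE)
    assert curve.mle_ratio == pytest.approx(1.0, rel=1e-6)
    assert not curve.excludes_unity
    assert curve.rel_at_unity == pytest.approx(1.0, rel=1e-9)


def test_mle_matches_known_ratio():
    curve = ratio_likelihood(270.0, 1000.0, NOISE)
    assert curve.mle_ratio == pytest.approx(0.27, rel=0.02)
    assert curve.mle_ratio == pytest.approx(
        dense_grid_mle(270.0, 1000.0, NOISE), rel=0.02
    )


def test_label_swap_gives_reciprocal_mle():
    a = ratio_likelihood(1000.0, 270.0, NOISE)
    b = ratio_likelihood(270.0, 1000.0, NOISE)
    assert a.mle_ratio * b.mle_ratio == pytest.approx(1.0, rel=0.01)


def test_curve_is_normalized_to_its_maximum():
    curve = ratio_likelihood(350.0, 900.0, NOISE)
    assert curve.rel_likelihood.max() <= 1.0 + 1e-12
    # the reported maximum really is the profile value at mle_ratio
    assert profile_loglik(350.0, 900.0, curve.mle_ratio, NOISE) == pytest.approx(
        curve.loglik_max, abs=1e-6
    )


def test_pure_proportional_noise_mle_is_intensity_ratio():
    noise = NoiseModel(0.0, 0.05)
    curve = ratio_likelihood(500.0, 800.0, noise)
    assert curve.mle_ratio == pytest.approx(500.0 / 800.0, rel=0.02)


def test_exclusion_is_monotone_in_signal_scale():
    """With a fixed additive noise floor, bigger signals sharpen curves."""
    noise = NoiseModel(50.0, 0.0)
    rels = [
        ratio_likelihood(k * 1300.0, k * 1000.0, noise).rel_at_unity
        for k in (1.0, 2.0, 4.0)
    ]
    assert rels[0] >= rels[1] >= rels[2]


def test_zero_intensity_flags_boundary():
    curve = ratio_likelihood(0.0, 1000.0, NOISE)
    assert curve.boundary
    with pytest.raises(ValidationError):
        ratio_likelihood(0.0, 0.0, NOISE)


def test_invalid_noise_model_rejected():
    with pytest.raises(ValidationError):
        NoiseModel(0.0, 0.0)
    with pytest.raises(ValidationError):
        NoiseModel(-1.0, 0.1)


# -- signed-RF convention ---------------------------------------------------


def test_signed_rf_convention():
    assert to_signed_rf(1.0) == pytest.approx(1.0)
    assert to_signed_rf(2.5) == pytest.approx(2.5)
    assert to_signed_rf(1 / 3.9) == pytest.approx(-3.9)
    with pytest.raises(ValidationError):
        to_signed_rf(0.0)
    with pytest.raises(ValidationError):
        to_signed_rf(-2.0)
    with pytest.raises(ValidationError):
        signed_to_ratio(0.5)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.floats(1e-6, 1e6))
def test_signed_rf_roundtrip(ratio):
    assert signed_to_ratio(to_signed_rf(ratio)) == pytest.approx(ratio, rel=1e-12)


# -- separation from unity on the reference peptides ------------------------


def test_all_reference_cdk6_curves_exclude_unity():
    """Synthetic intensities consistent with the printed CDK6 peptide RFs
    all yield curves clearly separated from RF = 1."""
    evidence = cdk6_evidence()
    out, curves = attach_likelihoods(evidence, {"Treg": 114, "Teff": 117}, NOISE)
    assert len(curves) == 12
    assert all(c.excludes_unity for c in curves.values())
    expected = cdk6_peptides()["signed_rf"].to_numpy()
    assert np.allclose(out["signed_rf"], expected, rtol=0.02)


# -- noise calibration ------------------------------------------------------


def test_noise_recovery_from_unregulated_peptides():
    evidence = make_null_evidence(2000, sigma0=5.0, c=0.03, seed=4)
    noise = fit_noise_from_unregulated(evidence, {"Treg": 114, "Teff": 117})
    assert noise.c == pytest.approx(0.03, rel=0.25)


def test_noise_fit_scale_invariant_in_c():
    labels = {"Treg": 114, "Teff": 117}
    a = fit_noise_from_unregulated(make_null_evidence(2000, 5.0, 0.03, 4), labels)
    b = fit_noise_from_unregulated(
        make_null_evidence(2000, 5.0, 0.03, 4, scale=7.0), labels
    )
    assert b.c == pytest.approx(a.c, rel=1e-9)


def test_noise_free_data_gives_vanishing_noise():
    evidence = make_null_evidence(500, sigma0=0.0, c=1e-12, seed=1)
    noise = fit_noise_from_unregulated(evidence, {"Treg": 114, "Teff": 117})
    assert noise.sigma0 <= 1e-6
    assert noise.c <= 1e-9


def test_too_few_peptides_raise_calibration_error():
    evidence = make_null_evidence(20, sigma0=5.0, c=0.03, seed=2)
    with pytest.raises(CalibrationError):
        fit_noise_from_unregulated(evidence, {"Treg": 114, "Teff": 117})


# -- grid contract ----------------------------------------------------------


def test_grid_must_bracket_unity():
    with pytest.raises(ValidationError):
        RatioGrid(2.0, 50.0, 400)
    grid = RatioGrid(1 / 50, 50.0, 400)
    assert len(grid.values) == 400
    assert grid.values[0] < 1 < grid.values[-1]
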