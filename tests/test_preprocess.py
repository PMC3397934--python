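"""Reporter extraction windows, impurity unmixing, channel normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinoquant.constants import CHANNELS, example_purity_matrix
from kinoquant.datasets import cdk6_evidence
from kinoquant.errors import ConfigError, NormalizationError
from kinoquant.io import ReporterSpectrum
from kinoquant.preprocess import (
    correct_impurity,
    extract_reporters,
    normalize_channels,
)

LABELS = {"Treg": 114, "Teff": 117}


def _spectrum(peaks):
    return ReporterSpectrum("s1", np.array(peaks, dtype=float), 500.0)


# -- extraction -------------------------------------------------------------


@pytest.mark.parametrize(
    "peaks,expected",
    [
        ([[114.1112, 500.0]], {114: 500.0, 115: 0.0, 116: 0.0, 117: 0.0}),
        ([[114.18, 500.0]], {114: 0.0, 115: 0.0, 116: 0.0, 117: 0.0}),
        (
            [[115.10, 120.0], [115.11, 80.0]],
            {114: 0.0, 115: 200.0, 116: 0.0, 117: 0.0},
        ),
    ],
)
def test_extraction_windows(peaks, expected):
    assert extract_reporters(_spectrum(peaks), tolerance=0.05) == expected


def test_overlapping_windows_rejected():
    with pytest.raises(ConfigError, match="overlap"):
        extract_reporters(_spectrum([[114.1, 1.0]]), tolerance=0.499)
    with pytest.raises(ConfigError):
        extract_reporters(_spectrum([[114.1, 1.0]]), tolerance=0.0)


# -- impurity correction ----------------------------------------------------


def test_identity_purity_is_noop():
    observed = {114: 95.0, 115: 105.0, 116: 3.0, 117: 0.0}
    corrected, clipped = correct_impurity(observed, np.eye(4))
    assert corrected == observed
    assert not clipped


def test_five_percent_leakage_recovered():
    purity = np.eye(4)
    purity[0, 0], purity[0, 1] = 0.95, 0.05
    corrected, _ = correct_impurity({114: 95.0, 115: 105.0, 116: 0.0, 117: 0.0},
                                    purity)
    assert corrected[114] == pytest.approx(100.0, abs=1e-6)
    assert corrected[115] == pytest.approx(100.0, abs=1e-6)
    assert corrected[116] == pytest.approx(0.0, abs=1e-6)


def test_all_zero_observed_stays_zero():
    corrected, clipped = correct_impurity(dict.fromkeys(CHANNELS, 0.0),
                                          example_purity_matrix())
    assert all(v == 0.0 for v in corrected.values())
    assert not clipped


def test_extract_then_identity_correct_equals_extract():
    spec = _spectrum([[114.1112, 400.0], [116.1116, 30.0]])
    extracted = extract_reporters(spec, tolerance=0.05)
    corrected, _ = correct_impurity(extracted, np.eye(4))
    assert corrected == extracted


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    true=st.lists(st.floats(0.0, 1e6), min_size=4, max_size=4),
    leak=st.floats(0.0, 0.08),
)
def test_forward_mix_then_correct_is_identity(true, leak):
    """Unmixing inverts mixing for any valid diagonally dominant matrix."""
    purity = np.eye(4) * (1 - 2 * leak)
    for i in range(4):
        purity[i, max(i - 1, 0)] += leak
        purity[i, min(i + 1, 3)] += leak
    purity /= purity.sum(axis=1, keepdims=True)
    observed = purity.T @ np.asarray(true)
    corrected, _ = correct_impurity(observed, purity)
    back = np.array([corrected[ch] for ch in CHANNELS])
    assert np.allclose(back, true, atol=1e-6 * (1 + max(true)))


# -- normalization ----------------------------------------------------------


def _two_peptide_table(int_treg, int_teff):
    rows = []
    for i, (t, e) in enumerate(zip(int_treg, int_teff)):
        rows.append(
            {
                "spectrum_id": f"s{i}",
                "peptide_sequence": f"PEP{i}K",
                "protein_id": "P1",
                "score": 50.0,
                "is_unique": True,
                "intensity_114": t,
                "intensity_115": 0.0,
                "intensity_116": 0.0,
                "intensity_117": e,
                "stage": "corrected",
            }
        )
    return pd.DataFrame(rows)


def test_balanced_totals_leave_table_unchanged():
    table = _two_peptide_table([600.0, 400.0], [300.0, 700.0])
    out = normalize_channels(table, LABELS)
    assert np.allclose(out["intensity_114"], table["intensity_114"])
    assert np.allclose(out["intensity_117"], table["intensity_117"])
    assert out["stage"].iloc[0] == "normalized"


def test_hand_computed_scalars():
    # totals 1000 vs 2000 -> scalars 1.5 and 0.75, both totals become 1500
    table = _two_peptide_table([400.0, 600.0], [900.0, 1100.0])
    out = normalize_channels(table, LABELS)
    assert out["intensity_114"].sum() == pytest.approx(1500.0)
    assert out["intensity_117"].sum() == pytest.approx(1500.0)
    assert np.allclose(out["intensity_114"],
                       table["intensity_114"] * 1.5)
    assert np.allclose(out["intensity_117"],
                       table["intensity_117"] * 0.75)


def test_global_rescaling_preserves_ratios():
    table = _two_peptide_table([400.0, 600.0], [900.0, 1100.0])
    doubled = table.copy()
    for col in ("intensity_114", "intensity_117"):
        doubled[col] = doubled[col] * 2.0
    a = normalize_channels(table, LABELS)
    b = normalize_channels(doubled, LABELS)
    assert np.allclose(
        a["intensity_114"] / a["intensity_117"],
        b["intensity_114"] / b["intensity_117"],
    )


def test_normalization_idempotent():
    table = _two_peptide_table([400.0, 600.0], [900.0, 1100.0])
    once = normalize_channels(table, LABELS)
    twice = normalize_channels(once, LABELS)
    for col in ("intensity_114", "intensity_117"):
        assert np.allclose(once[col], twice[col])


def test_zero_total_channel_named():
    table = _two_peptide_table([0.0, 0.0], [900.0, 1100.0])
    with pytest.raises(NormalizationError, match="114"):
        normalize_channels(table, LABELS)


def test_only_contributing_rows_set_scalars():
    """Low-score and non-unique rows are scaled but do not drive the fit."""
    table = _two_peptide_table([400.0, 600.0], [900.0, 1100.0])
    extra = _two_peptide_table([1e6], [1.0])
    extra["score"] = 10.0  # below threshold: must not affect scalars
    combined = pd.concat([table, extra], ignore_index=True)
    out = normalize_channels(combined, LABELS)
    assert np.allclose(out.loc[:1, "intensity_114"],
                       table["intensity_114"] * 1.5)


def test_median_method_centers_log_ratios():
    evidence = cdk6_evidence()
    evidence["stage"] = "corrected"
    out = normalize_channels(evidence, LABELS, method="median")
    logr = np.log(out["intensity_114"] / out["intensity_117"])
    assert np.median(logr) == pytest.approx(0.0, abs=1e-9)
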