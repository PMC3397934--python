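"""Peptide-to-protein rollup, the two-criterion calling rule, and the
catalog summaries."""

import numpy as np
import pytest

from kinoquant import (
    NoiseModel,
    SimulationConfig,
    aggregate_protein,
    call_differential,
    rf_distribution,
    summarize_kinome,
)
from kinoquant.datasets import cdk6_evidence, cdk6_peptides
from kinoquant.errors import AggregationError
from kinoquant.likelihood import attach_likelihoods
from kinoquant.pipeline import truth_frame
from kinoquant.protein import signed_median
from kinoquant.simulate import simulate_truth


# -- aggregation ------------------------------------------------------------


def test_cdk6_rollup_reproduces_printed_protein_rf():
    table = cdk6_peptides()
    reg = aggregate_protein("CDK6", table["signed_rf"].tolist(),
                            scores=table["score"].tolist())
    assert round(reg.protein_rf, 1) == -3.7
    assert reg.n_peptides == 12
    assert reg.total_score == pytest.approx(609.0)
    assert not reg.sign_conflict


def test_singleton_rollup_is_identity():
    reg = aggregate_protein("P", [-2.0])
    assert reg.protein_rf == -2.0


def test_conflicting_signs_snap_to_positive_unity_with_flag():
    reg = aggregate_protein("P", [2.0, -2.0])
    assert reg.protein_rf == 1.0
    assert reg.sign_conflict


def test_empty_peptide_list_rejected():
    with pytest.raises(AggregationError):
        aggregate_protein("P", [])


def test_combined_curve_multiplies_peptide_evidence():
    evidence = cdk6_evidence()
    noise = NoiseModel(1.0, 0.05)
    out, curves = attach_likelihoods(evidence, {"Treg": 114, "Teff": 117}, noise)
    reg = aggregate_protein("CDK6", out["signed_rf"].tolist(),
                            curves=list(curves.values()))
    combined = reg.combined_curve
    assert combined.rel_likelihood.max() <= 1.0 + 1e-12
    assert combined.excludes_unity
    # combined evidence is at least as concentrated as any single peptide
    assert combined.rel_at_unity <= min(c.rel_at_unity for c in curves.values())
    assert combined.mle_ratio == pytest.approx(1 / 3.69, rel=0.05)


# -- calling rule -----------------------------------------------------------


@pytest.mark.parametrize(
    "rfs,expected",
    [
        ([-3.6, -3.9, -3.4, -3.9], "down"),
        ([1.6, 1.4, 1.3, 1.2], "unchanged"),  # only one experiment >= 1.5
        ([1.6, 1.6, -1.6, 1.0], "unchanged"),  # median 1.3 below threshold
        ([-3.7, -3.1, -2.9, -3.2], "down"),
        ([1.6, 1.6, 1.0, 1.0], "unchanged"),  # median (1.0+1.6)/2 = 1.3
    ],
)
def test_calling_rule_examples(rfs, expected):
    assert call_differential(rfs).call == expected


def test_signed_median_even_count_snaps_into_convention():
    value, snapped = signed_median([-1.2, 1.4])
    assert value == 1.0 and snapped
    value, snapped = signed_median([1.6, 1.0, -1.6, 1.6])
    assert value == pytest.approx(1.3) and not snapped


def test_missing_experiments_excluded_from_median():
    call = call_differential([None, -3.0, -2.5, None], n_experiments=4)
    assert call.call == "down"
    assert call.median_rf == pytest.approx(-2.75)
    assert call.per_experiment_symbol == [None, "-", "-", None]
    single = call_differential([None, -3.0, None, None], n_experiments=4)
    assert single.call == "unchanged"  # min_experiments = 2 unsatisfiable


def test_threshold_is_inclusive():
    assert call_differential([-1.5, -1.5]).call == "down"
    assert call_differential([1.5, 1.5]).call == "up"
    assert call_differential([1.49, 1.49]).call == "unchanged"


# -- summaries --------------------------------------------------------------


def _fake_calls(medians):
    return [call_differential([m], min_experiments=1) for m in medians]


def test_fraction_kinases_and_score_contrast():
    truth = truth_frame(simulate_truth(SimulationConfig(seed=2, n_proteins=100,
                                                        frac_kinases=0.4)))
    calls = _fake_calls([1.0] * 100)
    for call, pid in zip(calls, truth["protein_id"]):
        call.protein_id = pid
    scores = dict.fromkeys(truth["protein_id"], 42.0)
    summary = summarize_kinome(calls, truth, scores=scores)
    assert summary["fraction_kinases"] == pytest.approx(0.40)
    assert summary["mean_score_kinases"] == summary["mean_score_others"] == 42.0
    assert summary["call_counts"]["unchanged"] == 100


def test_group_counts_follow_uniform_draws():
    config = SimulationConfig(seed=8, n_proteins=1000, frac_kinases=1.0,
                              frac_npk=0.0)
    truth = truth_frame(simulate_truth(config))
    counts = truth["kinase_group"].value_counts()
    expected = 1000 / 10
    sigma = np.sqrt(1000 * 0.1 * 0.9)
    assert set(counts.index) <= set(
        ("AGC", "CAMK", "CK1", "CMGC", "RGC", "STE", "TK", "TKL",
         "Atypical", "Other")
    )
    assert all(abs(c - expected) <= 3 * sigma for c in counts)


def test_unannotated_protein_listed_unknown():
    calls = _fake_calls([1.0])
    calls[0].protein_id = "MYSTERY"
    truth = truth_frame(simulate_truth(SimulationConfig(seed=1, n_proteins=5)))
    summary = summarize_kinome(calls, truth)
    assert summary["group_counts"]["unknown"] == 1


def test_rf_distribution_bins():
    values, counts, edges = rf_distribution(_fake_calls([1.0, 1.0, 1.0]))
    assert np.allclose(values, 0.0)
    assert counts.sum() == 3
    values, _, _ = rf_distribution(_fake_calls([2.0, -2.0]))
    assert sorted(values) == [-1.0, 1.0]


def test_rf_distribution_null_centers_at_zero():
    rng = np.random.default_rng(6)
    ratios = np.exp(rng.normal(0.0, 0.1, 400))
    medians = [r if r >= 1 else -1 / r for r in ratios]
    values, _, _ = rf_distribution(_fake_calls(medians))
    se = values.std(ddof=1) / np.sqrt(len(values))
    assert abs(values.mean()) < 3 * se
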