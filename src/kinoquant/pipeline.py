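"""Glue between spectra, identification tables and the model layer.

These helpers implement the seams the command line exposes: building a
raw evidence table from spectra + identifications, quantifying one
experiment end to end, and generating in-memory evidence tables straight
from the simulator for testing and calibration studies.
"""

from __future__ import annotations

import pandas as pd

from . import constants as C
from .config import AnalysisConfig, SimulationConfig
from .errors import ValidationError
from .io import INTENSITY_COLS, ReporterSpectrum
from .likelihood import RatioGrid, attach_likelihoods, fit_noise_from_unregulated
from .likelihood import NoiseModel
from .preprocess import correct_evidence, extract_reporters, normalize_channels
from .simulate import TruthRecord, simulate_experiment


def truth_frame(truth: list[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": t.protein_id,
                "is_kinase": t.is_kinase,
                "kinase_group": t.kinase_group,
                "true_signed_rf": t.true_signed_rf,
            }
            for t in truth
        ]
    )


def build_evidence(
    spectra: list[ReporterSpectrum],
    ids: pd.DataFrame,
    tolerance: float = C.DEFAULT_REPORTER_TOLERANCE_DA,
) -> pd.DataFrame:
    """Join spectra with identifications into a raw evidence table.

    Every identification row must reference a spectrum; reporter
    intensities are extracted from the spectrum's reporter region.
    """
    by_id = {sp.spectrum_id: sp for sp in spectra}
    rows = []
    for rec in ids.to_dict("records"):
        sp = by_id.get(rec["spectrum_id"])
        if sp is None:
            raise ValidationError(
                f"identification references unknown spectrum {rec['spectrum_id']!r}"
            )
        channels = extract_reporters(sp, tolerance=tolerance)
        row = dict(rec)
        for ch in C.CHANNELS:
            row[f"intensity_{ch}"] = channels[ch]
        rows.append(row)
    cols = list(ids.columns) + list(INTENSITY_COLS)
    out = pd.DataFrame(rows, columns=cols)
    out["stage"] = "raw"
    return out


def quantify_experiment(
    spectra: list[ReporterSpectrum],
    ids: pd.DataFrame,
    config: AnalysisConfig,
    experiment_index: int,
) -> tuple[pd.DataFrame, dict, NoiseModel, dict]:
    """Raw inputs -> normalized evidence with signed RFs and flags.

    Returns ``(evidence, curves, noise_model, stats)`` where stats counts
    spectra, unique peptides and exclusions for logging.
    """
    if experiment_index >= len(config.label_assignments):
        raise ValidationError(
            f"no label assignment for experiment {experiment_index + 1}"
        )
    labels = config.label_assignments[experiment_index]
    evidence = build_evidence(spectra, ids, tolerance=config.reporter_tolerance_da)
    evidence = correct_evidence(evidence, config.purity_matrix)
    evidence = normalize_channels(
        evidence, labels, method=config.normalization, score_min=config.score_min
    )
    if config.noise_sigma0 is not None and config.noise_c is not None:
        noise = NoiseModel(config.noise_sigma0, config.noise_c)
    else:
        noise = fit_noise_from_unregulated(evidence, labels,
                                           score_min=config.score_min)
    grid = RatioGrid(*config.ratio_grid_bounds, config.ratio_grid_points)
    evidence, curves = attach_likelihoods(
        evidence, labels, noise, grid=grid,
        alpha=config.likelihood_exclusion_alpha, score_min=config.score_min,
    )
    stats = {
        "n_spectra": len(spectra),
        "n_identifications": len(ids),
        "n_unique": int(evidence["is_unique"].sum()),
        "n_quantified": int(evidence["signed_rf"].notna().sum()),
        "n_excluded": int(evidence["signed_rf"].isna().sum()),
    }
    return evidence, curves, noise, stats


def simulate_evidence_tables(
    sim: SimulationConfig,
    tolerance: float = C.DEFAULT_REPORTER_TOLERANCE_DA,
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Generate all experiments of a study as raw evidence tables.

    Runs the full simulator (spectra + identifications) and the reporter
    extraction front-end, returning one raw evidence table per experiment
    plus the shared truth table.
    """
    tables = []
    truth_df = None
    for i in range(sim.n_experiments):
        spectra, ids, truth = simulate_experiment(sim, i)
        tables.append(build_evidence(spectra, ids, tolerance=tolerance))
        if truth_df is None:
            truth_df = truth_frame(truth)
    return tables, truth_df
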