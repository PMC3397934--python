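"""Synthetic 4-plex kinome experiments with known ground truth.

The generator emulates the data the analysis pipeline expects from a
two-condition (Treg vs. Teff) isobaric-labeling study:

* a catalog of affinity-enriched proteins, a configurable fraction of which
  are kinases annotated with Manning groups (non-kinases score lower on the
  identification scale, mimicking the enrichment quality seen in
  kinase-selective pulldowns);
* a fixed subset of truly regulated proteins with signed regulation
  factors (RF = Treg/Teff, reciprocals written as negative values);
* several unique tryptic-like peptides per protein, with log-normally
  distributed base intensities shared by the two channels of a spectrum;
* reporter intensities formed by placing the Treg/Teff signal on the
  experiment's assigned channels, mixing through a 4x4 label purity
  matrix, and adding zero-truncated Gaussian noise with standard
  deviation ``sigma0 + c * I``;
* standard MGF output with reporter ions at the canonical 4-plex masses
  plus a few backbone fragment peaks, and a matching identification table.

The same :class:`~kinoquant.config.SimulationConfig` seed always produces
byte-identical outputs; the protein-level truth is shared by all
experiments of a study so that cross-experiment calling can be scored
against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pyteomics import mass as _pymass

from . import constants as C
from .config import SimulationConfig
from .errors import ConfigError
from .io import ReporterSpectrum
from .likelihood import signed_to_ratio

_AMINO_ACIDS = "ACDEFGHIKLMNPQSTVWY"  # tryptic interior (no R/K until the end)


@dataclass
class TruthRecord:
    """Ground truth for one simulated protein."""

    protein_id: str
    is_kinase: bool
    kinase_group: str
    true_signed_rf: float

    def __post_init__(self) -> None:
        if abs(self.true_signed_rf) < 1:
            raise ValueError("signed RF convention has no values in (-1, 1)")
        if (self.kinase_group == "none") == self.is_kinase:
            raise ValueError("kinase_group must be 'none' iff not a kinase")


def _truth_rng(config: SimulationConfig) -> np.random.Generator:
    # child 0 of the study seed: truth shared across experiments
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])


def simulate_truth(config: SimulationConfig) -> list[TruthRecord]:
    """Draw the study-level protein catalog and regulation truth."""
    rng = _truth_rng(config)
    n = config.n_proteins
    n_kinase = int(round(config.frac_kinases * n))
    n_regulated = int(config.frac_regulated * n + 0.5)
    is_kinase = np.zeros(n, dtype=bool)
    is_kinase[rng.choice(n, size=n_kinase, replace=False)] = True

    groups = np.full(n, "none", dtype=object)
    kin_idx = np.nonzero(is_kinase)[0]
    for i in kin_idx:
        if rng.random() < config.frac_npk:
            groups[i] = "NPK"
        else:
            groups[i] = C.PROTEIN_KINASE_GROUPS[
                rng.integers(len(C.PROTEIN_KINASE_GROUPS))
            ]

    # regulation preferentially hits kinases (the biology the study targets)
    pool = kin_idx if len(kin_idx) >= n_regulated else np.arange(n)
    reg_idx = rng.choice(pool, size=n_regulated, replace=False)
    lo, hi = config.regulation_magnitude_range
    signed = np.ones(n)
    for i in reg_idx:
        magnitude = rng.uniform(lo, hi)
        signed[i] = magnitude if rng.random() < 0.5 else -magnitude

    records = []
    for i in range(n):
        prefix = "KIN" if is_kinase[i] else "PRT"
        records.append(
            TruthRecord(
                protein_id=f"{prefix}{i:04d}",
                is_kinase=bool(is_kinase[i]),
                kinase_group=str(groups[i]),
                true_signed_rf=float(signed[i]),
            )
        )
    return records


def _random_peptide(rng: np.random.Generator, taken: set[str]) -> str:
    while True:
        length = int(rng.integers(6, 16))
        body = "".join(_AMINO_ACIDS[j] for j in rng.integers(len(_AMINO_ACIDS), size=length))
        seq = body + ("K" if rng.random() < 0.5 else "R")
        if seq not in taken:
            taken.add(seq)
            return seq


def _backbone_peaks(seq: str, rng: np.random.Generator) -> list[tuple[float, float]]:
    """A few y-ion peaks so spectra are not reporter-only (ignored downstream)."""
    peaks = []
    for k in range(2, min(len(seq), 6)):
        mz = _pymass.fast_mass(seq[-k:], ion_type="y", charge=1)
        peaks.append((float(mz), float(rng.uniform(50, 500))))
    return peaks


def simulate_experiment(
    config: SimulationConfig, experiment_index: int
) -> tuple[list[ReporterSpectrum], pd.DataFrame, list[TruthRecord]]:
    """Generate one experiment's spectra, identification table and truth.

    The truth list is the study-level truth (identical for every
    ``experiment_index`` of the same config).
    """
    if not 0 <= experiment_index < config.n_experiments:
        raise ConfigError(
            f"experiment_index {experiment_index} outside 0..{config.n_experiments - 1}"
        )
    labels = config.label_assignments[experiment_index]
    treg_ch, teff_ch = labels["Treg"], labels["Teff"]
    truth = simulate_truth(config)

    ss = np.random.SeedSequence(config.seed).spawn(config.n_experiments + 1)
    rng = np.random.default_rng(ss[experiment_index + 1])
    purity_t = config.purity_matrix.T  # observed = purity^T @ true
    ch_index = {ch: i for i, ch in enumerate(C.CHANNELS)}
    reporter_mz = np.array([C.REPORTER_MZ[ch] for ch in C.CHANNELS])

    spectra: list[ReporterSpectrum] = []
    id_rows = []
    taken: set[str] = set()
    scan = 0
    for rec in truth:
        plo, phi = config.peptides_per_protein
        n_pep = int(rng.integers(plo, phi + 1))
        ratio = signed_to_ratio(rec.true_signed_rf)
        for _ in range(n_pep):
            seq = _random_peptide(rng, taken)
            scan += 1
            base = float(np.exp(rng.normal(config.base_intensity_log_mean,
                                           config.base_intensity_log_sd)))
            true_vec = np.zeros(4)
            true_vec[ch_index[teff_ch]] = base
            true_vec[ch_index[treg_ch]] = base * ratio
            mixed = purity_t @ true_vec
            sigma = config.noise_sigma0 + config.noise_c * mixed
            noise = rng.normal(0.0, 1.0, size=4) * sigma
            observed = np.clip(mixed + noise, 0.0, None)

            spectrum_id = f"exp{experiment_index + 1}.scan{scan:05d}.{seq}"
            jitter = np.clip(rng.normal(0.0, 0.004, size=4), -0.015, 0.015)
            peaks = [
                (float(reporter_mz[i] + jitter[i]), float(observed[i]))
                for i in range(4)
                if observed[i] > 0
            ]
            peaks.extend(_backbone_peaks(seq, rng))
            precursor = float(_pymass.fast_mass(seq, charge=2))
            spectra.append(
                ReporterSpectrum(
                    spectrum_id=spectrum_id,
                    peaks=np.array(peaks) if peaks else np.empty((0, 2)),
                    precursor_mz=precursor,
                    charge=2,
                )
            )
            if rec.is_kinase:
                score = max(8.0, rng.normal(55.0, 18.0))
            else:
                score = max(8.0, rng.normal(35.0, 12.0))
            id_rows.append(
                {
                    "spectrum_id": spectrum_id,
                    "peptide_sequence": seq,
                    "protein_id": rec.protein_id,
                    "score": round(float(score), 1),
                    "is_unique": bool(rng.random() >= config.frac_nonunique),
                }
            )
    ids = pd.DataFrame(id_rows, columns=list(
        ("spectrum_id", "peptide_sequence", "protein_id", "score", "is_unique")))
    return spectra, ids, truth
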