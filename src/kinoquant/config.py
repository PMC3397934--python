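"""Configuration objects and their YAML (de)serialization.

A single YAML file configures both the synthetic-data generator and the
analysis pipeline.  Fixed keys::

    reporter_tolerance_da, purity_matrix, noise_sigma0, noise_c,
    rf_threshold, min_regulated_experiments, likelihood_exclusion_alpha,
    label_assignments

plus a ``simulation:`` block for generator parameters.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import constants as C
from .errors import ConfigError


def _check_label_assignments(assignments) -> list[dict[str, int]]:
    out = []
    for i, amap in enumerate(assignments):
        if set(amap) != {"Treg", "Teff"}:
            raise ConfigError(
                f"label assignment {i}: expected keys Treg/Teff, got {sorted(amap)}"
            )
        treg, teff = int(amap["Treg"]), int(amap["Teff"])
        for ch in (treg, teff):
            if ch not in C.CHANNELS:
                raise ConfigError(f"label assignment {i}: channel {ch} not in {C.CHANNELS}")
        if treg == teff:
            raise ConfigError(f"label assignment {i}: Treg and Teff share channel {treg}")
        out.append({"Treg": treg, "Teff": teff})
    return out


def _check_purity(matrix) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.shape != (4, 4):
        raise ConfigError(f"purity matrix must be 4x4, got {m.shape}")
    if (m < 0).any() or (m > 1).any():
        raise ConfigError("purity matrix entries must lie in [0, 1]")
    if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
        raise ConfigError("purity matrix rows must sum to 1 within 1e-9")
    if not np.isfinite(np.linalg.cond(m)) or np.linalg.cond(m) > 1e12:
        raise ConfigError("purity matrix is singular or ill-conditioned")
    return m


@dataclass
class SimulationConfig:
    """Parameters of the synthetic kinome-experiment generator.

    Defaults describe a study of 200 affinity-enriched proteins of which
    40% are kinases, 5% of proteins truly regulated with signed
    regulation factors of magnitude 2–5, observed in four 4-plex runs with
    rotating condition/channel assignments.
    """

    n_proteins: int = 200
    frac_kinases: float = 0.40
    frac_npk: float = 0.08  # fraction of kinases with non-protein substrates
    frac_regulated: float = 0.05
    regulation_magnitude_range: tuple[float, float] = (2.0, 5.0)
    peptides_per_protein: tuple[int, int] = (3, 10)
    base_intensity_log_mean: float = 7.0
    base_intensity_log_sd: float = 1.0
    noise_sigma0: float = 5.0
    noise_c: float = 0.05
    purity_matrix: np.ndarray = field(default_factory=C.identity_purity_matrix)
    n_experiments: int = 4
    label_assignments: list[dict[str, int]] = field(
        default_factory=lambda: [dict(a) for a in C.DEFAULT_LABEL_ASSIGNMENTS]
    )
    frac_nonunique: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_kinases", "frac_npk", "frac_regulated", "frac_nonunique"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sigma0 < 0 or self.noise_c < 0:
            raise ConfigError("noise parameters must be >= 0")
        lo, hi = self.regulation_magnitude_range
        if not (1.0 <= lo <= hi):
            raise ConfigError("regulation magnitudes must satisfy 1 <= lo <= hi")
        plo, phi = self.peptides_per_protein
        if not (1 <= plo <= phi):
            raise ConfigError("peptides_per_protein must satisfy 1 <= lo <= hi")
        if self.n_proteins < 1 or self.n_experiments < 1:
            raise ConfigError("n_proteins and n_experiments must be positive")
        self.purity_matrix = _check_purity(self.purity_matrix)
        self.label_assignments = _check_label_assignments(self.label_assignments)
        if len(self.label_assignments) < self.n_experiments:
            raise ConfigError(
                f"{self.n_experiments} experiments but only "
                f"{len(self.label_assignments)} label assignments"
            )


@dataclass
class AnalysisConfig:
    """Parameters of the quantification/calling pipeline."""

    reporter_tolerance_da: float = C.DEFAULT_REPORTER_TOLERANCE_DA
    purity_matrix: np.ndarray = field(default_factory=C.identity_purity_matrix)
    #: noise model used by the likelihood; None means calibrate from the data
    noise_sigma0: float | None = None
    noise_c: float | None = None
    rf_threshold: float = C.DEFAULT_RF_THRESHOLD
    min_regulated_experiments: int = C.DEFAULT_MIN_REGULATED_EXPERIMENTS
    likelihood_exclusion_alpha: float = C.DEFAULT_EXCLUSION_ALPHA
    score_min: float = C.DEFAULT_SCORE_MIN
    normalization: str = "total"  # "total" | "median" | "none"
    ratio_grid_bounds: tuple[float, float] = (1.0 / 50.0, 50.0)
    ratio_grid_points: int = 400
    label_assignments: list[dict[str, int]] = field(
        default_factory=lambda: [dict(a) for a in C.DEFAULT_LABEL_ASSIGNMENTS]
    )

    def __post_init__(self) -> None:
        if not 0 < self.reporter_tolerance_da <= 0.5:
            raise ConfigError("reporter_tolerance_da must lie in (0, 0.5]")
        if self.normalization not in ("total", "median", "none"):
            raise ConfigError(f"unknown normalization {self.normalization!r}")
        if not 0 < self.likelihood_exclusion_alpha < 1:
            raise ConfigError("likelihood_exclusion_alpha must lie in (0, 1)")
        if self.rf_threshold < 1:
            raise ConfigError("rf_threshold must be >= 1 on the signed-RF scale")
        self.purity_matrix = _check_purity(self.purity_matrix)
        self.label_assignments = _check_label_assignments(self.label_assignments)


def _to_plain(obj):
    if isinstance(obj, np.ndarray):
        return [[float(x) for x in row] for row in obj]
    if isinstance(obj, tuple):
        return [_to_plain(x) for x in obj]
    if isinstance(obj, list):
        return [_to_plain(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def to_dict(sim: SimulationConfig | None, ana: AnalysisConfig | None) -> dict:
    out: dict = {}
    if ana is not None:
        out.update(_to_plain(dataclasses.asdict(ana)))
    if sim is not None:
        out["simulation"] = _to_plain(dataclasses.asdict(sim))
    return out


def save_config(path, sim: SimulationConfig | None = None,
                ana: AnalysisConfig | None = None) -> None:
    Path(path).write_text(yaml.safe_dump(to_dict(sim, ana), sort_keys=True))


def load_config(path) -> tuple[SimulationConfig, AnalysisConfig]:
    """Load a YAML config file; absent keys fall back to defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    sim_raw = raw.pop("simulation", {}) or {}
    sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    ana_fields = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - ana_fields
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    unknown = set(sim_raw) - sim_fields
    if unknown:
        raise ConfigError(f"{path}: unknown simulation keys {sorted(unknown)}")

    def _tupled(d, *names):
        for n in names:
            if n in d and d[n] is not None:
                d[n] = tuple(d[n])

    _tupled(sim_raw, "regulation_magnitude_range", "peptides_per_protein")
    _tupled(raw, "ratio_grid_bounds")
    sim = SimulationConfig(**sim_raw)
    ana = AnalysisConfig(**raw)
    return sim, ana


def config_hash(sim: SimulationConfig | None, ana: AnalysisConfig | None) -> str:
    """Short stable digest of a configuration, for output provenance."""
    text = yaml.safe_dump(to_dict(sim, ana), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]
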