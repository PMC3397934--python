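"""The modelling front door: :class:`KinomeQuant` and its results object.

``KinomeQuant`` is constructed from one peptide-evidence table per
experiment (plus the experiment's condition→channel maps) and ``fit()``
runs the estimation chain — impurity correction if needed, channel
normalization, noise calibration, per-peptide likelihood curves, protein
rollup and cross-experiment differential calling — returning a
:class:`KinomeQuantResults` carrying the estimates, their likelihood
curves, the calls and a text ``summary()``.

Example
-------
>>> from kinoquant import KinomeQuant, SimulationConfig
>>> from kinoquant.pipeline import simulate_evidence_tables
>>> tables, truth = simulate_evidence_tables(SimulationConfig(seed=3))
>>> res = KinomeQuant(tables).fit()
>>> res.calls_frame.head()
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import constants as C
from . import io as kio
from .config import AnalysisConfig
from .errors import ValidationError
from .likelihood import (
    NoiseModel,
    RatioGrid,
    attach_likelihoods,
    fit_noise_from_unregulated,
)
from .preprocess import correct_evidence, normalize_channels
from .protein import (
    DifferentialCall,
    ProteinRegulation,
    aggregate_protein,
    call_differential,
    rf_distribution,
    summarize_kinome,
)


class KinomeQuant:
    """Differential kinase-expression model over N 4-plex experiments.

    Parameters
    ----------
    evidence_tables
        One evidence DataFrame (``kinoquant.io`` schema) per experiment,
        at any stage: raw tables are impurity-corrected with the
        configured purity matrix, then normalized.
    config
        :class:`~kinoquant.config.AnalysisConfig`; defaults follow the
        four-run reference design.  ``config.noise_sigma0/noise_c`` of
        ``None`` means the noise model is calibrated from each
        experiment's own unregulated peptides.
    """

    def __init__(
        self,
        evidence_tables: list[pd.DataFrame],
        config: AnalysisConfig | None = None,
    ) -> None:
        if not evidence_tables:
            raise ValidationError("need at least one evidence table")
        self.config = config or AnalysisConfig()
        if len(evidence_tables) > len(self.config.label_assignments):
            raise ValidationError(
                f"{len(evidence_tables)} experiments but only "
                f"{len(self.config.label_assignments)} label assignments"
            )
        self.evidence_tables = list(evidence_tables)

    @classmethod
    def from_files(cls, paths, config: AnalysisConfig | None = None) -> "KinomeQuant":
        return cls([kio.read_evidence(p) for p in paths], config=config)

    # -- fitting ----------------------------------------------------------

    def _prepare(self, table: pd.DataFrame, labels) -> pd.DataFrame:
        cfg = self.config
        if len(table) and table["stage"].iloc[0] == "raw":
            table = correct_evidence(table, cfg.purity_matrix)
        if len(table) and table["stage"].iloc[0] != "normalized":
            table = normalize_channels(
                table, labels, method=cfg.normalization, score_min=cfg.score_min
            )
        return table

    def _noise_for(self, table: pd.DataFrame, labels) -> NoiseModel:
        cfg = self.config
        if cfg.noise_sigma0 is not None and cfg.noise_c is not None:
            return NoiseModel(cfg.noise_sigma0, cfg.noise_c)
        return fit_noise_from_unregulated(table, labels, score_min=cfg.score_min)

    def fit(self, require_exclusion: bool = True) -> "KinomeQuantResults":
        """Run the full estimation chain and return the results object."""
        cfg = self.config
        grid = RatioGrid(*cfg.ratio_grid_bounds, cfg.ratio_grid_points)
        peptide_tables: list[pd.DataFrame] = []
        noise_models: list[NoiseModel] = []
        regulations: dict[str, list[ProteinRegulation | None]] = {}
        n_exp = len(self.evidence_tables)

        for i, raw in enumerate(self.evidence_tables):
            labels = cfg.label_assignments[i]
            table = self._prepare(raw, labels)
            noise = self._noise_for(table, labels)
            noise_models.append(noise)
            table, curves = attach_likelihoods(
                table, labels, noise, grid=grid,
                alpha=cfg.likelihood_exclusion_alpha, score_min=cfg.score_min,
            )
            peptide_tables.append(table)
            quantified = table.index[table["signed_rf"].notna()]
            for protein_id, rows in table.loc[quantified].groupby("protein_id"):
                reg = aggregate_protein(
                    str(protein_id),
                    rows["signed_rf"].tolist(),
                    curves=[curves[ix] for ix in rows.index],
                    scores=rows["score"].tolist(),
                    experiment_index=i,
                    alpha=cfg.likelihood_exclusion_alpha,
                )
                regulations.setdefault(str(protein_id), [None] * n_exp)[i] = reg

        calls = [
            call_differential(
                regs,
                threshold=cfg.rf_threshold,
                min_experiments=cfg.min_regulated_experiments,
                require_exclusion=require_exclusion,
                n_experiments=n_exp,
            )
            for regs in regulations.values()
        ]
        calls.sort(key=lambda c: c.protein_id)
        return KinomeQuantResults(
            model=self,
            peptide_tables=peptide_tables,
            noise_models=noise_models,
            regulations=regulations,
            calls=calls,
        )


@dataclass
class KinomeQuantResults:
    """Fitted estimates, curves, calls and summaries."""

    model: KinomeQuant
    peptide_tables: list[pd.DataFrame]
    noise_models: list[NoiseModel]
    regulations: dict[str, list[ProteinRegulation | None]]
    calls: list[DifferentialCall]
    _calls_frame: pd.DataFrame | None = field(default=None, repr=False)

    # -- tabular views ----------------------------------------------------

    @property
    def calls_frame(self) -> pd.DataFrame:
        """One row per protein: per-experiment RFs, symbols, median, call."""
        if self._calls_frame is None:
            n_exp = len(self.peptide_tables)
            rows = []
            for c in self.calls:
                row = {"protein_id": c.protein_id}
                for i in range(n_exp):
                    row[f"rf_exp{i + 1}"] = (
                        np.nan if c.per_experiment_rf[i] is None
                        else c.per_experiment_rf[i]
                    )
                    row[f"sym_exp{i + 1}"] = c.per_experiment_symbol[i] or "NA"
                row["median_rf"] = c.median_rf
                row["call"] = c.call
                row["n_regulated_experiments"] = c.n_regulated_experiments
                rows.append(row)
            self._calls_frame = pd.DataFrame(rows)
        return self._calls_frame

    @property
    def protein_frame(self) -> pd.DataFrame:
        """Per protein × experiment regulation estimates."""
        rows = []
        for protein_id, regs in sorted(self.regulations.items()):
            for reg in regs:
                if reg is None:
                    continue
                rows.append(
                    {
                        "protein_id": protein_id,
                        "experiment": reg.experiment_index + 1,
                        "protein_rf": reg.protein_rf,
                        "n_peptides": reg.n_peptides,
                        "total_score": reg.total_score,
                        "excludes_unity": reg.excludes_unity,
                        "sign_conflict": reg.sign_conflict,
                    }
                )
        return pd.DataFrame(rows)

    def protein_scores(self) -> dict[str, float]:
        """Mean per-experiment total identification score per protein."""
        out: dict[str, float] = {}
        for protein_id, regs in self.regulations.items():
            vals = [r.total_score for r in regs if r is not None
                    and np.isfinite(r.total_score)]
            if vals:
                out[protein_id] = float(np.mean(vals))
        return out

    # -- summaries --------------------------------------------------------

    def kinome_summary(self, annotation: pd.DataFrame) -> dict:
        return summarize_kinome(self.calls, annotation, scores=self.protein_scores())

    def rf_histogram(self, bins=None):
        return rf_distribution(self.calls, bins=bins)

    def save_results(self, path, annotation: dict | None = None,
                     provenance: dict | None = None) -> None:
        kio.write_results(self.calls, path, annotation=annotation,
                          provenance=provenance)

    def summary(self, max_rows: int = 30) -> str:
        """Human-readable fit report."""
        n_exp = len(self.peptide_tables)
        n_pep = sum(int(t["signed_rf"].notna().sum()) for t in self.peptide_tables)
        counts = {"up": 0, "down": 0, "unchanged": 0}
        for c in self.calls:
            counts[c.call] += 1
        lines = [
            "Kinome differential expression (RF = Treg/Teff)",
            "=" * 55,
            f"Experiments:            {n_exp}",
            f"Quantified proteins:    {len(self.calls)}",
            f"Quantified peptides:    {n_pep}",
            "Noise models:           "
            + "; ".join(
                f"exp{i + 1}: sigma0={nm.sigma0:.2f}, c={nm.c:.4f}"
                for i, nm in enumerate(self.noise_models)
            ),
            f"Calls:                  {counts['down']} down, "
            f"{counts['up']} up, {counts['unchanged']} unchanged",
            "",
        ]
        regulated = [c for c in self.calls if c.call != "unchanged"]
        if regulated:
            lines.append(
                f"{'protein':<12}" + "".join(f"{f'RF e{i+1}':>9}" for i in range(n_exp))
                + f"{'median':>9}  call"
            )
            lines.append("-" * (12 + 9 * (n_exp + 1) + 6))
            for c in regulated[:max_rows]:
                cells = "".join(
                    f"{'':>9}" if rf is None else f"{rf:>9.1f}"
                    for rf in c.per_experiment_rf
                )
                lines.append(
                    f"{c.protein_id:<12}{cells}{c.median_rf:>9.1f}  {c.call}"
                )
        return "\n".join(lines)
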