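"""Shared constants: reporter channels, canonical m/z values, kinase taxonomy."""

from __future__ import annotations

import numpy as np

#: The four iTRAQ 4-plex reporter channels, by nominal mass.
CHANNELS: tuple[int, ...] = (114, 115, 116, 117)

#: Canonical monoisotopic m/z of the 4-plex reporter ions (Da).
REPORTER_MZ: dict[int, float] = {
    114: 114.1112,
    115: 115.1083,
    116: 116.1116,
    117: 117.1150,
}

#: Default extraction window half-width around each reporter m/z (Da).
DEFAULT_REPORTER_TOLERANCE_DA = 0.05

#: Mascot-style peptide identification score threshold for quantification.
DEFAULT_SCORE_MIN = 20.0

#: Signed regulation-factor threshold for a per-experiment call symbol.
DEFAULT_RF_THRESHOLD = 1.5

#: Minimum number of experiments with a non-zero symbol for a differential call.
DEFAULT_MIN_REGULATED_EXPERIMENTS = 2

#: Relative-likelihood level below which a curve "excludes unity" (RF = 1).
DEFAULT_EXCLUSION_ALPHA = 0.05

#: Per-experiment condition → channel maps of a four-run reference design.
DEFAULT_LABEL_ASSIGNMENTS: tuple[dict[str, int], ...] = (
    {"Treg": 114, "Teff": 117},
    {"Treg": 115, "Teff": 114},
    {"Treg": 116, "Teff": 114},
    {"Treg": 117, "Teff": 114},
)

#: Manning kinase-group taxonomy used for catalog annotation.  NPK marks
#: kinases whose substrates are not proteins; "none" marks non-kinases.
PROTEIN_KINASE_GROUPS: tuple[str, ...] = (
    "AGC", "CAMK", "CK1", "CMGC", "RGC", "STE", "TK", "TKL", "Atypical", "Other",
)
KINASE_GROUPS: tuple[str, ...] = PROTEIN_KINASE_GROUPS + ("NPK",)
ALL_GROUPS: tuple[str, ...] = KINASE_GROUPS + ("none",)


def identity_purity_matrix() -> np.ndarray:
    """4x4 purity matrix of perfectly clean labels."""
    return np.eye(4)


def example_purity_matrix() -> np.ndarray:
    """A realistic 4-plex purity matrix (rows: true label, cols: observed).

    Each label leaks a few percent of its signal into the -1/+1 Da
    neighbouring reporter masses and a trace into +2 Da, the pattern
    produced by the isotope envelopes of the label reagents.  Rows sum to 1.
    """
    m = np.array(
        [
            [0.929, 0.059, 0.002, 0.000],
            [0.020, 0.923, 0.056, 0.001],
            [0.000, 0.030, 0.924, 0.045],
            [0.000, 0.001, 0.040, 0.924],
        ]
    )
    # fold the off-grid leakage back onto the diagonal so rows sum to 1
    m[np.arange(4), np.arange(4)] += 1.0 - m.sum(axis=1)
    return m
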