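import numpy as np
import pandas as pd
import pytest

from kinoquant import SimulationConfig


@pytest.fixture
def small_sim() -> SimulationConfig:
    """A fast two-experiment study for structural tests."""
    return SimulationConfig(
        seed=42,
        n_proteins=30,
        frac_regulated=0.1,
        n_experiments=2,
        peptides_per_protein=(2, 5),
    )


@pytest.fixture
def noise_free_sim() -> SimulationConfig:
    """Noise-free, identity-purity study: observed ratios are exact."""
    return SimulationConfig(
        seed=7,
        n_proteins=20,
        frac_regulated=0.2,
        n_experiments=2,
        peptides_per_protein=(2, 4),
        noise_sigma0=0.0,
        noise_c=0.0,
    )


def make_null_evidence(n: int, sigma0: float, c: float, seed: int,
                       scale: float = 1.0,
                       labels=None) -> pd.DataFrame:
    """Unregulated two-channel peptides under the affine noise law."""
    labels = labels or {"Treg": 114, "Teff": 117}
    rng = np.random.default_rng(seed)
    base = np.exp(rng.normal(7.0, 1.0, n)) * scale
    t = np.clip(base + rng.normal(0, 1, n) * (sigma0 * scale + c * base), 0, None)
    e = np.clip(base + rng.normal(0, 1, n) * (sigma0 * scale + c * base), 0, None)
    df = pd.DataFrame(
        {
            "spectrum_id": [f"s{i}" for i in range(n)],
            "peptide_sequence": "PEPTIDEK",
            "protein_id": "P1",
            "score": 50.0,
            "is_unique": True,
            "intensity_114": 0.0,
            "intensity_115": 0.0,
            "intensity_116": 0.0,
            "intensity_117": 0.0,
            "stage": "normalized",
        }
    )
    df[f"intensity_{labels['Treg']}"] = t
    df[f"intensity_{labels['Teff']}"] = e
    return df
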