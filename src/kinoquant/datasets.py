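"""Small reference datasets used in examples and validation tests.

Both tables come from a published quantitative comparison of regulatory
(Treg) and effector (Teff) CD4+ T-cell kinomes and are transcribed here
as plain Python literals; regulation factors use the signed convention
(RF = Treg/Teff, ratios below 1 written as negative reciprocals).
"""

from __future__ import annotations

import pandas as pd

#: 12 unique tryptic CDK6 peptides from one representative experiment:
#: identification score and signed peptide-level regulation factor.  The
#: protein-level rollup of these values is the package's worked example.
CDK6_PEPTIDES: tuple[tuple[str, float, float], ...] = (
    ("ADQQYECVAEIGEGAYGK", 50, -4.2),
    ("CLTFNPAK", 44, -3.6),
    ("DMMFQLLR", 28, -3.9),
    ("DVALPR", 30, -3.6),
    ("FVTDIDELGK", 70, -3.1),
    ("FVTDIDELGKDLLLK", 43, -3.1),
    ("GSSDVDQLGK", 63, -3.9),
    ("ILDVIGLPGEEDWPR", 77, -4.9),
    ("ISAYSALSHPYFQDLER", 50, -2.9),
    ("LFDVCTVSR", 38, -4.3),
    ("SAQPIEK", 30, -2.8),
    ("VQTGEEGMPLSTIR", 86, -4.0),
)

#: The 11 kinases called differentially expressed in that study:
#: median signed RF over the four experiments.
DIFFERENTIAL_KINASE_MEDIANS: tuple[tuple[str, float], ...] = (
    ("CDK1", -3.6),
    ("AURKB", -3.6),
    ("CDK6", -3.2),
    ("SRC", -2.5),
    ("CDK2", -1.6),
    ("NEK9", 1.6),
    ("STK10", 1.7),
    ("KCC2D", 1.7),
    ("CDK3", 2.0),
    ("STK4", 2.3),
    ("EPHB1", 6.9),
)


def cdk6_peptides() -> pd.DataFrame:
    """CDK6 peptide table: peptide_sequence, score, signed_rf."""
    return pd.DataFrame(
        CDK6_PEPTIDES, columns=["peptide_sequence", "score", "signed_rf"]
    ).assign(protein_id="CDK6")


def cdk6_evidence(labels: dict[str, int] | None = None) -> pd.DataFrame:
    """The CDK6 peptides as a normalized evidence table.

    Channel intensities are synthetic: the Teff channel is set to a
    nominal 1000 and the Treg channel to 1000 times the ratio implied by
    each printed signed RF, so the table reproduces the printed
    peptide-level RFs exactly in the noise-free limit.
    """
    from .likelihood import signed_to_ratio

    labels = labels or {"Treg": 114, "Teff": 117}
    rows = []
    for i, (seq, score, rf) in enumerate(CDK6_PEPTIDES):
        intens = {ch: 0.0 for ch in (114, 115, 116, 117)}
        intens[labels["Teff"]] = 1000.0
        intens[labels["Treg"]] = 1000.0 * signed_to_ratio(rf)
        rows.append(
            {
                "spectrum_id": f"cdk6.scan{i + 1:03d}",
                "peptide_sequence": seq,
                "protein_id": "CDK6",
                "score": float(score),
                "is_unique": True,
                **{f"intensity_{ch}": v for ch, v in intens.items()},
                "stage": "normalized",
            }
        )
    return pd.DataFrame(rows)


def differential_kinase_medians() -> pd.DataFrame:
    """Reference medians: protein_id, median_rf."""
    return pd.DataFrame(
        DIFFERENTIAL_KINASE_MEDIANS, columns=["protein_id", "median_rf"]
    )
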