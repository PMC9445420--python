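"""Bundled worked-example tables for the LUAD repositioning filters.

These are the published candidate table from a LUAD repositioning
analysis — ten drugs/preclinical compounds with their Jaccard overlap
and proximity z-scores, together with the reported all-drug mean
Jaccard — and the corresponding physical drug-target interaction pairs
with median IC50 values. They serve as fixed inputs for exercising the
summary and IC50 filters on real numbers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["luad_candidate_drugs", "luad_ic50_pairs",
           "LUAD_ALL_DRUG_MEAN_JACCARD"]

# reported mean Jaccard score over all ~3,700 scored drugs and compounds
LUAD_ALL_DRUG_MEAN_JACCARD = 0.036

_CANDIDATES = [
    ("Chlorpromazine", 0.059, -2.371),
    ("Bromoethylamine", 0.057, -2.476),
    ("Azathioprine", 0.054, -3.848),
    ("Ethanol", 0.050, -2.310),
    ("Papaverine", 0.044, -3.345),
    ("Fluoxetine", 0.043, -3.516),
    ("Cimetidine", 0.040, -2.125),
    ("Benzbromarone", 0.039, -2.325),
    ("Rotenone", 0.038, -3.437),
    ("Sulfasalazine", 0.038, -2.663),
]

_IC50 = [
    ("Benzbromarone", "CYP2C9", 41.00),
    ("Benzbromarone", "AKR1C1", 48.00),
    ("Benzbromarone", "SLC22A6", 4600.00),
    ("Cimetidine", "HRH2", 500.00),
    ("Bromoethylamine", "NPY1R", 0.06),
    ("Bromoethylamine", "GRK5", 11.80),
    ("Bromoethylamine", "MMP9", 26.00),
    ("Bromoethylamine", "ANO1", 156.50),
    ("Bromoethylamine", "FNTB", 180.00),
    ("Bromoethylamine", "OPRD1", 362.00),
    ("Bromoethylamine", "RAD51", 370.00),
    ("Bromoethylamine", "ABCG2", 527.50),
    ("Bromoethylamine", "TYMS", 1288.00),
    ("Bromoethylamine", "DHFR", 5010.00),
]


def luad_candidate_drugs() -> pd.DataFrame:
    """Ten reported candidates with Jaccard and proximity z-scores.

    The overlap fraction is not printed per drug; all ten survived the
    >= 50% overlap rule, so it is recorded as satisfied (1.0).
    """
    df = pd.DataFrame(_CANDIDATES, columns=["drug", "jaccard", "z"])
    df["overlap_fraction"] = 1.0
    return df.set_index("drug")


def luad_ic50_pairs() -> pd.DataFrame:
    """Reported physical drug-target pairs with median IC50 (nM)."""
    return pd.DataFrame(_IC50, columns=["drug", "target_gene",
                                        "median_ic50_nM"]).astype(
        {"median_ic50_nM": np.float64})
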