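"""Published reference panels for the thioacetamide pooled-hepatocyte study.

Per-lot (lots A–E) log2 fold-change values for the key hepatocyte drug
transporters and cytochrome P450 enzymes, and the per-lot liver-toxicity
feature-set scores (mean |log2 FC| over the PTGS and TMG gene sets), as
printed in the published report tables of a five-lot pooled-human-hepatocyte
thioacetamide exposure experiment (high dose vs. control, 24 h). They serve
as inputs for recomputing the cross-lot Avg./SD summary columns and the
sign-consistency annotations.
"""

from __future__ import annotations

import pandas as pd

LOTS = ["A", "B", "C", "D", "E"]

#: Hepatocyte drug-transporter panel: per-lot log2 FC by gene symbol.
TRANSPORTER_PANEL: dict[str, list[float]] = {
    "SLCO1B3": [0.37, -0.10, -0.33, -0.34, 1.27],
    "SLCO2B1": [0.76, 0.29, 1.19, 0.58, -2.49],
    "SLC22A7": [2.56, -1.88, -3.97, -1.59, 4.25],   # OAT2
    "SLC22A9": [0.08, 0.67, 0.86, 0.45, 0.14],      # OAT7
    "SLC22A1": [0.22, -1.52, 0.23, 3.32, 0.21],     # OCT1
    "ABCC3": [-0.24, 0.63, 1.45, -0.65, 0.97],      # MRP3
    "ABCC4": [0.24, -1.81, -1.57, 2.19, 0.37],      # MRP4
    "ABCC2": [0.24, 0.37, 0.25, 0.32, 0.30],        # MRP2
    "ATP8B1": [-0.22, -0.36, -0.55, -0.49, -0.16],  # FIC1
    "ABCG2": [0.25, 0.44, 0.14, 0.18, 0.27],        # BCRP
    "ABCB1": [0.20, -0.63, 0.90, 0.14, 5.27],       # Pgp / MDR1
    "ABCB4": [-0.41, 0.37, 0.85, -2.17, -0.48],     # MDR3
    "SLC16A11": [3.94, 0.64, 3.61, 0.66, 1.85],
    "SLC16A13": [0.44, 0.78, 0.93, 1.08, 0.52],
}

#: Cytochrome P450 enzyme panel: per-lot log2 FC by gene symbol.
CYP_PANEL: dict[str, list[float]] = {
    "CYP2C9": [0.33, 0.36, 1.16, 0.90, 0.14],
    "CYP3A4": [0.51, 2.11, 1.22, 0.86, 0.35],
    "CYP3A5": [1.05, 0.87, 0.87, 0.91, 0.90],
    "CYP26A1": [-2.20, -7.22, -2.66, -3.33, -3.37],
    "CYP26B1": [-2.98, -5.48, -4.07, -3.10, -6.86],
    "CYP1A1": [1.02, 2.02, 2.86, 2.89, -1.46],
    "CYP1A2": [-0.20, 0.68, 0.14, 0.60, -0.12],
    "CYP2C19": [0.27, 0.33, 0.85, 0.69, 0.82],
    "CYP2C8": [-0.63, -0.29, -0.28, 3.45, -0.38],
    "CYP2E1": [0.31, 0.23, 0.28, 0.24, 0.22],
}

#: Liver-toxicity feature-set scores (mean |log2 FC| per lot).
#: PTGS: predictive toxicogenomics space; TMG: toxicity module genes.
FEATURE_SET_SCORES: dict[str, list[float]] = {
    "PTGS_all": [0.75, 0.80, 0.94, 0.88, 0.85],
    "PTGS_core": [0.71, 0.78, 0.89, 0.80, 0.81],
    "TMG": [0.68, 0.70, 0.83, 0.79, 0.74],
}


def transporter_frame() -> pd.DataFrame:
    """Transporter panel as a genes x lots DataFrame."""
    return pd.DataFrame.from_dict(TRANSPORTER_PANEL, orient="index", columns=LOTS)


def cyp_frame() -> pd.DataFrame:
    """CYP panel as a genes x lots DataFrame."""
    return pd.DataFrame.from_dict(CYP_PANEL, orient="index", columns=LOTS)


def feature_score_frame() -> pd.DataFrame:
    """Feature-set per-lot scores as a sets x lots DataFrame."""
    return pd.DataFrame.from_dict(FEATURE_SET_SCORES, orient="index", columns=LOTS)
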