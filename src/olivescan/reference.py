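"""Published worked-example tables from the motivating olive study.

Two small reference tables from a published three-cultivar olive
ripening study are bundled so that the selection rule and the GPI
ranking can be exercised against known printed values without access to
the (unreleased) field data:

* :func:`published_loadings` — PCA and sparse-PCA loadings of the 35
  colorimetric indexes (components PC1, PC2, SPC1, SPC2).  Applying the
  nonzero-loading union rule to the sparse components retains 28 of the
  35 indexes.
* :func:`published_gpi` — the GPI values of the three network variants
  per cultivar and trait, whose descending order reproduces the
  published ranks.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["published_loadings", "published_gpi", "PUBLISHED_GPI_RANKS"]

# RGB index -> (PC1, PC2, SPC1, SPC2)
_LOADINGS = {
    "R": (0.173673, -0.17527, 0.190384, 0.0),
    "G": (0.193318, -0.13006, 0.25154, 0.0),
    "B": (-0.04634, -0.34902, 0.029027, 0.0),
    "NR": (0.112447, 0.184999, 0.0, 0.0),
    "NG": (0.195725, 0.118161, 0.0, 0.0),
    "NB": (-0.18671, -0.1504, 0.0, 0.0),
    "GB": (0.107347, 0.289417, 0.001645, 0.0),
    "RB": (0.098209, 0.290244, 0.001023, 0.0),
    "GR": (0.184904, 0.037012, 0.000741, 0.0),
    "BI": (0.174901, -0.19118, 0.172234, 0.0),
    "BIM": (0.162807, -0.22338, 0.012636, 0.0),
    "SCI": (-0.18633, -0.02744, 0.0, 0.0),
    "GLI": (0.198202, 0.105196, 0.001438, 0.0),
    "HI": (0.009223, 0.039836, -0.00091, 0.0),
    "NGRDI": (0.186327, 0.027439, 0.0, 0.0),
    "NDGBI": (0.187861, 0.155, 0.001253, 0.0),
    "NDRBI": (0.170895, 0.194543, 0.000646, 0.0),
    "I": (0.161255, -0.22798, 0.478908, 0.0),
    "S": (0.186705, 0.150404, 0.000897, 0.0),
    "VARI": (0.192465, 0.000261, 0.0, 0.0),
    "HUE": (-0.19007, -0.0248, -0.00694, 0.0),
    "HUE2": (-0.16947, -0.01249, -0.00573, 0.0),
    "BGI": (-0.19762, -0.09568, -0.00164, 0.0),
    "L": (0.179046, -0.17924, 0.457194, 0.0),
    "GRAY": (0.184074, -0.16516, 0.207812, 0.0),
    "GLAI": (0.192465, 0.000261, 0.014478, 0.0),
    "CI": (0.182407, 0.13823, 0.001129, 0.0),
    "SHP": (-0.01298, -0.01486, -0.00018, -1.0),
    "RI": (-0.1057, 0.288167, 0.0, 0.0),
    "RminB": (0.194727, 0.040558, 0.160705, 0.0),
    "RplusB": (0.097349, -0.29776, 0.208727, 0.0),
    "RplusG": (0.183643, -0.15131, 0.436911, 0.0),
    "RminG": (-0.18022, -0.00587, -0.05907, 0.0),
    "GminB": (0.202835, 0.031916, 0.224126, 0.0),
    "BplusG": (0.141039, -0.25804, 0.27192, 0.0),
}

# (cultivar, trait) -> {model: GPI value}
_GPI = {
    ("Coratina", "phenols"): {"BPNN": -0.15014, "PCA_BPNN": 0.17129, "SPCA_BPNN": -0.17755},
    ("Coratina", "oil"): {"BPNN": -0.1025, "PCA_BPNN": 0.21589, "SPCA_BPNN": 0.37732},
    ("Frantoio", "phenols"): {"BPNN": -0.41955, "PCA_BPNN": 0.03186, "SPCA_BPNN": 0.43254},
    ("Frantoio", "oil"): {"BPNN": -0.51611, "PCA_BPNN": -0.34027, "SPCA_BPNN": 0.17350},
    ("Leccino", "phenols"): {"BPNN": 0.41724, "PCA_BPNN": 0.10131, "SPCA_BPNN": 0.17279},
    ("Leccino", "oil"): {"BPNN": -0.05665, "PCA_BPNN": -0.16239, "SPCA_BPNN": -0.62195},
}

#: Published ranks per (cultivar, trait) in model registration order.
PUBLISHED_GPI_RANKS = {
    ("Coratina", "phenols"): {"BPNN": 2, "PCA_BPNN": 1, "SPCA_BPNN": 3},
    ("Coratina", "oil"): {"BPNN": 3, "PCA_BPNN": 2, "SPCA_BPNN": 1},
    ("Frantoio", "phenols"): {"BPNN": 3, "PCA_BPNN": 2, "SPCA_BPNN": 1},
    ("Frantoio", "oil"): {"BPNN": 3, "PCA_BPNN": 2, "SPCA_BPNN": 1},
    ("Leccino", "phenols"): {"BPNN": 1, "PCA_BPNN": 3, "SPCA_BPNN": 2},
    ("Leccino", "oil"): {"BPNN": 1, "PCA_BPNN": 2, "SPCA_BPNN": 3},
}


def published_loadings() -> pd.DataFrame:
    """35 x 4 loading table (columns PC1, PC2, SPC1, SPC2)."""
    return pd.DataFrame.from_dict(
        _LOADINGS, orient="index", columns=["PC1", "PC2", "SPC1", "SPC2"]
    )


def published_gpi() -> pd.DataFrame:
    """Long table with columns cultivar, trait, model, gpi."""
    rows = [
        {"cultivar": c, "trait": t, "model": m, "gpi": v}
        for (c, t), d in _GPI.items()
        for m, v in d.items()
    ]
    return pd.DataFrame(rows)
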