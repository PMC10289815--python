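"""RGB colorimetric indexes computed from mean fruit pixel values.

Thirty-five scalar indexes are derived from the per-sample mean red (R),
green (G) and blue (B) pixel values of the segmented fruit region.  They
include the raw channels, channel ratios and normalised differences
(e.g. NGRDI, NDGBI), brightness measures (BI, GRAY, I), hue-like angles
(HUE, HUE2) and simple sums/differences (RminB, RplusG, ...), all of which
have been used in the plant-phenotyping literature as proxies of pigment
and water status.

Two formula dialects are supported because several published formulas
contain typesetting artifacts:

``interpreted`` (default)
    The constant ``30.5`` in the hue angles is read as ``3**0.5`` and the
    lightness index ``L`` as ``(R + G + B)/3``, which matches the standard
    forms of those indexes.

``as_printed``
    Every formula is evaluated exactly as typeset, artifacts included.

Degenerate denominators (e.g. HI or SHP when G == B, the normalised
channels when R + G + B == 0) yield NaN — an *undefined flag* — rather
than raising; imputation is deferred to modelling time.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["INDEX_NAMES", "DIALECTS", "compute_indexes", "build_feature_table"]

#: Canonical order of the 35 index names.
INDEX_NAMES: tuple[str, ...] = (
    "R", "G", "B", "NR", "NG", "NB", "GB", "RB", "GR", "BI", "BIM", "SCI",
    "GLI", "HI", "NGRDI", "NDGBI", "NDRBI", "I", "S", "VARI", "HUE", "HUE2",
    "BGI", "L", "GRAY", "GLAI", "CI", "SHP", "RI", "RminB", "RplusB",
    "RplusG", "RminG", "GminB", "BplusG",
)

DIALECTS = ("interpreted", "as_printed")

_SQRT3 = math.sqrt(3.0)


def _div(num: float, den: float) -> float:
    """Quotient with NaN on a zero denominator (undefined flag)."""
    if den == 0:
        return math.nan
    return num / den


def compute_indexes(
    means, dialect: str = "interpreted"
) -> "pd.Series[float]":
    """Compute the 35 colorimetric indexes for one sample.

    Parameters
    ----------
    means : tuple of float or mapping
        The (R, G, B) channel means, each in [0, 255].  A mapping with
        keys ``r_mean``/``g_mean``/``b_mean`` (or ``R``/``G``/``B``) is
        also accepted.
    dialect : {"interpreted", "as_printed"}
        How to read the ambiguous printed formulas (see module docstring).

    Returns
    -------
    pandas.Series
        Length-35 series indexed by :data:`INDEX_NAMES`; undefined values
        are NaN.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    r, g, b = _coerce_means(means)
    for name, v in (("R", r), ("G", g), ("B", b)):
        if not 0 <= v <= 255:
            raise ValueError(f"channel mean {name}={v} outside [0, 255]")

    s = r + g + b
    out: dict[str, float] = {"R": r, "G": g, "B": b}
    out["NR"] = _div(r, s)
    out["NG"] = _div(g, s)
    out["NB"] = _div(b, s)
    out["GB"] = _div(g, b)
    out["RB"] = _div(r, b)
    out["GR"] = _div(g, r)
    out["BI"] = math.sqrt((r**2 + g**2 + b**2) / 3.0)
    # BIM kept as printed under both dialects: no canonical form is known.
    out["BIM"] = math.sqrt((r * 2 + g * 2 + b * 2) / 3.0)
    out["SCI"] = _div(r - g, r + g)
    out["GLI"] = _div(2 * g - r - b, 2 * g + r + b)
    out["HI"] = _div(2 * r - g - b, g - b)
    out["NGRDI"] = _div(g - r, g + r)
    out["NDGBI"] = _div(g - b, g + b)
    out["NDRBI"] = _div(r - b, r + b)
    out["I"] = s
    out["S"] = _div(s - 3 * b, s)
    out["VARI"] = _div(g - r, g + r - b)
    if dialect == "interpreted":
        out["HUE"] = _atan_div(2 * (b - g - r), _SQRT3 * (g - r))
        out["HUE2"] = _atan_div(2 * (r - g - r), _SQRT3 * (g - b))
        out["L"] = s / 3.0
    else:
        out["HUE"] = math.atan(2 * (b - g - r) / 30.5 * (g - r))
        out["HUE2"] = math.atan(2 * (r - g - r) / 30.5 * (g - b))
        out["L"] = r + g + b / 3.0
    out["BGI"] = _div(b, g)
    out["GRAY"] = 0.299 * r + 0.587 * g + 0.114 * b
    out["GLAI"] = _glai(r, g, b)
    out["CI"] = _div(r - b, r)
    out["SHP"] = _div(2 * (r - g - b), g - b)
    out["RI"] = _div(r**2, b * g**3)
    out["RminB"] = r - b
    out["RplusB"] = r + b
    out["RplusG"] = r + g
    out["RminG"] = r - g
    out["GminB"] = g - b
    out["BplusG"] = b + g
    return pd.Series([out[k] for k in INDEX_NAMES], index=list(INDEX_NAMES), dtype=float)


def _atan_div(num: float, den: float) -> float:
    if den == 0:
        return math.nan
    return math.atan(num / den)


def _glai(r: float, g: float, b: float) -> float:
    den = g + r - b
    if den == 0:
        return math.nan
    return 25.0 * (g - r) / den + 1.25


def _coerce_means(means) -> tuple[float, float, float]:
    if isinstance(means, Mapping):
        for keys in (("r_mean", "g_mean", "b_mean"), ("R", "G", "B")):
            if all(k in means for k in keys):
                return tuple(float(means[k]) for k in keys)  # type: ignore[return-value]
        raise KeyError("mapping must contain r_mean/g_mean/b_mean or R/G/B")
    r, g, b = means
    return float(r), float(g), float(b)


def build_feature_table(
    samples: pd.DataFrame, dialect: str = "interpreted"
) -> tuple[pd.DataFrame, pd.Series]:
    """Compute the 35-index feature matrix for a sample table.

    Parameters
    ----------
    samples : pandas.DataFrame
        Must have ``r_mean``, ``g_mean``, ``b_mean`` columns; row order is
        preserved and the index carried over.
    dialect : str
        Formula dialect passed to :func:`compute_indexes`.

    Returns
    -------
    (features, undefined_counts)
        ``features`` is an ``n x 35`` DataFrame; ``undefined_counts`` a
        per-index count of NaN (undefined-flag) entries.
    """
    required = ("r_mean", "g_mean", "b_mean")
    missing = [c for c in required if c not in samples.columns]
    if missing:
        raise KeyError(f"sample table is missing channel columns: {missing}")
    rows = [
        compute_indexes((row.r_mean, row.g_mean, row.b_mean), dialect=dialect)
        for row in samples.itertuples()
    ]
    features = pd.DataFrame(rows, index=samples.index)
    features.columns = list(INDEX_NAMES)
    undefined = features.isna().sum()
    return features, undefined
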