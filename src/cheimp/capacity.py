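"""Food shares, subsistence poverty line, and capacity-to-pay measures.

The WHO/Xu subsistence method identifies households whose food budget
share lies in a middle percentile band (by default the 45th-55th) of the
survey-weighted food-share distribution, and sets the poverty line ``ell``
to the weighted mean of their equivalence-adjusted food expenditure
``fe_i = f_i / he_i``.  A household's subsistence expenditure is then
``s_i = ell * he_i`` and its capacity-to-pay is non-subsistence
expenditure, with a nonfood fallback for households spending less on
food than subsistence:

    ctp_who = x - s   if s <= f
              x - f   otherwise

The two equivalence-based alternatives are total expenditure per adult
equivalent (``ctp_wb = x / he``) and nonfood expenditure per adult
equivalent (``ctp_nf = (x - food_wb) / he``), where the nonfood
deduction uses the broader food definition that includes alcohol,
tobacco and food away from home.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cheimp.equivalence import EquivalenceParams, equivalent_adults

__all__ = [
    "PovertyLine",
    "compute_ctp_nf",
    "compute_ctp_wb",
    "compute_ctp_who",
    "derive_households",
    "food_share",
    "poverty_line",
    "select_band",
    "subsistence",
    "weighted_quantile",
]


@dataclass(frozen=True)
class PovertyLine:
    """Per-adult-equivalent subsistence value with band metadata.

    Attributes
    ----------
    ell
        Weighted mean of equivalence-adjusted food expenditure over the
        middle-food-share band (currency/month per adult equivalent).
    band_lo_value, band_hi_value
        Food-share values at the lower and upper band percentiles.
    n_band
        Unweighted count of households in the band.
    total_band_weight
        Sum of survey weights over the band.
    """

    ell: float
    band_lo_value: float
    band_hi_value: float
    n_band: int
    total_band_weight: float

    def __post_init__(self) -> None:
        if self.ell < 0:
            raise ValueError("poverty line must be non-negative")
        if self.n_band < 1:
            raise ValueError("band must contain at least one household")
        if self.band_lo_value > self.band_hi_value:
            raise ValueError("band_lo_value must not exceed band_hi_value")


def food_share(f, x):
    """Food budget share ``wf = f / x``.

    ``x`` must be strictly positive; households with zero total
    expenditure are excluded upstream because the share is undefined.
    """
    f = np.asarray(f, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("total expenditure must be positive to form a food share")
    if np.any(f < 0) or np.any(f > x):
        raise ValueError("food expenditure must satisfy 0 <= f <= x")
    wf = f / x
    return float(wf) if wf.ndim == 0 else wf


def weighted_quantile(values, weights, q: float) -> float:
    """Left-continuous inverse of the weighted ECDF.

    Returns the smallest observed value ``v`` such that the cumulative
    normalised weight of observations with value ``<= v`` is at least
    ``q``.  No interpolation: the result is always an observed value, so
    a percentile band built from these quantiles is never empty.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise ValueError("weighted_quantile requires non-empty input")
    if v.shape != w.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and finite")
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"quantile level must lie in [0, 1], got {q}")
    order = np.argsort(v, kind="stable")
    cum = np.cumsum(w[order])
    # cum[-1] is the running total: the comparison is then identical to a
    # sequential sort-and-accumulate pass over the same data.
    idx = int(np.searchsorted(cum, q * cum[-1], side="left"))
    idx = min(idx, v.size - 1)
    return float(v[order][idx])


def select_band(food_shares, weights, band_lo: float, band_hi: float):
    """Indicator of membership in the middle food-share percentile band.

    ``I_i = 1`` iff ``wf_lo <= wf_i <= wf_hi`` where the bounds are the
    weighted quantiles of the food-share distribution at ``band_lo`` and
    ``band_hi``.  Both ends are inclusive, so boundary ties are all
    included and the band is non-empty by construction.

    Returns ``(indicator array, lo_value, hi_value)``.
    """
    wf = np.asarray(food_shares, dtype=float)
    if not (0.0 <= band_lo < band_hi <= 1.0):
        raise ValueError("band bounds must satisfy 0 <= lo < hi <= 1")
    lo_val = weighted_quantile(wf, weights, band_lo)
    hi_val = weighted_quantile(wf, weights, band_hi)
    indicator = (wf >= lo_val) & (wf <= hi_val)
    if not indicator.any():
        raise RuntimeError("empty food-share band (cannot occur with ECDF quantiles)")
    return indicator, lo_val, hi_val


def poverty_line(fe, weights, in_band) -> PovertyLine:
    """Weighted mean of equivalence-adjusted food expenditure over the band.

        ell = sum_{i: I_i=1} w_i * fe_i / sum_{i: I_i=1} w_i

    ``fe`` is food expenditure (WHO definition) divided by equivalent
    adults.  Band metadata (bounds are attached by the caller via
    :func:`select_band`; here only membership is needed).
    """
    fe = np.asarray(fe, dtype=float)
    w = np.asarray(weights, dtype=float)
    mask = np.asarray(in_band, dtype=bool)
    if not mask.any():
        raise ValueError("empty band: no households selected for the poverty line")
    total_w = float(w[mask].sum())
    ell = float(np.sum(w[mask] * fe[mask]) / total_w)
    return PovertyLine(
        ell=ell,
        band_lo_value=float("nan"),
        band_hi_value=float("nan"),
        n_band=int(mask.sum()),
        total_band_weight=total_w,
    )


def subsistence(ell: float, he):
    """Household subsistence expenditure ``s = ell * he``."""
    if ell < 0:
        raise ValueError("poverty line must be non-negative")
    he = np.asarray(he, dtype=float)
    if np.any(he <= 0):
        raise ValueError("equivalent adults must be positive")
    s = ell * he
    return float(s) if s.ndim == 0 else s


def compute_ctp_who(x, f, s):
    """Non-subsistence capacity-to-pay (household currency/month).

    ``x - s`` when subsistence does not exceed actual food spending
    (``s <= f``), and nonfood expenditure ``x - f`` otherwise, so the
    result is non-negative whenever ``0 <= f <= x``.
    """
    x = np.asarray(x, dtype=float)
    f = np.asarray(f, dtype=float)
    s = np.asarray(s, dtype=float)
    ctp = np.where(s <= f, x - s, x - f)
    return float(ctp) if ctp.ndim == 0 else ctp


def compute_ctp_wb(x, he):
    """Total expenditure per adult equivalent, ``x / he``."""
    x = np.asarray(x, dtype=float)
    he = np.asarray(he, dtype=float)
    if np.any(he <= 0):
        raise ValueError("equivalent adults must be positive")
    ctp = x / he
    return float(ctp) if ctp.ndim == 0 else ctp


def compute_ctp_nf(x, food_wb, he):
    """Nonfood expenditure per adult equivalent, ``(x - food_wb) / he``.

    The food deduction uses the broad definition including alcohol,
    tobacco and food away from home.
    """
    x = np.asarray(x, dtype=float)
    food_wb = np.asarray(food_wb, dtype=float)
    he = np.asarray(he, dtype=float)
    if np.any(he <= 0):
        raise ValueError("equivalent adults must be positive")
    if np.any(food_wb < 0) or np.any(food_wb > x):
        raise ValueError("food_wb must satisfy 0 <= food_wb <= x")
    ctp = (x - food_wb) / he
    return float(ctp) if ctp.ndim == 0 else ctp


def derive_households(
    frame: pd.DataFrame,
    params: EquivalenceParams = EquivalenceParams(),
    band_lo: float = 0.45,
    band_hi: float = 0.55,
) -> tuple[pd.DataFrame, PovertyLine]:
    """Compute all per-household derived quantities for one survey.

    Takes a validated survey frame (columns ``household_id, adults,
    kids, food_who, food_wb, total, oop, weight``) and returns a frame
    with equivalent adults ``he``, food share ``wf`` (WHO food
    definition), equivalence-adjusted food expenditure ``fe``, band
    indicator ``in_band``, subsistence ``s``, nonfood ``z``, and the
    three capacity-to-pay columns, together with the fitted
    :class:`PovertyLine`.

    The poverty line is always computed from the supplied dataset alone
    (per survey year), never pooled across datasets.
    """
    d = frame.reset_index(drop=True).copy()
    d["he"] = equivalent_adults(d["adults"].to_numpy(), d["kids"].to_numpy(), params)
    d["wf"] = food_share(d["food_who"].to_numpy(), d["total"].to_numpy())
    d["fe"] = d["food_who"] / d["he"]
    d["z"] = d["total"] - d["food_wb"]

    indicator, lo_val, hi_val = select_band(
        d["wf"].to_numpy(), d["weight"].to_numpy(), band_lo, band_hi
    )
    d["in_band"] = indicator
    pl = poverty_line(d["fe"].to_numpy(), d["weight"].to_numpy(), indicator)
    pl = PovertyLine(
        ell=pl.ell,
        band_lo_value=lo_val,
        band_hi_value=hi_val,
        n_band=pl.n_band,
        total_band_weight=pl.total_band_weight,
    )

    d["s"] = subsistence(pl.ell, d["he"].to_numpy())
    d["ctp_who"] = compute_ctp_who(
        d["total"].to_numpy(), d["food_who"].to_numpy(), d["s"].to_numpy()
    )
    d["ctp_wb"] = compute_ctp_wb(d["total"].to_numpy(), d["he"].to_numpy())
    d["ctp_nf"] = compute_ctp_nf(
        d["total"].to_numpy(), d["food_wb"].to_numpy(), d["he"].to_numpy()
    )
    return d, pl
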