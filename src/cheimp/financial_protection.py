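"""Catastrophic-expenditure and impoverishment incidence estimators.

A household is flagged as facing catastrophic health expenditure at
threshold ``kappa`` when its OOP share of capacity-to-pay is at least
``kappa`` (inclusive), and as impoverished when total expenditure meets
subsistence but falls below it once OOP payments are netted out:

    P = 1  iff  x >= s  and  x - oop < s.

Incidence is the survey-weighted percentage of flagged households, with
a design-based normal-approximation confidence interval for a weighted
proportion (no stratification or clustering: the surveys' design
variables are outside the data schema).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from cheimp.capacity import PovertyLine, derive_households
from cheimp.equivalence import EquivalenceParams

__all__ = [
    "AnalysisResult",
    "IncidenceEstimate",
    "flag_catastrophic",
    "flag_impoverished",
    "oop_share",
    "run_analysis",
    "weighted_incidence",
]

_METHODS = ("who", "wb", "nf")


@dataclass(frozen=True)
class IncidenceEstimate:
    """Survey-weighted incidence for one (method, threshold) cell.

    ``point`` and the CI bounds are percentages of weighted households;
    ``threshold`` is ``None`` for impoverishment.
    """

    method: str
    threshold: float | None
    point: float
    ci_lo: float
    ci_hi: float
    n_flagged: int
    n_total: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_lo <= self.point <= self.ci_hi <= 100.0):
            raise ValueError("CI must satisfy 0 <= lo <= point <= hi <= 100")
        if self.n_flagged > self.n_total:
            raise ValueError("n_flagged cannot exceed n_total")


def oop_share(oop, ctp, he=None, equivalise_oop: bool = False, method: str = "who"):
    """Share of capacity-to-pay devoted to OOP health payments.

    By default this is the literal ratio ``oop / ctp`` for every method,
    even though the ``wb`` and ``nf`` capacities are per adult
    equivalent while OOP is a household total.  With
    ``equivalise_oop=True`` and method ``wb`` or ``nf``, OOP is divided
    by equivalent adults first, so the share reduces algebraically to
    ``oop / x`` or ``oop / z``.

    A zero capacity with positive OOP yields ``+inf`` (catastrophic at
    every threshold); zero capacity with zero OOP yields 0.
    """
    oop = np.asarray(oop, dtype=float)
    ctp = np.asarray(ctp, dtype=float)
    if np.any(oop < 0) or np.any(ctp < 0):
        raise ValueError("oop and ctp must be non-negative")
    if equivalise_oop and method in ("wb", "nf"):
        if he is None:
            raise ValueError("equivalise_oop requires equivalent adults")
        he = np.asarray(he, dtype=float)
        oop = oop / he
    with np.errstate(divide="ignore", invalid="ignore"):
        share = np.where(
            ctp > 0,
            np.divide(oop, ctp, out=np.zeros_like(oop + ctp), where=ctp > 0),
            np.where(oop > 0, np.inf, 0.0),
        )
    return float(share) if share.ndim == 0 else share


def flag_catastrophic(share, kappa: float):
    """Catastrophe indicator: ``share >= kappa`` (inclusive threshold)."""
    if not (0.0 < kappa <= 1.0):
        raise ValueError(f"threshold must lie in (0, 1], got {kappa}")
    flags = np.asarray(share, dtype=float) >= kappa
    return bool(flags) if flags.ndim == 0 else flags


def flag_impoverished(x, oop, s):
    """Impoverishment indicator: at or above subsistence before OOP, below after."""
    x = np.asarray(x, dtype=float)
    oop = np.asarray(oop, dtype=float)
    s = np.asarray(s, dtype=float)
    flags = (x >= s) & (x - oop < s)
    return bool(flags) if flags.ndim == 0 else flags


def weighted_incidence(
    flags,
    weights,
    ci_level: float = 0.95,
    method: str = "who",
    threshold: float | None = None,
) -> IncidenceEstimate:
    """Survey-weighted percentage of flagged households with a CI.

    Point estimate ``100 * sum(w*c) / sum(w)``.  The standard error is
    the Horvitz-Thompson-style ``sqrt(sum(w_i^2 (c_i - p)^2)) / sum(w)``
    for the weighted proportion ``p``, with a normal-quantile CI
    truncated to [0, 100].
    """
    c = np.asarray(flags, dtype=float)
    w = np.asarray(weights, dtype=float)
    if c.size == 0:
        raise ValueError("weighted_incidence requires non-empty input")
    if c.shape != w.shape:
        raise ValueError("flags and weights must have equal length")
    if not (0.0 < ci_level < 1.0):
        raise ValueError("ci_level must lie in (0, 1)")
    total_w = float(w.sum())
    p = float(np.sum(w * c) / total_w)
    se = float(math.sqrt(np.sum(w**2 * (c - p) ** 2)) / total_w)
    z = float(stats.norm.ppf(0.5 * (1.0 + ci_level)))
    point = 100.0 * p
    half = 100.0 * z * se
    return IncidenceEstimate(
        method=method,
        threshold=threshold,
        point=point,
        ci_lo=max(0.0, point - half),
        ci_hi=min(100.0, point + half),
        n_flagged=int(c.sum()),
        n_total=int(c.size),
    )


@dataclass
class AnalysisResult:
    """Full output of one pipeline run."""

    estimates: list[IncidenceEstimate]
    derived: pd.DataFrame
    poverty_line: PovertyLine
    diagnostics: dict = field(default_factory=dict)


def run_analysis(frame: pd.DataFrame, config) -> AnalysisResult:
    """Run the full pipeline on a validated survey frame.

    Orchestrates equivalence, food shares, band selection, the poverty
    line, the three capacity-to-pay measures, OOP shares, catastrophe
    flags at every configured threshold, and impoverishment, returning
    the incidence estimates plus the per-household derived table.
    Fully deterministic given inputs.

    ``config`` is a :class:`cheimp.survey_io.RunConfig` (duck-typed: any
    object with the same attributes works).
    """
    params = EquivalenceParams(alpha=config.alpha, theta=config.theta)
    d, pl = derive_households(
        frame, params, band_lo=config.band_lo, band_hi=config.band_hi
    )
    w = d["weight"].to_numpy()

    n_infinite = 0
    estimates: list[IncidenceEstimate] = []
    for method in config.methods:
        if method not in _METHODS:
            raise ValueError(f"unknown capacity-to-pay method: {method!r}")
        ctp = d[f"ctp_{method}"].to_numpy()
        share = oop_share(
            d["oop"].to_numpy(),
            ctp,
            he=d["he"].to_numpy(),
            equivalise_oop=config.equivalise_oop,
            method=method,
        )
        d[f"share_{method}"] = share
        n_infinite += int(np.isinf(share).sum())
        for kappa in config.thresholds:
            flags = flag_catastrophic(share, kappa)
            d[f"che_{method}_{kappa:g}"] = flags
            estimates.append(
                weighted_incidence(
                    flags, w, ci_level=config.ci_level, method=method, threshold=kappa
                )
            )

    imp = flag_impoverished(d["total"].to_numpy(), d["oop"].to_numpy(), d["s"].to_numpy())
    d["impoverished"] = imp
    estimates.append(
        weighted_incidence(
            imp, w, ci_level=config.ci_level, method="impoverishment", threshold=None
        )
    )

    diagnostics = {
        "n_households": int(len(d)),
        "n_infinite_shares": n_infinite,
    }
    return AnalysisResult(
        estimates=estimates, derived=d, poverty_line=pl, diagnostics=diagnostics
    )
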