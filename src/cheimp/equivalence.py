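"""Adult-equivalence scale for household consumption.

A household with ``A`` adults and ``K`` children (aged 14 and under) is
converted to a number of equivalent adults

    he = (A + alpha * K) ** theta

where ``alpha`` is the relative cost of a child and ``theta`` captures
household economies of scale.  With ``alpha = 1`` and ``theta = 1`` the
scale reduces to household size.  The defaults ``alpha = 0.5`` and
``theta = 0.9`` are the values conventionally used in South African
poverty measurement, and the same scale is applied to every
capacity-to-pay construction for consistency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EquivalenceParams", "equivalent_adults"]


@dataclass(frozen=True)
class EquivalenceParams:
    """Child cost ``alpha`` in [0, 1] and scale economy ``theta`` in (0, 1]."""

    alpha: float = 0.5
    theta: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not (0.0 < self.theta <= 1.0):
            raise ValueError(f"theta must lie in (0, 1], got {self.theta}")


def equivalent_adults(adults, kids, params: EquivalenceParams = EquivalenceParams()):
    """Number of equivalent adults ``(A + alpha*K) ** theta``.

    Parameters
    ----------
    adults, kids
        Integral person counts (scalars or arrays).  Non-integer values
        are rejected: survey counts are integral, and a fractional count
        signals an upstream data error.
    params
        Scale parameters.

    Returns
    -------
    float or ndarray
        ``he > 0``; at most ``A + K``.

    Raises
    ------
    ValueError
        If any household is empty (``A + K = 0``), any count is negative
        or non-integral, or the base ``A + alpha*K`` is zero (all-child
        household with ``alpha = 0``).
    """
    a = np.asarray(adults)
    k = np.asarray(kids)
    for name, arr in (("adults", a), ("kids", k)):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ValueError(f"{name} must be integral counts")
        if np.any(arr < 0):
            raise ValueError(f"{name} must be non-negative")
    if np.any(a + k == 0):
        raise ValueError("degenerate household: adults + kids must be >= 1")
    base = a.astype(float) + params.alpha * k.astype(float)
    if np.any(base == 0):
        raise ValueError(
            "degenerate household: adults = 0 with alpha = 0 gives zero base"
        )
    he = base**params.theta
    if np.isscalar(adults) and np.isscalar(kids):
        return float(he)
    return he
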