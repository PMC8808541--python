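"""Significance of the overlap between two marker sets.

Given two marker sets of sizes ``n`` and ``D`` drawn from a universe of
``N`` markers with ``x`` markers in common, the probability of at least
``x`` shared markers under random draws is the upper tail of
``Hypergeometric(N, D, n)``.  For array-scale universes (N in the hundreds
of thousands) naive factorials overflow, so the exact tail is accumulated
in log-space from log-gamma terms.  A continuity-corrected normal
approximation with ``Z = |x - 0.5 - n*p| / sqrt(n*p*q)``, ``p = D/N``, is
used instead when the sampling fraction is small (``10*n < N``) and the
normal range ``p +/- 2*sqrt(p*q/n)`` stays positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf, gammaln

__all__ = [
    "OverlapTest",
    "hypergeom_upper_tail",
    "normal_approx_tail",
    "overlap_probability",
]


@dataclass
class OverlapTest:
    """Contingency of two marker sets and the tail probability of their overlap."""

    x: int
    n: int
    D: int
    N: int
    p_value: float
    method: str  # "exact" or "normal_approx"
    Z: float | None = None

    def to_dict(self) -> dict:
        return {
            "x": self.x, "n": self.n, "D": self.D, "N": self.N,
            "p_value": self.p_value, "method": self.method, "Z": self.Z,
        }


def _validate(x: int, n: int, D: int, N: int) -> None:
    if min(x, n, D, N) < 0 or n > N or D > N:
        raise ValueError(f"inconsistent counts: x={x}, n={n}, D={D}, N={N}")
    if x > min(n, D):
        raise ValueError(f"overlap x={x} exceeds min(n, D)={min(n, D)}")


def _log_pmf(i: np.ndarray, n: int, D: int, N: int) -> np.ndarray:
    # log C(D, i) + log C(N-D, n-i) - log C(N, n) via log-gamma
    def logc(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return logc(D, i) + logc(N - D, n - i) - logc(N, n)


def hypergeom_upper_tail(x: int, n: int, D: int, N: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(N, D, n), computed in log-space.

    Terms are summed from ``x`` upward and truncation stops once a term
    falls below 1e-18 of the running total (the tail is monotone decreasing
    well past its mode, so later terms are negligible).
    """
    _validate(x, n, D, N)
    if x == 0:
        return 1.0
    upper = min(n, D)
    i = np.arange(x, upper + 1)
    logs = _log_pmf(i.astype(float), n, D, N)
    peak = logs.max()
    terms = np.exp(logs - peak)
    total = 0.0
    for k, t in enumerate(terms):
        total += t
        # beyond the mode the terms decay geometrically; stop when negligible
        if k > 0 and terms[k] < terms[k - 1] and t < 1e-18 * total:
            break
    return float(min(1.0, np.exp(peak) * total))


def normal_approx_tail(x: int, n: int, D: int, N: int) -> tuple[float, float]:
    """Continuity-corrected normal approximation to the overlap upper tail.

    Returns ``(Z, p)`` with ``Z = |x - 0.5 - n*p| / sqrt(n*p*q)`` and the
    upper-tail probability ``p = (1 - erf(Z / sqrt(2))) / 2``.
    """
    _validate(x, n, D, N)
    p = D / N
    q = 1.0 - p
    npq = n * p * q
    if npq == 0:
        raise ValueError("n*p*q is zero; the normal approximation is undefined")
    Z = abs((x - 0.5 - n * p) / np.sqrt(npq))
    return float(Z), float((1.0 - erf(Z / np.sqrt(2.0))) / 2.0)


def _normal_regime(n: int, D: int, N: int) -> bool:
    p = D / N
    q = 1.0 - p
    if p == 0 or q == 0 or n == 0:
        return False
    half_width = 2.0 * np.sqrt(p * q / n)
    return (p - half_width > 0) and (p + half_width > 0) and (n * 10 < N)


def overlap_probability(x: int, n: int, D: int, N: int) -> OverlapTest:
    """Overlap tail probability, switching between the exact and normal methods.

    The normal approximation is used when ``p +/- 2*sqrt(p*q/n) > 0`` and
    ``10*n < N``; otherwise the exact log-space hypergeometric tail.
    """
    _validate(x, n, D, N)
    if _normal_regime(n, D, N):
        Z, p_val = normal_approx_tail(x, n, D, N)
        return OverlapTest(x=x, n=n, D=D, N=N, p_value=p_val, method="normal_approx", Z=Z)
    return OverlapTest(
        x=x, n=n, D=D, N=N, p_value=hypergeom_upper_tail(x, n, D, N), method="exact"
    )
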