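"""Two one-sided tests (TOST) for a lack of association, and their defects.

The TOST principle applied to the symmetric hypotheses
H0: |rho| >= rho_B vs. H1: |rho| < rho_B gives closed-form critical
half-widths

    TOST-r:     r_hat    = rho_B  - z_alpha * sigma_B,   sigma_B = (1-rho_B^2)/sqrt(N-3)
    TOST-zeta:  zeta_hat = zeta_B - z_alpha * sigma_zeta

and rejection regions (-r_hat, r_hat) / (-zeta_hat, zeta_hat).  Unlike the
mean-equivalence TOST, the correlation versions degenerate: the half-width
is non-positive — the region is empty and the test can never reject —
whenever N falls below a closed-form threshold.  This module exposes the
regions, the degeneracy thresholds with minimum nonempty sample sizes, and
the exact (normal-approximation) Type I error rates, which stay strictly
below alpha at every finite N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional

from scipy.stats import norm

from .core import (
    _validate_alpha,
    _validate_n,
    _validate_rho,
    fisher_z,
    inverse_fisher_z,
    sigma_r,
    sigma_zeta,
)
from .regions import EquivalenceBounds, RejectionRegion

__all__ = [
    "tost_region",
    "tost_min_sample_size",
    "tost_true_type1",
    "tost_region_general",
    "region_for",
    "TostDiagnostics",
]

_METHODS = ("tost-r", "tost-zeta")


def _validate_method(method: str) -> str:
    method = method.lower().replace("_", "-")
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}; got {method!r}")
    return method


def _validate_rho_b(rho_b: float) -> float:
    rho_b = _validate_rho(rho_b, "rho_b")
    if rho_b <= 0.0:
        raise ValueError(f"rho_b must be positive; got {rho_b}")
    return rho_b


@dataclass(frozen=True)
class TostDiagnostics:
    """Degeneracy diagnostics for a TOST procedure at fixed (alpha, rho_B).

    ``threshold_real`` is the real-valued bound on N below which the
    rejection region is empty; ``min_n`` the smallest integer sample size
    with a nonempty region.  ``type1_at_n`` maps each queried N to the true
    (normal-approximation) Type I error rate, which is 0 exactly while the
    region is empty and climbs toward alpha as N grows.
    """

    method: str
    alpha: float
    rho_b: float
    threshold_real: float
    min_n: int
    type1_at_n: Dict[int, float] = field(default_factory=dict)


def tost_region(
    method: str, rho_b: float, n: int, alpha: float = 0.05
) -> RejectionRegion:
    """Closed-form TOST rejection region on the r scale.

    An empty region (half-width <= 0) is reported with endpoints (0, 0)
    and ``empty=True``; a boundary half-width of exactly zero counts as
    empty, since a zero-width interval can never contain r.
    """
    method = _validate_method(method)
    rho_b = _validate_rho_b(rho_b)
    n = _validate_n(n)
    alpha = _validate_alpha(alpha, upper=0.5)
    z_a = norm.isf(alpha)
    if method == "tost-r":
        half = rho_b - z_a * sigma_r(rho_b, n)
        if half <= 0.0:
            return RejectionRegion(method=method, lower=0.0, upper=0.0,
                                   alpha=alpha, n=n, empty=True)
        return RejectionRegion(method=method, lower=-half, upper=half,
                               alpha=alpha, n=n)
    zeta_half = fisher_z(rho_b) - z_a * sigma_zeta(n)
    if zeta_half <= 0.0:
        return RejectionRegion(method=method, lower=0.0, upper=0.0,
                               alpha=alpha, n=n, empty=True,
                               zeta_lower=0.0, zeta_upper=0.0)
    return RejectionRegion(
        method=method,
        lower=inverse_fisher_z(-zeta_half),
        upper=inverse_fisher_z(zeta_half),
        alpha=alpha,
        n=n,
        zeta_lower=-zeta_half,
        zeta_upper=zeta_half,
    )


def tost_min_sample_size(
    method: str, rho_b: float, alpha: float = 0.05
) -> TostDiagnostics:
    """Degeneracy threshold on N and the minimum nonempty sample size.

    Requiring a positive half-width gives the closed-form bounds

        TOST-r:     N > z_alpha^2 (1 + rho_B^2)^2 / rho_B^2 + 3
        TOST-zeta:  N > z_alpha^2 / zeta_B^2 + 3

    and min_n is the smallest integer strictly exceeding the threshold
    (the region is still empty at N equal to the zeta threshold, where the
    half-width vanishes exactly).

    The zeta-scale threshold is the exact flip point of the region.  The
    r-scale threshold is the conventional published form and is
    conservative: the half-width rho_B - z_alpha (1 - rho_B^2)/sqrt(N-3)
    actually turns positive at the smaller bound
    z_alpha^2 (1 - rho_B^2)^2 / rho_B^2 + 3, so every N >= min_n is
    guaranteed nonempty but some smaller N already are.
    """
    method = _validate_method(method)
    rho_b = _validate_rho_b(rho_b)
    alpha = _validate_alpha(alpha, upper=0.5)
    z_a = norm.isf(alpha)
    if method == "tost-r":
        threshold = z_a**2 * (1.0 + rho_b**2) ** 2 / rho_b**2 + 3.0
    else:
        threshold = z_a**2 / fisher_z(rho_b) ** 2 + 3.0
    min_n = math.floor(threshold) + 1
    # guard the exact-integer corner: strict inequality required
    if min_n <= threshold:  # pragma: no cover - needs threshold == integer
        min_n += 1
    return TostDiagnostics(
        method=method, alpha=alpha, rho_b=rho_b,
        threshold_real=threshold, min_n=min_n,
    )


def tost_true_type1(
    method: str, rho_b: float, n: int, alpha: float = 0.05
) -> float:
    """True Type I error rate of a TOST procedure at rho = +/- rho_B.

    Under the normal approximation the rejection probability at the bound is

        Phi(-z_alpha) - Phi(z_alpha - 2 b / s)

    with (b, s) = (rho_B, sigma_B) for TOST-r and (zeta_B, sigma_zeta) for
    TOST-zeta, truncated below at 0 (it is exactly 0 while the region is
    empty).  The rate is strictly below alpha for every finite N and has
    supremum alpha as N -> infinity.
    """
    method = _validate_method(method)
    rho_b = _validate_rho_b(rho_b)
    n = _validate_n(n)
    alpha = _validate_alpha(alpha, upper=0.5)
    if tost_region(method, rho_b, n, alpha).empty:
        return 0.0
    z_a = norm.isf(alpha)
    if method == "tost-r":
        b, s = rho_b, sigma_r(rho_b, n)
    else:
        b, s = fisher_z(rho_b), sigma_zeta(n)
    rate = norm.cdf(-z_a) - norm.cdf(z_a - 2.0 * b / s)
    return max(rate, 0.0)


def tost_region_general(
    bounds: EquivalenceBounds, n: int, alpha: float = 0.05, scale: str = "r"
) -> RejectionRegion:
    """Asymmetric-bounds TOST: an extension beyond the symmetric case.

    The standard TOST construction is defined only for the symmetric
    lack-of-association bounds; this generalization runs the two one-sided
    z tests at rho_L and rho_U with per-bound standard deviations (r scale)
    or the constant Fisher-z standard deviation (zeta scale).  Provided for
    completeness; it inherits the same degeneracy defect.
    """
    n = _validate_n(n)
    alpha = _validate_alpha(alpha, upper=0.5)
    z_a = norm.isf(alpha)
    if scale == "r":
        lower = bounds.rho_l + z_a * sigma_r(bounds.rho_l, n)
        upper = bounds.rho_u - z_a * sigma_r(bounds.rho_u, n)
        if lower >= upper:
            return RejectionRegion(method="tost-r", lower=0.0, upper=0.0,
                                   alpha=alpha, n=n, empty=True)
        return RejectionRegion(method="tost-r", lower=lower, upper=upper,
                               alpha=alpha, n=n)
    if scale != "zeta":
        raise ValueError(f"scale must be 'r' or 'zeta'; got {scale!r}")
    zl = bounds.zeta_l + z_a * sigma_zeta(n)
    zu = bounds.zeta_u - z_a * sigma_zeta(n)
    if zl >= zu:
        return RejectionRegion(method="tost-zeta", lower=0.0, upper=0.0,
                               alpha=alpha, n=n, empty=True,
                               zeta_lower=0.0, zeta_upper=0.0)
    return RejectionRegion(
        method="tost-zeta",
        lower=inverse_fisher_z(zl),
        upper=inverse_fisher_z(zu),
        alpha=alpha,
        n=n,
        zeta_lower=zl,
        zeta_upper=zu,
    )


def region_for(
    method: str, bounds: EquivalenceBounds, n: int, alpha: float = 0.05
) -> RejectionRegion:
    """Dispatch a rejection region for any of the four procedures."""
    from .regions import solve_equt_r, solve_equt_zeta

    method = method.lower().replace("_", "-")
    if method == "equt-r":
        return solve_equt_r(bounds, n, alpha)
    if method == "equt-zeta":
        return solve_equt_zeta(bounds, n, alpha)
    if method in _METHODS:
        if bounds.is_symmetric:
            return tost_region(method, bounds.rho_b, n, alpha)
        scale = "r" if method == "tost-r" else "zeta"
        return tost_region_general(bounds, n, alpha, scale=scale)
    raise ValueError(
        f"method must be one of ('equt-r', 'equt-zeta', 'tost-r', 'tost-zeta'); "
        f"got {method!r}"
    )
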