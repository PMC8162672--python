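"""Analytic power functions and sample-size determination.

For a solved rejection region (L, U) the power of an equivalence test at a
true correlation rho is the normal-approximation probability that the test
statistic lands in the region:

    Psi_r    = Phi((U - rho)/sigma_r) - Phi((L - rho)/sigma_r)
    Psi_zeta = Phi((u - zeta)/sigma_zeta) - Phi((l - zeta)/sigma_zeta)

with the zeta-based procedures evaluated wholly on the Fisher-z scale
(zeta = atanh(rho), (l, u) the native zeta-scale critical values).  At
rho equal to either equivalence bound the power reduces to the size alpha
by construction; strictly inside the bounds it grows to 1 with N, which is
what makes minimal-sample-size search well posed.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import norm

from .core import _validate_alpha, _validate_n, _validate_rho, fisher_z, sigma_r, sigma_zeta
from .regions import EquivalenceBounds, RejectionRegion
from .tost import region_for

__all__ = ["power", "power_of_region", "sample_size", "SampleSizeResult"]


def power_of_region(region: RejectionRegion, rho: float) -> float:
    """Normal-approximation rejection probability of a solved region at rho."""
    rho = _validate_rho(rho)
    if region.empty:
        return 0.0
    if region.zeta_lower is not None:
        s = sigma_zeta(region.n)
        z = fisher_z(rho)
        val = norm.cdf((region.zeta_upper - z) / s) - norm.cdf((region.zeta_lower - z) / s)
    else:
        s = sigma_r(rho, region.n)
        val = norm.cdf((region.upper - rho) / s) - norm.cdf((region.lower - rho) / s)
    return float(min(max(val, 0.0), 1.0))


def power(
    method: str,
    bounds: EquivalenceBounds,
    rho: float,
    n: int,
    alpha: float = 0.05,
) -> float:
    """Attained power of a named procedure at true correlation rho.

    Solves (or evaluates) the rejection region for (bounds, n, alpha) and
    integrates the approximate sampling distribution of the procedure's own
    statistic over it.  Outside the equivalence interval the returned value
    is a Type I error rate, still well defined.  Empty TOST regions give
    power 0.
    """
    n = _validate_n(n)
    alpha = _validate_alpha(alpha, upper=0.5)
    return power_of_region(region_for(method, bounds, n, alpha), rho)


@dataclass(frozen=True)
class SampleSizeResult:
    """Minimal sample size achieving a target power, with the power attained."""

    method: str
    n_star: int
    attained_power: float
    target_power: float
    rho: float
    bounds: EquivalenceBounds
    alpha: float


def sample_size(
    method: str,
    bounds: EquivalenceBounds,
    rho: float,
    alpha: float = 0.05,
    target_power: float = 0.80,
    max_n: int = 10**7,
) -> SampleSizeResult:
    """Smallest integer N >= 4 whose analytic power reaches the target.

    The critical region is re-solved at every candidate N.  Search is
    exponential bracketing (doubling from N = 8) followed by integer
    bisection; because the region endpoints are themselves N-dependent the
    power can wobble locally, so the bisection result is re-scanned over a
    +/- 2 window and the smallest qualifying N returned.

    Raises
    ------
    RuntimeError
        If no N <= ``max_n`` attains the target (e.g. rho too close to an
        equivalence bound, where power is pinned near alpha).
    """
    rho = _validate_rho(rho)
    alpha = _validate_alpha(alpha, upper=0.5)
    if not 0.0 < target_power < 1.0:
        raise ValueError(f"target_power must lie in (0, 1); got {target_power!r}")

    def pw(n: int) -> float:
        return power(method, bounds, rho, n, alpha)

    lo, hi = 4, 8
    if pw(lo) >= target_power:
        hi = lo
    else:
        while pw(hi) < target_power:
            lo = hi
            hi *= 2
            if hi > max_n:
                raise RuntimeError(
                    f"no sample size <= {max_n} attains power {target_power} for "
                    f"{method} at rho={rho} within bounds "
                    f"({bounds.rho_l}, {bounds.rho_u}); rho may be too close to a bound"
                )
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if pw(mid) >= target_power:
                hi = mid
            else:
                lo = mid
    # local guard against non-monotone wobble of the N-dependent region
    n_star = hi
    for cand in range(max(4, hi - 2), hi + 3):
        if pw(cand) >= target_power:
            n_star = cand
            break
    return SampleSizeResult(
        method=method,
        n_star=n_star,
        attained_power=pw(n_star),
        target_power=target_power,
        rho=rho,
        bounds=bounds,
        alpha=alpha,
    )
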