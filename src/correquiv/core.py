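"""Fisher's z transformation and the asymptotic sampling distributions of r.

For paired bivariate-normal observations the sample Pearson correlation r
is approximately N(rho, sigma_r^2) with sigma_r = (1 - rho^2)/sqrt(N - 3),
and Fisher's z statistic zeta_hat = atanh(r) is approximately
N(zeta, sigma_zeta^2) with sigma_zeta = 1/sqrt(N - 3).  These two normal
approximations are the substrate for every equivalence procedure in this
package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

__all__ = [
    "fisher_z",
    "inverse_fisher_z",
    "sigma_r",
    "sigma_zeta",
    "significance_test",
    "SignificanceResult",
]


def _validate_rho(rho: float, name: str = "rho") -> float:
    rho = float(rho)
    if not math.isfinite(rho) or not -1.0 < rho < 1.0:
        raise ValueError(f"{name} must lie strictly inside (-1, 1); got {rho!r}")
    return rho


def _validate_n(n: int) -> int:
    if n != int(n):
        raise ValueError(f"sample size must be an integer; got {n!r}")
    n = int(n)
    if n < 4:
        raise ValueError(f"sample size must be at least 4 so that N - 3 > 0; got {n}")
    return n


def _validate_alpha(alpha: float, upper: float = 1.0) -> float:
    alpha = float(alpha)
    if not 0.0 < alpha < upper:
        raise ValueError(f"alpha must lie in (0, {upper}); got {alpha!r}")
    return alpha


def fisher_z(rho: float) -> float:
    """Fisher's variance-stabilizing transformation atanh(rho).

    Strictly increasing odd bijection from (-1, 1) onto the real line;
    zeta = 0.5 * ln((1 + rho)/(1 - rho)).

    Raises
    ------
    ValueError
        If ``|rho| >= 1`` (the transform diverges at the boundary).
    """
    rho = _validate_rho(rho)
    return math.atanh(rho)


def inverse_fisher_z(zeta: float) -> float:
    """Back-transform tanh(zeta) = (e^{2 zeta} - 1)/(e^{2 zeta} + 1)."""
    zeta = float(zeta)
    if not math.isfinite(zeta):
        raise ValueError(f"zeta must be finite; got {zeta!r}")
    return math.tanh(zeta)


def sigma_r(rho: float, n: int) -> float:
    """Large-sample standard deviation of r: (1 - rho^2)/sqrt(n - 3)."""
    rho = _validate_rho(rho)
    n = _validate_n(n)
    return (1.0 - rho * rho) / math.sqrt(n - 3)


def sigma_zeta(n: int) -> float:
    """Large-sample standard deviation of Fisher's z: 1/sqrt(n - 3).

    Independent of the population correlation — the variance-stabilizing
    property that motivates the transformation.
    """
    n = _validate_n(n)
    return 1.0 / math.sqrt(n - 3)


@dataclass(frozen=True)
class SignificanceResult:
    """Outcome of the conventional two-sided test of H0: rho = rho0."""

    statistic: float
    p_value: float
    reject: bool
    r: float
    n: int
    rho0: float
    alpha: float


def significance_test(
    r: float, n: int, rho0: float = 0.0, alpha: float = 0.05
) -> SignificanceResult:
    """Conventional two-sided z test of H0: rho = rho0 via Fisher's z.

    The statistic is Z* = (atanh(r) - atanh(rho0)) * sqrt(n - 3); the null
    is rejected when ``|Z*|`` exceeds the upper alpha/2 standard-normal
    quantile.  Included to round out the correlation toolkit — the
    equivalence procedures in :mod:`correquiv.regions` invert the roles of
    the hypotheses.
    """
    r = _validate_rho(r, "r")
    rho0 = _validate_rho(rho0, "rho0")
    n = _validate_n(n)
    alpha = _validate_alpha(alpha)
    z_star = (math.atanh(r) - math.atanh(rho0)) * math.sqrt(n - 3)
    p = 2.0 * norm.sf(abs(z_star))
    return SignificanceResult(
        statistic=z_star,
        p_value=p,
        reject=bool(abs(z_star) > norm.isf(alpha / 2.0)),
        r=r,
        n=n,
        rho0=rho0,
        alpha=alpha,
    )
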