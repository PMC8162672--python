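"""Dual-constraint critical values of the extended equivalence tests."""

import numpy as np
import pytest
from scipy.stats import norm

from correquiv import (
    EquivalenceBounds,
    decide_equivalence,
    sigma_r,
    sigma_zeta,
    solve_equt_r,
    solve_equt_symmetric,
    solve_equt_zeta,
)
from reference_values import TABLE1_INTERVALS

CONFIGS = [
    (rho_l, rho_u, n)
    for (rho_l, rho_u) in TABLE1_INTERVALS
    for n in (25, 50, 100, 500)
] + [(-0.1, 0.1, 25), (-0.2, 0.2, 500), (-0.45, 0.6, 12)]


class TestBounds:
    def test_derived_zeta_image(self):
        b = EquivalenceBounds(0.0, 0.2)
        assert b.zeta_l == 0.0
        assert b.zeta_u == pytest.approx(np.arctanh(0.2), rel=1e-15)
        assert not b.is_symmetric

    def test_symmetric_constructor(self):
        b = EquivalenceBounds.symmetric(0.1)
        assert b.is_symmetric
        assert b.rho_b == 0.1
        assert b.zeta_b == pytest.approx(np.arctanh(0.1))

    @pytest.mark.parametrize("lo, hi", [(0.2, 0.1), (0.1, 0.1), (-1.0, 0.5), (0.0, 1.0)])
    def test_invalid_bounds_rejected(self, lo, hi):
        with pytest.raises(ValueError):
            EquivalenceBounds(lo, hi)

    def test_rho_b_requires_symmetry(self):
        with pytest.raises(ValueError):
            _ = EquivalenceBounds(0.0, 0.2).rho_b


def _size_at(region, rho, n, scale):
    """Independent recomputation of the rejection probability at a bound."""
    if scale == "zeta":
        s = sigma_zeta(n)
        lo, hi, mu = region.zeta_lower, region.zeta_upper, np.arctanh(rho)
    else:
        s = sigma_r(rho, n)
        lo, hi, mu = region.lower, region.upper, rho
    return norm.cdf((hi - mu) / s) - norm.cdf((lo - mu) / s)


@pytest.mark.parametrize("rho_l, rho_u, n", CONFIGS)
@pytest.mark.parametrize("alpha", [0.05, 0.01])
def test_size_constraints_hold_to_1e10(rho_l, rho_u, n, alpha):
    """Both rejection probabilities equal alpha at the equivalence bounds."""
    b = EquivalenceBounds(rho_l, rho_u)
    reg_r = solve_equt_r(b, n, alpha)
    for rho in (rho_l, rho_u):
        assert _size_at(reg_r, rho, n, "r") == pytest.approx(alpha, abs=1e-10)
    reg_z = solve_equt_zeta(b, n, alpha)
    for rho in (rho_l, rho_u):
        assert _size_at(reg_z, rho, n, "zeta") == pytest.approx(alpha, abs=1e-10)


@pytest.mark.parametrize(
    "method, rho_l, rho_u, n, expected",
    [
        ("equt-r", 0.0, 0.20, 500, (0.0730, 0.1298)),
        ("equt-r", 0.05, 0.15, 25, (0.0780, 0.1051)),
        ("equt-zeta", 0.0, 0.20, 500, (0.0728, 0.1290)),
        ("equt-zeta", 0.15, 0.25, 25, (0.1873, 0.2137)),
    ],
)
def test_reference_intervals_to_4dp(method, rho_l, rho_u, n, expected):
    solver = solve_equt_r if method == "equt-r" else solve_equt_zeta
    reg = solver(EquivalenceBounds(rho_l, rho_u), n)
    assert (round(reg.lower, 4), round(reg.upper, 4)) == expected


@pytest.mark.parametrize("rho_l, rho_u, n", [(0.0, 0.2, 25), (0.1, 0.3, 100)])
def test_reflection_symmetry(rho_l, rho_u, n):
    """Negating the bounds negates and swaps the region."""
    fwd = solve_equt_r(EquivalenceBounds(rho_l, rho_u), n)
    rev = solve_equt_r(EquivalenceBounds(-rho_u, -rho_l), n)
    assert rev.lower == pytest.approx(-fwd.upper, abs=1e-12)
    assert rev.upper == pytest.approx(-fwd.lower, abs=1e-12)


def test_zeta_region_midpoint_symmetry():
    b = EquivalenceBounds(0.05, 0.15)
    reg = solve_equt_zeta(b, 80)
    assert reg.zeta_lower + reg.zeta_upper == pytest.approx(
        b.zeta_l + b.zeta_u, abs=1e-12
    )
    # r-scale endpoints are exactly the tanh images
    assert reg.lower == np.tanh(reg.zeta_lower)
    assert reg.upper == np.tanh(reg.zeta_upper)


@pytest.mark.parametrize("rho_b", [0.1, 0.2])
@pytest.mark.parametrize("n", [25, 100, 500])
@pytest.mark.parametrize("scale", ["r", "zeta"])
def test_symmetric_shortcut_matches_general_solver(rho_b, n, scale):
    shortcut = solve_equt_symmetric(rho_b, n, scale=scale)
    b = EquivalenceBounds.symmetric(rho_b)
    general = solve_equt_r(b, n) if scale == "r" else solve_equt_zeta(b, n)
    assert shortcut.lower == pytest.approx(general.lower, abs=1e-8)
    assert shortcut.upper == pytest.approx(general.upper, abs=1e-8)
    assert shortcut.upper == pytest.approx(-shortcut.lower, abs=1e-12)


def test_symmetric_critical_value_tends_to_bound():
    # as N grows at fixed rho_B the critical value approaches rho_B
    # approach is at the z_alpha * sigma_B ~ n^{-1/2} rate
    vals = [solve_equt_symmetric(0.2, n).upper for n in (100, 10_000, 10_000_000)]
    assert vals == sorted(vals)
    assert vals[-1] == pytest.approx(0.2, abs=1e-3)


def test_grid_search_oracle_symmetric():
    """Brute-force scan of the one-dimensional size equation, step 1e-6."""
    rho_b, n, alpha = 0.2, 50, 0.05
    s = sigma_r(rho_b, n)
    grid = np.arange(0.0, rho_b + 10 * s, 1e-6)
    size = norm.cdf((grid - rho_b) / s) - norm.cdf(-(grid + rho_b) / s)
    oracle = grid[np.argmin(np.abs(size - alpha))]
    solved = solve_equt_symmetric(rho_b, n).upper
    assert solved == pytest.approx(oracle, abs=1e-6)


def test_grid_search_oracle_asymmetric():
    """Coarse-to-fine scan over (L, U) pairs for asymmetric bounds."""
    rho_l, rho_u, n, alpha = 0.0, 0.2, 25, 0.05
    s_l, s_u = sigma_r(rho_l, n), sigma_r(rho_u, n)

    def best_on(lo_grid, up_grid):
        L, U = np.meshgrid(lo_grid, up_grid, indexing="ij")
        res1 = norm.cdf((U - rho_l) / s_l) - norm.cdf((L - rho_l) / s_l) - alpha
        res2 = norm.cdf((U - rho_u) / s_u) - norm.cdf((L - rho_u) / s_u) - alpha
        worst = np.maximum(np.abs(res1), np.abs(res2))
        i, j = np.unravel_index(np.argmin(worst), worst.shape)
        return lo_grid[i], up_grid[j]

    lo, up = best_on(np.arange(-0.1, 0.2, 1e-3), np.arange(0.0, 0.3, 1e-3))
    lo, up = best_on(np.arange(lo - 2e-3, lo + 2e-3, 1e-6),
                     np.arange(up - 2e-3, up + 2e-3, 1e-6))
    reg = solve_equt_r(EquivalenceBounds(rho_l, rho_u), n, alpha)
    assert reg.lower == pytest.approx(lo, abs=2e-6)
    assert reg.upper == pytest.approx(up, abs=2e-6)


@pytest.mark.parametrize("rho_l, rho_u", list(TABLE1_INTERVALS))
@pytest.mark.parametrize("n", [150, 300, 500])
def test_r_and_zeta_regions_converge_for_large_n(rho_l, rho_u, n):
    """The two extended procedures become nearly identical for N >= 150."""
    b = EquivalenceBounds(rho_l, rho_u)
    reg_r = solve_equt_r(b, n)
    reg_z = solve_equt_zeta(b, n)
    assert abs(reg_r.lower - reg_z.lower) < 2.5e-3
    assert abs(reg_r.upper - reg_z.upper) < 2.5e-3


class TestDecision:
    def test_interior_rejects_boundary_does_not(self):
        reg = solve_equt_zeta(EquivalenceBounds(0.0, 0.2), 500)
        mid = 0.5 * (reg.lower + reg.upper)
        assert decide_equivalence(mid, reg).reject_null
        assert not decide_equivalence(reg.upper, reg).reject_null

    def test_published_interval_decision(self):
        # observed r = 0.09 inside the (0.0728, 0.1290) region at N = 500
        reg = solve_equt_zeta(EquivalenceBounds(0.0, 0.2), 500)
        d = decide_equivalence(0.09, reg)
        assert d.reject_null
        assert d.conclusion == "equivalence declared"
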