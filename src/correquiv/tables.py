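"""Regenerate the package's benchmark tables of critical values and power.

Four standing study designs are wired in (the same grids used throughout
the documentation): critical intervals of the extended equivalence tests
over four asymmetric reference ranges (``T1``); critical intervals of all
four lack-of-association tests at rho_B = 0.1 and 0.2 (``T3``); simulated
powers of the four tests over a rho x rho_B x N grid (``T4``); and minimal
sample sizes with estimated and simulated power for the two extended tests
over fourteen design rows (``T5``).  Deterministic columns (intervals, N,
estimated power) are exact recomputations; simulated columns are fresh
Monte-Carlo estimates carrying their own standard errors.  Pass
``replicates=0`` to emit only the deterministic columns.
"""

from __future__ import annotations

from typing import List

import numpy as np
import pandas as pd

from .power import power_of_region, sample_size
from .regions import EquivalenceBounds
from .simulate import SimulationConfig, estimate_rejection_rate
from .tost import region_for

__all__ = ["reproduce_table", "TABLE_IDS"]

TABLE_IDS = ("T1", "T3", "T4", "T5")

_T1_BOUNDS = [(0.00, 0.20), (0.05, 0.15), (0.10, 0.30), (0.15, 0.25)]
_T1_N = [25, 50, 100, 500]
_T3_RHO_B = [0.10, 0.20]
_T3_N = [25, 50, 100, 500]
_T4_N = [25, 50, 100, 200, 300, 400, 500]
_T4_RHO = [0.0, 0.05]
_T5_ROWS = [
    ((0.0, 0.2), 0.1),
    ((0.1, 0.3), 0.2),
    ((0.2, 0.4), 0.3),
    ((0.3, 0.5), 0.4),
    ((0.4, 0.6), 0.5),
    ((-0.1, 0.1), 0.0),
    ((-0.1, 0.1), 0.05),
    ((-0.2, 0.2), 0.0),
    ((-0.2, 0.2), 0.1),
    ((-0.2, 0.2), 0.15),
    ((-0.3, 0.3), 0.0),
    ((-0.3, 0.3), 0.1),
    ((-0.3, 0.3), 0.2),
    ((-0.3, 0.3), 0.25),
]
_EQUT = ("equt-r", "equt-zeta")
_ALL = ("equt-r", "equt-zeta", "tost-r", "tost-zeta")


def _child_seeds(seed: int, k: int) -> List[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(k, dtype=np.uint32)]


def _critical_table(
    bound_pairs, methods, replicates: int, seed: int, alpha: float
) -> pd.DataFrame:
    rows = []
    seeds = iter(_child_seeds(seed, len(bound_pairs) * len(_T1_N)))
    for rho_l, rho_u in bound_pairs:
        bounds = EquivalenceBounds(rho_l, rho_u)
        for n in _T1_N:
            cell_seed = next(seeds)
            regions = {m: region_for(m, bounds, n, alpha) for m in methods}
            rates = {}
            if replicates:
                # simulated Type I error taken at the upper bound rho_U
                config = SimulationConfig(
                    rho=rho_u, n=n, replicates=replicates, seed=cell_seed
                )
                results = estimate_rejection_rate(config, list(regions.values()))
                rates = {m: results[m] for m in methods}
            for m in methods:
                reg = regions[m]
                row = {
                    "rho_l": rho_l,
                    "rho_u": rho_u,
                    "n": n,
                    "method": m,
                    "lower": reg.lower,
                    "upper": reg.upper,
                    "empty": reg.empty,
                }
                if replicates:
                    row["simulated_type1"] = rates[m].rejection_rate
                    row["error"] = rates[m].rejection_rate - alpha
                    row["mc_se"] = rates[m].monte_carlo_se
                    row["seed"] = cell_seed
                    row["replicates"] = replicates
                rows.append(row)
    return pd.DataFrame(rows)


def _power_table(replicates: int, seed: int, alpha: float) -> pd.DataFrame:
    rows = []
    combos = [
        (rho_b, rho, n) for rho_b in _T3_RHO_B for rho in _T4_RHO for n in _T4_N
    ]
    seeds = iter(_child_seeds(seed, len(combos)))
    for rho_b, rho, n in combos:
        cell_seed = next(seeds)
        bounds = EquivalenceBounds.symmetric(rho_b)
        regions = {m: region_for(m, bounds, n, alpha) for m in _ALL}
        results = {}
        if replicates:
            config = SimulationConfig(rho=rho, n=n, replicates=replicates, seed=cell_seed)
            results = estimate_rejection_rate(config, list(regions.values()))
        for m in _ALL:
            row = {
                "rho_b": rho_b,
                "rho": rho,
                "n": n,
                "method": m,
                "power_formula": power_of_region(regions[m], rho),
                "empty": regions[m].empty,
            }
            if replicates:
                row["simulated_power"] = results[m].rejection_rate
                row["mc_se"] = results[m].monte_carlo_se
                row["seed"] = cell_seed
                row["replicates"] = replicates
            rows.append(row)
    return pd.DataFrame(rows)


def _samplesize_table(
    replicates: int, seed: int, alpha: float, target_power: float
) -> pd.DataFrame:
    rows = []
    seeds = iter(_child_seeds(seed, len(_T5_ROWS) * len(_EQUT)))
    for (rho_l, rho_u), rho in _T5_ROWS:
        bounds = EquivalenceBounds(rho_l, rho_u)
        for m in _EQUT:
            cell_seed = next(seeds)
            res = sample_size(m, bounds, rho, alpha, target_power)
            row = {
                "rho_l": rho_l,
                "rho_u": rho_u,
                "rho": rho,
                "method": m,
                "n": res.n_star,
                "estimated_power": res.attained_power,
            }
            if replicates:
                config = SimulationConfig(
                    rho=rho, n=res.n_star, replicates=replicates, seed=cell_seed
                )
                region = region_for(m, bounds, res.n_star, alpha)
                sim = estimate_rejection_rate(config, region)
                row["simulated_power"] = sim.rejection_rate
                row["error"] = sim.rejection_rate - res.attained_power
                row["mc_se"] = sim.monte_carlo_se
                row["seed"] = cell_seed
                row["replicates"] = replicates
            rows.append(row)
    return pd.DataFrame(rows)


def reproduce_table(
    table_id: str,
    replicates: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    target_power: float = 0.80,
) -> pd.DataFrame:
    """Recompute one of the standing benchmark tables as a tidy DataFrame.

    Parameters
    ----------
    table_id : {"T1", "T3", "T4", "T5"}
        Which study design to regenerate (see module docstring).
    replicates : int
        Monte-Carlo replicates per simulated cell; 0 skips the simulated
        columns entirely.
    seed : int
        Master seed; each cell receives an independent child seed derived
        from it, so the whole table is reproducible.
    """
    table_id = table_id.upper()
    if table_id not in TABLE_IDS:
        raise ValueError(f"table_id must be one of {TABLE_IDS}; got {table_id!r}")
    if replicates < 0 or replicates != int(replicates):
        raise ValueError(f"replicates must be a nonnegative integer; got {replicates!r}")
    replicates = int(replicates)
    if table_id == "T1":
        return _critical_table(_T1_BOUNDS, _EQUT, replicates, seed, alpha)
    if table_id == "T3":
        pairs = [(-b, b) for b in _T3_RHO_B]
        return _critical_table(pairs, _ALL, replicates, seed, alpha)
    if table_id == "T4":
        return _power_table(replicates, seed, alpha)
    return _samplesize_table(replicates, seed, alpha, target_power)
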