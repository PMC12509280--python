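"""Probabilistic sensitivity analysis over unit costs.

Every cost item is given a gamma distribution parameterised by the method
of moments from a mean and a 95% interval obtained by halving and doubling
the mean.  Strategy outcomes are *frozen* (discounted event counts and
QALYs from one simulation run); each PSA draw re-prices the strategies,
rebuilds the efficient frontier and records the optimal strategy at each
willingness-to-pay value, yielding cost-effectiveness acceptability
curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cea import COST_ITEMS, CostBasis, CostSchedule, efficient_frontier

__all__ = ["CostDistributionSpec", "PSAResult", "gamma_from_mean", "build_specs", "run_psa"]

#: 95% interval width in standard deviations under the normal approximation
_CI_WIDTH_SD = 3.92


@dataclass
class CostDistributionSpec:
    """Gamma distribution of one unit cost (method of moments)."""

    mean: float
    sd: float
    shape: float  # k = mu^2 / sigma^2
    scale: float  # theta = sigma^2 / mu
    ci95: Tuple[float, float]

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.sd == 0.0:
            return np.full(size, self.mean)
        return rng.gamma(self.shape, self.scale, size)


def gamma_from_mean(mean: float, ci_rule: str = "half_double") -> CostDistributionSpec:
    """Spec from a mean: CI = (mean/2, 2 mean), sd = CI width / 3.92."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    if ci_rule != "half_double":
        raise ValueError(f"unknown ci rule {ci_rule!r}")
    lo, hi = mean / 2.0, 2.0 * mean
    sd = (hi - lo) / _CI_WIDTH_SD
    return CostDistributionSpec(
        mean=mean, sd=sd, shape=mean**2 / sd**2, scale=sd**2 / mean, ci95=(lo, hi)
    )


def build_specs(costs: CostSchedule, zero_variance: bool = False) -> Dict[str, CostDistributionSpec]:
    """One distribution per cost item with a positive base value."""
    specs: Dict[str, CostDistributionSpec] = {}
    for item, value in zip(COST_ITEMS, costs.item_values()):
        if value <= 0:
            continue
        spec = gamma_from_mean(value)
        if zero_variance:
            spec = CostDistributionSpec(value, 0.0, np.inf, 0.0, (value, value))
        specs[item] = spec
    return specs


@dataclass
class PSAResult:
    """Per-draw optima and acceptability curves."""

    n_draws: int
    wtp_grid: np.ndarray
    draw_optimal: pd.DataFrame  # draws x wtp grid, strategy names
    ceac: pd.DataFrame  # wtp grid x strategy, probability optimal
    prob_optimal: pd.Series  # at the base willingness-to-pay

    def probability_optimal(self, strategy: str, wtp: float) -> float:
        row = self.ceac.loc[wtp]
        return float(row.get(strategy, 0.0))


def run_psa(
    frozen: Dict[str, Tuple[CostBasis, float]],
    specs: Dict[str, CostDistributionSpec],
    n_draws: int = 1000,
    seed: int = 0,
    wtp_grid: Optional[Sequence[float]] = None,
    base_wtp: float = 20_000.0,
) -> PSAResult:
    """Re-price frozen outcomes under ``n_draws`` cost sets.

    ``frozen`` maps strategy name to ``(cost basis, qalys per 1000)``.
    Cost items are drawn independently (no correlation structure is
    assumed).  Deterministic per seed.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    wtps = np.asarray(sorted(set([*map(float, wtp_grid or [])] + [float(base_wtp)])))
    rng = np.random.default_rng(seed)

    names = list(frozen)
    basis_matrix = np.stack([frozen[name][0].counts for name in names])
    qalys = np.array([frozen[name][1] for name in names])

    item_index = [COST_ITEMS.index(item) for item in specs]
    base_values = np.zeros(len(COST_ITEMS))
    draws = np.tile(base_values, (n_draws, 1))
    for j, (item, spec) in zip(item_index, specs.items()):
        draws[:, j] = spec.sample(rng, n_draws)

    optima = np.empty((n_draws, wtps.size), dtype=object)
    for d in range(n_draws):
        cost = basis_matrix @ draws[d]
        fr = efficient_frontier(list(zip(names, qalys, cost)), wtp=float(wtps[0]))
        for wi, wtp in enumerate(wtps):
            opt = fr.frontier[0]
            for nm in fr.frontier:
                ic = fr.icers[nm]
                if ic is None or ic <= wtp:
                    opt = nm
            optima[d, wi] = opt

    draw_optimal = pd.DataFrame(optima, columns=wtps)
    ceac = pd.DataFrame(
        {
            wtp: draw_optimal[wtp].value_counts(normalize=True).reindex(names, fill_value=0.0)
            for wtp in wtps
        }
    ).T
    ceac.index.name = "wtp"
    prob_optimal = ceac.loc[float(base_wtp)]
    return PSAResult(
        n_draws=n_draws,
        wtp_grid=wtps,
        draw_optimal=draw_optimal,
        ceac=ceac,
        prob_optimal=prob_optimal,
    )
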