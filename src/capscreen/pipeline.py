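"""End-to-end model facade, run configuration and report generation.

`ScreeningCEAModel` ties the stages together in a fit/results idiom:
construct the model with strategies, adherence, costs and utilities, call
:meth:`ScreeningCEAModel.fit` to calibrate the natural history, simulate
the cohort and evaluate every strategy, and work with the returned
:class:`ScreeningCEAResults` (outcome tables, efficient frontier, PSA,
threshold search, summary).

`run_pipeline` drives the same flow from a YAML-serialisable
:class:`RunConfig` and writes the report bundle (CSV/JSON artifacts); the
command-line interface is a thin wrapper around it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .cea import (
    CEAConfig,
    CostBasis,
    CostSchedule,
    FrontierResult,
    StrategyOutcomes,
    UtilitySchedule,
    cost_per_qaly,
    efficient_frontier,
    load_default_costs_utilities,
    percent_reduction,
    threshold_search,
)
from .engine import count_tests, no_screening_run, run_strategy
from .lifetable import LifeTable
from .natural_history import (
    CalibrationResult,
    CalibrationTargets,
    NaturalHistoryModel,
    NaturalHistoryParams,
    simulate_cohort,
)
from .psa import PSAResult, build_specs, run_psa
from .screening_tests import load_default_profiles
from .strategies import (
    ADHERENCE_SCENARIOS,
    STRATEGY_NAMES,
    AdherenceScenario,
    Strategy,
    build_canonical_strategies,
)

__all__ = [
    "RunConfig",
    "ScreeningCEAModel",
    "ScreeningCEAResults",
    "run_pipeline",
    "make_table3",
    "make_table4",
]


def _derive_seed(seed: int, k: int) -> int:
    return (seed * 1_000_003 + k) % (2**31 - 1)


# ----------------------------------------------------------------------
class RunConfig(BaseModel):
    """Validated run configuration (YAML-friendly)."""

    cohort_size: int = Field(default=200_000, ge=1)
    calibration_size: int = Field(default=100_000, ge=1000)
    seed: int = 1
    strategies: List[str] = Field(default_factory=lambda: list(STRATEGY_NAMES))
    adherence: str = "full"
    surveillance_overrides: Dict[str, float] = Field(default_factory=dict)
    costs_file: Optional[str] = None
    utilities_file: Optional[str] = None
    life_table_file: Optional[str] = None
    discount_rate: float = Field(default=0.03, ge=0)
    wtp: float = Field(default=20_000.0, gt=0)
    cce_review_cost: float = Field(default=0.0, ge=0)
    psa_enabled: bool = False
    psa_draws: int = Field(default=1000, ge=1)
    threshold_enabled: bool = False
    threshold_bracket: Tuple[float, float] = (1.0, 600.0)
    output_dir: str = "capscreen_output"

    @field_validator("strategies")
    @classmethod
    def _known_strategies(cls, v: List[str]) -> List[str]:
        if not v:
            raise ValueError(
                f"strategies must not be empty; valid names: {sorted(STRATEGY_NAMES)}"
            )
        unknown = set(v) - set(STRATEGY_NAMES)
        if unknown:
            raise ValueError(
                f"unknown strategies {sorted(unknown)}; valid names: {sorted(STRATEGY_NAMES)}"
            )
        return v

    @field_validator("adherence")
    @classmethod
    def _known_adherence(cls, v: str) -> str:
        if v not in ADHERENCE_SCENARIOS:
            raise ValueError(
                f"unknown adherence scenario {v!r}; valid: {sorted(ADHERENCE_SCENARIOS)}"
            )
        return v

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def resolve_files(self) -> None:
        for name in ("costs_file", "utilities_file", "life_table_file"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: no such file {p!r}")


# ----------------------------------------------------------------------
@dataclass
class ScreeningCEAResults:
    """Fitted outcomes of a full screening evaluation."""

    calibration: Optional[CalibrationResult]
    params: NaturalHistoryParams
    baseline: StrategyOutcomes
    outcomes: Dict[str, StrategyOutcomes]
    config: CEAConfig
    costs: CostSchedule
    utilities: UtilitySchedule
    n: int
    seed: int
    adherence: AdherenceScenario

    # -- tables --------------------------------------------------------
    def table3(self) -> pd.DataFrame:
        return make_table3(list(self.outcomes.values()), self.baseline)

    def table4(self) -> pd.DataFrame:
        return make_table4(list(self.outcomes.values()), self.baseline)

    def frontier(self, wtp: Optional[float] = None) -> FrontierResult:
        rows = [("no_screening", self.baseline.qalys, self.baseline.total_cost)]
        rows += [(o.name, o.qalys, o.total_cost) for o in self.outcomes.values()]
        return efficient_frontier(rows, wtp=wtp or self.config.wtp)

    def frozen(self) -> Dict[str, Tuple[CostBasis, float]]:
        """Cost bases + QALYs for re-pricing (PSA, threshold search)."""
        out = {"no_screening": (self.baseline.basis, self.baseline.qalys)}
        out.update({o.name: (o.basis, o.qalys) for o in self.outcomes.values()})
        return out

    # -- analyses on frozen outcomes -----------------------------------
    def run_psa(
        self,
        n_draws: int = 1000,
        seed: Optional[int] = None,
        wtp_grid: Optional[Sequence[float]] = None,
        zero_variance: bool = False,
    ) -> PSAResult:
        specs = build_specs(self.costs, zero_variance=zero_variance)
        return run_psa(
            self.frozen(),
            specs,
            n_draws=n_draws,
            seed=_derive_seed(self.seed, 77) if seed is None else seed,
            wtp_grid=wtp_grid,
            base_wtp=self.config.wtp,
        )

    def cce_cost_threshold(
        self,
        strategy: str = "biennial_cce",
        criterion: str = "on_frontier",
        bracket: Tuple[float, float] = (1.0, 600.0),
        tol: float = 0.5,
    ):
        """Capsule unit cost at which ``strategy`` becomes cost effective.

        ``criterion`` is ``on_frontier`` (member of the efficient
        frontier) or ``optimal_at_wtp``.
        """
        frozen = self.frozen()
        if strategy not in frozen:
            raise ValueError(f"strategy {strategy!r} is not among the fitted outcomes")
        values = self.costs.item_values()

        def crit(cce_cost: float) -> bool:
            v = values.copy()
            from .cea import COST_ITEMS

            v[COST_ITEMS.index("cce")] = cce_cost
            table = [(name, q, float(b.counts @ v)) for name, (b, q) in frozen.items()]
            fr = efficient_frontier(table, wtp=self.config.wtp)
            if criterion == "on_frontier":
                return fr.status[strategy] == "frontier"
            if criterion == "optimal_at_wtp":
                return fr.optimal == strategy
            raise ValueError(f"unknown criterion {criterion!r}")

        return threshold_search(crit, bracket, tol=tol)

    # -- reductions ----------------------------------------------------
    def reductions(self) -> pd.DataFrame:
        rows = []
        for o in self.outcomes.values():
            rows.append(
                {
                    "strategy": o.name,
                    "incidence_reduction_pct": percent_reduction(
                        self.baseline.crc_cases, o.crc_cases
                    ),
                    "mortality_reduction_pct": percent_reduction(
                        self.baseline.crc_deaths, o.crc_deaths
                    ),
                }
            )
        return pd.DataFrame(rows).set_index("strategy")

    def summary(self) -> str:
        fr = self.frontier()
        lines = []
        if self.calibration is not None:
            lines += [self.calibration.summary(), ""]
        lines += [
            f"Screening evaluation: {self.n:,} persons, adherence '{self.adherence.name}',"
            f" discount {self.config.discount_rate:.0%}, WTP EUR {self.config.wtp:,.0f}/QALY",
            "",
            self.table4().to_string(),
            "",
            "Efficient frontier: " + " -> ".join(fr.frontier),
            f"Optimal at WTP: {fr.optimal}",
        ]
        return "\n".join(lines)


def make_table3(outcomes: List[StrategyOutcomes], baseline: StrategyOutcomes) -> pd.DataFrame:
    """Per-1000 discounted test counts and lifetime CRC burden by strategy."""
    rows = []
    for o in [baseline] + outcomes:
        rows.append(
            {
                "strategy": o.name,
                "fits": int(round(o.tests.get("fit", 0.0))),
                "cces": int(round(o.tests.get("cce", 0.0))),
                "colonoscopies": int(round(o.tests.get("colonoscopy", 0.0))),
                "complications": round(o.complications, 2),
                "crc_cases": int(round(o.crc_cases)),
                "crc_deaths": int(round(o.crc_deaths)),
            }
        )
    return pd.DataFrame(rows).set_index("strategy")


def make_table4(outcomes: List[StrategyOutcomes], baseline: StrategyOutcomes) -> pd.DataFrame:
    """Discounted life years, QALYs, gains, costs and cost/QALY by strategy.

    Rows are ordered by ascending total cost, baseline included.
    """
    if baseline is None:
        raise ValueError("a no-screening baseline is required")
    rows = []
    for o in [baseline] + outcomes:
        ly_g = 0.0 if o is baseline else o.life_years - baseline.life_years
        q_g = 0.0 if o is baseline else o.qalys - baseline.qalys
        rows.append(
            {
                "strategy": o.name,
                "life_years": int(round(o.life_years)),
                "qalys": int(round(o.qalys)),
                "ly_gained": int(round(ly_g)),
                "qaly_gained": int(round(q_g)),
                "cost": int(round(o.total_cost)),
                "cost_per_qaly": cost_per_qaly(o.total_cost, o.qalys),
            }
        )
    return pd.DataFrame(rows).set_index("strategy").sort_values("cost")


# ----------------------------------------------------------------------
class ScreeningCEAModel:
    """Full evaluation model: natural history + strategies + economics.

    Parameters default to the shipped Table-style inputs; ``fit`` runs
    calibration (unless pre-calibrated parameters are supplied), simulates
    the cohort once, replays it under every strategy with common random
    numbers, and accounts costs and QALYs.
    """

    def __init__(
        self,
        strategies: Optional[List[Strategy]] = None,
        adherence: AdherenceScenario = ADHERENCE_SCENARIOS["full"],
        profiles=None,
        costs: Optional[CostSchedule] = None,
        utilities: Optional[UtilitySchedule] = None,
        config: Optional[CEAConfig] = None,
        targets: Optional[CalibrationTargets] = None,
        life_table: Optional[LifeTable] = None,
        params: Optional[NaturalHistoryParams] = None,
    ):
        self.strategies = strategies or build_canonical_strategies()
        self.adherence = adherence
        self.profiles = profiles or load_default_profiles()
        default_costs, default_utils = load_default_costs_utilities()
        self.costs = costs or default_costs
        self.utilities = utilities or default_utils
        self.config = config or CEAConfig()
        self.targets = targets or CalibrationTargets()
        self.life_table = life_table or LifeTable.gompertz_makeham()
        self.params = params

    def fit(
        self,
        n: int = 200_000,
        calibration_size: int = 100_000,
        seed: int = 1,
    ) -> ScreeningCEAResults:
        calibration = None
        params = self.params
        if params is None:
            calibration = NaturalHistoryModel(
                targets=self.targets, life_table=self.life_table
            ).fit(sim_size=calibration_size, seed=_derive_seed(seed, 1))
            params = calibration.params

        cohort = simulate_cohort(params, self.life_table, n, seed=_derive_seed(seed, 2))
        from .cea import strategy_outcomes  # local import avoids cycle at module load

        baseline = strategy_outcomes(
            no_screening_run(cohort), self.costs, self.utilities, self.config
        )
        outcomes: Dict[str, StrategyOutcomes] = {}
        screen_seed = _derive_seed(seed, 3)
        for strat in self.strategies:
            run = run_strategy(
                cohort, strat, self.adherence, self.profiles, seed=screen_seed
            )
            outcomes[strat.name] = strategy_outcomes(
                run, self.costs, self.utilities, self.config, baseline=baseline
            )
        return ScreeningCEAResults(
            calibration=calibration,
            params=params,
            baseline=baseline,
            outcomes=outcomes,
            config=self.config,
            costs=self.costs,
            utilities=self.utilities,
            n=n,
            seed=seed,
            adherence=self.adherence,
        )


# ----------------------------------------------------------------------
def run_pipeline(config: RunConfig, stages: Optional[set] = None) -> Dict[str, Path]:
    """Execute the configured stages and write the report bundle.

    Stages: ``calibrate``, ``simulate``, ``cea`` (always implied by later
    stages), ``psa``, ``threshold``.  Returns the paths written.  The same
    config and seed produce byte-identical artifacts.
    """
    config.resolve_files()
    stages = stages or {"calibrate", "simulate", "cea"}
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    costs, utilities = load_default_costs_utilities()
    if config.cce_review_cost:
        costs.cce_review = config.cce_review_cost
    life_table = (
        LifeTable.from_yaml(config.life_table_file)
        if config.life_table_file
        else LifeTable.gompertz_makeham()
    )
    all_strategies = {s.name: s for s in build_canonical_strategies()}
    chosen = [all_strategies[name] for name in config.strategies]
    if config.surveillance_overrides:
        chosen = [s.with_policy(**config.surveillance_overrides) for s in chosen]

    model = ScreeningCEAModel(
        strategies=chosen,
        adherence=ADHERENCE_SCENARIOS[config.adherence],
        costs=costs,
        utilities=utilities,
        config=CEAConfig(discount_rate=config.discount_rate, wtp=config.wtp),
        life_table=life_table,
    )
    results = model.fit(
        n=config.cohort_size,
        calibration_size=config.calibration_size,
        seed=config.seed,
    )

    written: Dict[str, Path] = {}

    def save_csv(name: str, frame: pd.DataFrame) -> None:
        path = outdir / name
        frame.to_csv(path, float_format="%.6f")
        written[name] = path

    path = outdir / "params.yaml"
    results.params.to_yaml(path)
    written["params.yaml"] = path

    save_csv("table3.csv", results.table3())
    save_csv("table4.csv", results.table4())
    save_csv("reductions.csv", results.reductions())

    fr = results.frontier()
    frontier_payload = {
        "wtp": fr.wtp,
        "frontier": fr.frontier,
        "optimal": fr.optimal,
        "status": fr.status,
        "icers": fr.icers,
        "points": {
            name: {"qalys": q, "cost": c}
            for name, q, c in [
                ("no_screening", results.baseline.qalys, results.baseline.total_cost)
            ]
            + [(o.name, o.qalys, o.total_cost) for o in results.outcomes.values()]
        },
    }
    path = outdir / "frontier.json"
    path.write_text(json.dumps(frontier_payload, indent=2, sort_keys=True))
    written["frontier.json"] = path

    if "psa" in stages:
        psa = results.run_psa(n_draws=config.psa_draws)
        save_csv("psa_ceac.csv", psa.ceac)

    if "threshold" in stages:
        capsule = [
            s for s in ("biennial_cce", "triennial_cce", "cce_triage")
            if s in config.strategies
        ]
        if capsule:
            th = results.cce_cost_threshold(
                strategy=capsule[0], bracket=config.threshold_bracket
            )
            payload = {
                "strategy": capsule[0],
                "criterion": "on_frontier",
                "found": th.found,
                "threshold": th.threshold,
                "bracket": list(th.bracket),
            }
        else:
            payload = {
                "found": False,
                "reason": "no capsule strategy in the configured strategy list",
            }
        path = outdir / "threshold.json"
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        written["threshold.json"] = path

    log = {
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(config.model_dump_json()),
        "artifact_sha256": {
            name: hashlib.sha256(p.read_bytes()).hexdigest() for name, p in written.items()
        },
    }
    path = outdir / "run_log.json"
    path.write_text(json.dumps(log, indent=2, sort_keys=True))
    written["run_log.json"] = path
    return written
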