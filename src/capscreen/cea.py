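"""Health-economic evaluation of screening runs.

Converts event logs and resolved life histories into discounted life
years, QALYs and costs (healthcare-sector perspective, EUR 2018), and
performs the decision analysis: strong and extended dominance, the
efficient frontier, ICERs, the willingness-to-pay decision, and a
threshold search on a unit cost.

Discounting uses a common reference age (the first invitation age, 55 by
default) for every strategy including the no-screening arm; years lived
before the reference age are not discounted.  Treatment costs and
disease-related utility losses follow three phases of care keyed to stage
at diagnosis: the initial year after diagnosis, ongoing whole years in
between, and the terminal last year of life, which depends on the cause of
death.  When diagnosis and death fall in the same year the terminal phase
takes precedence.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .engine import StrategyRun

__all__ = [
    "CostSchedule",
    "UtilitySchedule",
    "CEAConfig",
    "CostBasis",
    "StrategyOutcomes",
    "FrontierResult",
    "ThresholdResult",
    "load_default_costs_utilities",
    "discounted_value",
    "discount_weight",
    "life_years_discounted",
    "strategy_outcomes",
    "person_qaly",
    "person_cost",
    "percent_reduction",
    "percent_increase",
    "cost_per_qaly",
    "efficient_frontier",
    "threshold_search",
]

_STAGES = ("I", "II", "III", "IV")

#: order of the cost items in a basis vector
COST_ITEMS = (
    ["fit", "cce", "colonoscopy", "polypectomy", "perforation", "cce_review"]
    + [f"initial_{s}" for s in _STAGES]
    + ["ongoing"]
    + [f"terminal_crc_{s}" for s in _STAGES]
    + [f"terminal_other_{s}" for s in _STAGES]
)


@dataclass
class CostSchedule:
    """Unit and phase-of-care costs, EUR at 2018 price level."""

    unit: Dict[str, float]
    initial: np.ndarray  # by stage I-IV
    ongoing_per_year: float
    terminal_crc_death: np.ndarray
    terminal_other_death: np.ndarray
    cce_review: float = 0.0

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, float)
        self.terminal_crc_death = np.asarray(self.terminal_crc_death, float)
        self.terminal_other_death = np.asarray(self.terminal_other_death, float)
        vals = np.concatenate(
            [
                list(self.unit.values()),
                self.initial,
                [self.ongoing_per_year, self.cce_review],
                self.terminal_crc_death,
                self.terminal_other_death,
            ]
        )
        if np.any(vals < 0):
            raise ValueError("costs must be non-negative")

    def item_values(self) -> np.ndarray:
        return np.array(
            [
                self.unit["fit"],
                self.unit["cce"],
                self.unit["colonoscopy"],
                self.unit["polypectomy"],
                self.unit["perforation"],
                self.cce_review,
                *self.initial,
                self.ongoing_per_year,
                *self.terminal_crc_death,
                *self.terminal_other_death,
            ]
        )

    @classmethod
    def from_item_values(cls, values: Sequence[float]) -> "CostSchedule":
        v = np.asarray(values, float)
        return cls(
            unit={
                "fit": v[0], "cce": v[1], "colonoscopy": v[2],
                "polypectomy": v[3], "perforation": v[4],
            },
            cce_review=float(v[5]),
            initial=v[6:10],
            ongoing_per_year=float(v[10]),
            terminal_crc_death=v[11:15],
            terminal_other_death=v[15:19],
        )


@dataclass
class UtilitySchedule:
    """Per-event and per-phase annual QALY decrements."""

    events: Dict[str, float]
    initial: np.ndarray
    ongoing: np.ndarray
    terminal_crc_death: np.ndarray
    terminal_other_death: np.ndarray

    def __post_init__(self) -> None:
        self.initial = np.asarray(self.initial, float)
        self.ongoing = np.asarray(self.ongoing, float)
        self.terminal_crc_death = np.asarray(self.terminal_crc_death, float)
        self.terminal_other_death = np.asarray(self.terminal_other_death, float)
        vals = np.concatenate(
            [
                list(self.events.values()),
                self.initial, self.ongoing,
                self.terminal_crc_death, self.terminal_other_death,
            ]
        )
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("utility decrements must lie in [0, 1]")


def load_default_costs_utilities() -> Tuple[CostSchedule, UtilitySchedule]:
    ref = importlib.resources.files("capscreen.data") / "costs_utilities.yaml"
    data = yaml.safe_load(ref.read_text())
    c, u = data["costs"], data["utilities"]

    def by_stage(d):
        return np.array([d[s] for s in _STAGES])

    costs = CostSchedule(
        unit=dict(c["unit"]),
        cce_review=float(c.get("cce_review", 0.0)),
        initial=by_stage(c["treatment"]["initial"]),
        ongoing_per_year=float(c["treatment"]["ongoing_per_year"]),
        terminal_crc_death=by_stage(c["treatment"]["terminal_crc_death"]),
        terminal_other_death=by_stage(c["treatment"]["terminal_other_death"]),
    )
    utils = UtilitySchedule(
        events=dict(u["events"]),
        initial=by_stage(u["phases"]["initial"]),
        ongoing=by_stage(u["phases"]["ongoing"]),
        terminal_crc_death=by_stage(u["phases"]["terminal_crc_death"]),
        terminal_other_death=by_stage(u["phases"]["terminal_other_death"]),
    )
    return costs, utils


@dataclass
class CEAConfig:
    discount_rate: float = 0.03
    wtp: float = 20_000.0
    reference_age: float = 55.0
    per_capita_scale: float = 1000.0

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ValueError("discount rate must be non-negative")
        if self.wtp <= 0:
            raise ValueError("willingness-to-pay must be positive")


# ----------------------------------------------------------------------
# Discounting primitives
# ----------------------------------------------------------------------
def discounted_value(amount, event_age, reference_age, rate) -> float:
    """Present value at ``reference_age`` of ``amount`` at ``event_age``."""
    if np.any(np.asarray(event_age) < reference_age):
        raise ValueError("event age precedes the discount reference age")
    return amount / (1.0 + rate) ** (np.asarray(event_age) - reference_age)


def discount_weight(age, reference_age: float, rate: float):
    """Discount factor; ages before the reference carry weight 1."""
    a = np.asarray(age, float)
    return np.where(a > reference_age, (1.0 + rate) ** -(a - reference_age), 1.0)


def life_years_discounted(death_age, reference_age: float, rate: float):
    """Discounted years lived from birth to death.

    Years before the reference age count at full weight; later years are
    discounted continuously.  With rate 0 this equals the death age.
    """
    d = np.asarray(death_age, float)
    if rate == 0.0:
        return d.copy()
    lam = np.log1p(rate)
    tail = (1.0 - np.exp(-lam * np.maximum(d - reference_age, 0.0))) / lam
    return np.minimum(d, reference_age) + tail


# ----------------------------------------------------------------------
# Cohort-level accounting
# ----------------------------------------------------------------------
@dataclass
class CostBasis:
    """Discounted per-1000 quantities of every cost item.

    ``total_cost(costs)`` re-prices a frozen run under any cost schedule
    without re-simulating, which is what the probabilistic sensitivity and
    threshold analyses rely on.
    """

    counts: np.ndarray  # aligned with COST_ITEMS

    def total_cost(self, costs: CostSchedule) -> float:
        return float(self.counts @ costs.item_values())

    def with_item(self, item: str, count: float) -> "CostBasis":
        c = self.counts.copy()
        c[COST_ITEMS.index(item)] = count
        return CostBasis(c)


@dataclass
class StrategyOutcomes:
    """Per-1000 discounted outcomes of one strategy."""

    name: str
    life_years: float
    qalys: float
    total_cost: float
    crc_cases: float
    crc_deaths: float
    tests: Dict[str, float]
    complications: float
    basis: CostBasis
    ly_gained: Optional[float] = None
    qaly_gained: Optional[float] = None

    def __post_init__(self) -> None:
        if self.crc_deaths > self.crc_cases + 1e-9:
            raise ValueError("deaths cannot exceed cases")
        if self.total_cost < 0:
            raise ValueError("cost must be non-negative")

    @property
    def cost_per_qaly(self) -> float:
        return cost_per_qaly(self.total_cost, self.qalys)

    def set_baseline(self, baseline: "StrategyOutcomes") -> None:
        self.ly_gained = self.life_years - baseline.life_years
        self.qaly_gained = self.qalys - baseline.qalys


def _phase_accumulate(
    dx_age: np.ndarray,
    death_age: np.ndarray,
    stage: np.ndarray,
    crc_death: np.ndarray,
    utilities: UtilitySchedule,
    config: CEAConfig,
):
    """Walk the care years of each diagnosed person.

    Returns per-item basis contributions (initial / ongoing / terminal
    counts, discounted) and the summed discounted phase QALY decrement.
    """
    n = dx_age.size
    initial = np.zeros(4)
    ongoing = 0.0
    terminal_crc = np.zeros(4)
    terminal_other = np.zeros(4)
    qaly_loss = 0.0
    if n == 0:
        return initial, ongoing, terminal_crc, terminal_other, qaly_loss

    util_term = np.where(
        crc_death[:, None],
        utilities.terminal_crc_death[None, :],
        utilities.terminal_other_death[None, :],
    )  # (n, 4)
    s_idx = stage - 1
    m = np.maximum(np.ceil(death_age - dx_age).astype(int), 1)
    for k in range(int(m.max())):
        act = m > k
        if not np.any(act):
            break
        w = discount_weight(dx_age[act] + k, config.reference_age, config.discount_rate)
        si = s_idx[act]
        is_term = (m[act] - 1) == k
        is_init = (k == 0) & ~is_term
        is_ong = ~is_term & ~is_init

        if np.any(is_init):
            np.add.at(initial, si[is_init], w[is_init])
            qaly_loss += float(np.sum(utilities.initial[si[is_init]] * w[is_init]))
        if np.any(is_ong):
            ongoing += float(np.sum(w[is_ong]))
            qaly_loss += float(np.sum(utilities.ongoing[si[is_ong]] * w[is_ong]))
        if np.any(is_term):
            dur = np.clip(death_age[act][is_term] - (dx_age[act][is_term] + k), 0.0, 1.0)
            crc_t = crc_death[act][is_term]
            np.add.at(terminal_crc, si[is_term][crc_t], w[is_term][crc_t])
            np.add.at(terminal_other, si[is_term][~crc_t], w[is_term][~crc_t])
            qaly_loss += float(
                np.sum(util_term[act][is_term, si[is_term]] * dur * w[is_term])
            )
    return initial, ongoing, terminal_crc, terminal_other, qaly_loss


def strategy_outcomes(
    run: StrategyRun,
    costs: CostSchedule,
    utilities: UtilitySchedule,
    config: CEAConfig = None,
    baseline: Optional[StrategyOutcomes] = None,
) -> StrategyOutcomes:
    """Discounted per-1000 life years, QALYs and cost basis of a run."""
    config = config or CEAConfig()
    out = run.outcomes
    ev = run.events
    scale = config.per_capita_scale / run.n
    r, ref = config.discount_rate, config.reference_age

    ly = float(life_years_discounted(out.death_age, ref, r).sum())

    w_ev = discount_weight(ev.age, ref, r)
    counts = np.zeros(len(COST_ITEMS))
    ev_qaly_loss = 0.0
    for kind, item in (("fit", "fit"), ("cce", "cce"), ("colonoscopy", "colonoscopy"),
                       ("polypectomy", "polypectomy"), ("perforation", "perforation")):
        mask = ev.mask(kind)
        counts[COST_ITEMS.index(item)] = w_ev[mask].sum()
    counts[COST_ITEMS.index("cce_review")] = counts[COST_ITEMS.index("cce")]

    m = ev.mask("fit")
    pos = ev.flag[m] == 1
    ev_qaly_loss += utilities.events["fit_positive"] * float(w_ev[m][pos].sum())
    ev_qaly_loss += utilities.events["fit_negative"] * float(w_ev[m][~pos].sum())
    m = ev.mask("cce")
    pos = ev.flag[m] == 1
    ev_qaly_loss += utilities.events["cce_finding"] * float(w_ev[m][pos].sum())
    ev_qaly_loss += utilities.events["cce_negative"] * float(w_ev[m][~pos].sum())
    ev_qaly_loss += utilities.events["colonoscopy"] * float(w_ev[ev.mask("colonoscopy")].sum())
    ev_qaly_loss += utilities.events["perforation"] * float(w_ev[ev.mask("perforation")].sum())

    dxed = out.dx_mode > 0
    initial, ongoing, term_crc, term_oth, phase_qaly_loss = _phase_accumulate(
        out.dx_age[dxed],
        out.death_age[dxed],
        out.dx_stage[dxed].astype(int),
        out.death_cause[dxed] == 1,
        utilities,
        config,
    )
    counts[COST_ITEMS.index("initial_I"):COST_ITEMS.index("initial_IV") + 1] = initial
    counts[COST_ITEMS.index("ongoing")] = ongoing
    counts[COST_ITEMS.index("terminal_crc_I"):COST_ITEMS.index("terminal_crc_IV") + 1] = term_crc
    counts[COST_ITEMS.index("terminal_other_I"):COST_ITEMS.index("terminal_other_IV") + 1] = term_oth

    counts *= scale
    basis = CostBasis(counts)
    qalys = (ly - ev_qaly_loss - phase_qaly_loss) * scale
    summary = out.summary_per_1000()
    res = StrategyOutcomes(
        name=run.strategy_name,
        life_years=ly * scale,
        qalys=qalys,
        total_cost=basis.total_cost(costs),
        crc_cases=summary["crc_cases_per_1000"],
        crc_deaths=summary["crc_deaths_per_1000"],
        tests={
            k: counts[COST_ITEMS.index(k)] for k in ("fit", "cce", "colonoscopy")
        },
        complications=counts[COST_ITEMS.index("perforation")],
        basis=basis,
    )
    if baseline is not None:
        res.set_baseline(baseline)
    return res


# ----------------------------------------------------------------------
# Single-person accounting (object API)
# ----------------------------------------------------------------------
def _person_phase(diagnosis, utilities, config):
    if diagnosis is None:
        return (np.zeros(4), 0.0, np.zeros(4), np.zeros(4), 0.0)
    return _phase_accumulate(
        np.array([diagnosis["age"]], float),
        np.array([diagnosis["death_age"]], float),
        np.array([diagnosis["stage"]], int),
        np.array([diagnosis["death_cause"] == "crc"]),
        utilities,
        config,
    )


def person_qaly(
    death_age: float,
    diagnosis: Optional[dict],
    events: Sequence[Tuple[float, str, int]],
    utilities: UtilitySchedule,
    config: CEAConfig = None,
) -> float:
    """Discounted QALYs of one person.

    ``diagnosis`` is ``None`` or a dict with keys ``age``, ``stage``,
    ``death_age``, ``death_cause`` ("crc"/"other"); ``events`` is a
    sequence of ``(age, kind, flag)`` screening events.
    """
    config = config or CEAConfig()
    q = float(life_years_discounted(death_age, config.reference_age, config.discount_rate))
    for age, kind, flag in events:
        w = float(discount_weight(age, config.reference_age, config.discount_rate))
        if kind == "fit":
            key = "fit_positive" if flag else "fit_negative"
        elif kind == "cce":
            key = "cce_finding" if flag else "cce_negative"
        elif kind in ("colonoscopy", "perforation"):
            key = kind
        else:
            continue
        q -= utilities.events[key] * w
    *_, phase_loss = _person_phase(diagnosis, utilities, config)
    return q - phase_loss


def person_cost(
    diagnosis: Optional[dict],
    events: Sequence[Tuple[float, str, int]],
    costs: CostSchedule,
    utilities: UtilitySchedule = None,
    config: CEAConfig = None,
) -> float:
    """Discounted healthcare cost of one person (tests + phases of care)."""
    config = config or CEAConfig()
    if diagnosis is not None and "stage" not in diagnosis:
        raise ValueError("diagnosis requires a stage")
    total = 0.0
    for age, kind, _flag in events:
        w = float(discount_weight(age, config.reference_age, config.discount_rate))
        if kind in ("fit", "cce", "colonoscopy", "polypectomy", "perforation"):
            total += costs.unit[kind] * w
            if kind == "cce":
                total += costs.cce_review * w
    utilities = utilities or load_default_costs_utilities()[1]
    initial, ongoing, term_crc, term_oth, _ = _person_phase(diagnosis, utilities, config)
    total += float(initial @ costs.initial)
    total += ongoing * costs.ongoing_per_year
    total += float(term_crc @ costs.terminal_crc_death)
    total += float(term_oth @ costs.terminal_other_death)
    return total


# ----------------------------------------------------------------------
# Report arithmetic
# ----------------------------------------------------------------------
def percent_reduction(baseline_per_1000: float, scenario_per_1000: float) -> float:
    """Reduction versus baseline, percent, to one decimal."""
    if baseline_per_1000 <= 0:
        raise ValueError("baseline must be positive")
    return round(100.0 * (baseline_per_1000 - scenario_per_1000) / baseline_per_1000, 1)


def percent_increase(baseline: float, scenario: float) -> float:
    """Increase versus baseline, percent, to one decimal."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return round(100.0 * (scenario - baseline) / baseline, 1)


def cost_per_qaly(total_cost: float, qalys: float) -> float:
    """Average cost per QALY, to two decimals."""
    if qalys <= 0:
        raise ValueError("QALYs must be positive")
    return round(total_cost / qalys, 2)


# ----------------------------------------------------------------------
# Frontier
# ----------------------------------------------------------------------
@dataclass
class FrontierResult:
    """Dominance classification and ICERs over a set of strategies."""

    status: Dict[str, str]  # frontier | strongly_dominated | extended_dominated
    icers: Dict[str, Optional[float]]  # vs next-less-effective frontier member
    frontier: List[str]  # ordered by increasing QALYs
    optimal: str  # at the willingness-to-pay threshold
    wtp: float


def efficient_frontier(
    table: Sequence[Tuple[str, float, float]], wtp: float = 20_000.0
) -> FrontierResult:
    """Classify strategies given ``(name, qalys, cost)`` rows.

    Strongly dominated: another strategy is at least as effective and at
    most as costly (strictly better on one axis).  Extended dominance is
    removed iteratively while building the convex hull in order of
    increasing QALYs, leaving strictly increasing ICERs.  The optimal
    strategy is the frontier member with the highest ICER not exceeding
    ``wtp`` (the cheapest member if every ICER exceeds it).
    """
    if len(table) < 2:
        raise ValueError("need at least two strategies")
    names = [t[0] for t in table]
    if len(set(names)) != len(names):
        raise ValueError("duplicate strategy names")
    q = np.array([t[1] for t in table], float)
    c = np.array([t[2] for t in table], float)

    # exact duplicates merge onto one representative (lowest name, so the
    # classification is invariant to input order)
    groups: Dict[Tuple[float, float], List[int]] = {}
    for i in range(len(names)):
        groups.setdefault((float(q[i]), float(c[i])), []).append(i)
    rep = {}
    for idxs in groups.values():
        if len(idxs) > 1:
            keep = min(idxs, key=lambda i: names[i])
            for i in idxs:
                if i != keep:
                    rep[i] = keep

    status = {}
    strong = np.zeros(len(names), bool)
    for i in range(len(names)):
        if i in rep:
            strong[i] = strong[rep[i]]
            continue
        for j in range(len(names)):
            if j == i or j in rep:
                continue
            if q[j] >= q[i] and c[j] <= c[i] and (q[j] > q[i] or c[j] < c[i]):
                strong[i] = True
                break

    cand = [i for i in range(len(names)) if not strong[i] and i not in rep]
    cand.sort(key=lambda i: (q[i], c[i]))
    # stack entries: (index, icer vs previous member)
    stack: List[Tuple[int, Optional[float]]] = []
    ext = set()
    for i in cand:
        while stack:
            top, top_icer = stack[-1]
            icer = (c[i] - c[top]) / (q[i] - q[top])
            if top_icer is not None and icer <= top_icer:
                ext.add(top)
                stack.pop()
            else:
                break
        prev_icer = None if not stack else (c[i] - c[stack[-1][0]]) / (q[i] - q[stack[-1][0]])
        stack.append((i, prev_icer))

    icers: Dict[str, Optional[float]] = {}
    frontier_names = []
    for i, icer in stack:
        status[names[i]] = "frontier"
        icers[names[i]] = None if icer is None else float(icer)
        frontier_names.append(names[i])
    for i in ext:
        status[names[i]] = "extended_dominated"
        icers[names[i]] = None
    for i in range(len(names)):
        if names[i] not in status:
            status[names[i]] = "strongly_dominated"
            icers[names[i]] = None
    for i, j in rep.items():
        status[names[i]] = status[names[j]]

    optimal = frontier_names[0]
    for name in frontier_names:
        ic = icers[name]
        if ic is None or ic <= wtp:
            optimal = name
    return FrontierResult(
        status=status, icers=icers, frontier=frontier_names, optimal=optimal, wtp=wtp
    )


# ----------------------------------------------------------------------
# Threshold search
# ----------------------------------------------------------------------
@dataclass
class ThresholdResult:
    found: bool
    threshold: Optional[float]
    bracket: Tuple[float, float]
    criterion_at_low: bool
    criterion_at_high: bool
    n_evaluations: int


def threshold_search(
    criterion: Callable[[float], bool],
    bracket: Tuple[float, float],
    tol: float = 0.5,
    monotonicity_probes: int = 3,
) -> ThresholdResult:
    """Bisect the value of a cost parameter at which ``criterion`` flips.

    ``criterion(x)`` must be monotone over the bracket (spot-checked with
    interior probes).  If the criterion is constant over the bracket the
    result reports ``found=False``.
    """
    lo, hi = bracket
    if not lo < hi:
        raise ValueError("invalid bracket")
    f_lo, f_hi = criterion(lo), criterion(hi)
    evals = 2
    if f_lo == f_hi:
        return ThresholdResult(False, None, bracket, f_lo, f_hi, evals)
    seq = [f_lo]
    for x in np.linspace(lo, hi, monotonicity_probes + 2)[1:-1]:
        seq.append(criterion(x))
        evals += 1
    seq.append(f_hi)
    flips = sum(seq[i] != seq[i + 1] for i in range(len(seq) - 1))
    if flips != 1:
        raise ValueError("criterion is not monotone over the bracket")
    a, b = lo, hi
    while b - a > tol:
        mid = 0.5 * (a + b)
        if criterion(mid) == f_lo:
            a = mid
        else:
            b = mid
        evals += 1
    return ThresholdResult(True, 0.5 * (a + b), bracket, f_lo, f_hi, evals)
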