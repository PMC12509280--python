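"""Execute a screening strategy against a simulated cohort.

The engine replays the cohort's frozen latent histories under a strategy's
invitation schedule, triage rules and surveillance pathway, producing an
event log (invitations, tests, referrals, polypectomies, complications,
diagnoses) and resolved per-person outcomes.

All stochastic screening decisions (participation, per-lesion detection,
reach, false positives, perforations) are counter-based uniforms keyed by
(seed, person, age, channel) or (lesion, age, channel), shared across
strategies: two strategies evaluated with the same seed see *identical*
randomness wherever their pathways coincide, so paired differences are
nearly noise-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import _rng
from .anatomy import DEFAULT_FIT_LATE_HORIZON
from .natural_history import Cohort, PersonOutcomes
from .screening_tests import TestProfile, load_default_profiles
from .strategies import AdherenceScenario, Strategy, invitation_ages

__all__ = ["EventLog", "StrategyRun", "run_strategy", "no_screening_run", "count_tests", "EVENT_KINDS"]

_BIG = 10**9

# actions
_ROUTINE, _REPEAT_CCE, _SURV_COLO = 0, 1, 2

# event kinds
EVENT_KINDS = (
    "invitation",
    "fit",
    "cce",
    "colonoscopy",
    "polypectomy",
    "perforation",
    "diagnosis",
)
_K = {k: i for i, k in enumerate(EVENT_KINDS)}

# screening channels (person, age)
_CH_PART = 0x51
_CH_FIT_FP = 0x52
_CH_CCE_REACH = 0x53
_CH_CCE_FP = 0x54
_CH_COLO_REACH = 0x55
_CH_PERF = 0x56
# lesion-level channels (lesion key, age)
_CH_FIT_V = 0x61
_CH_CCE_Z = 0x62
_CH_COLO_Z = 0x63


class EventLog:
    """Columnar log of screening events for a whole cohort run.

    Events are chronological per person; ``flag`` carries the
    kind-specific detail (test result 0/1, diagnosis stage 1-4).
    """

    def __init__(self, person: np.ndarray, age: np.ndarray, kind: np.ndarray, flag: np.ndarray):
        order = np.lexsort((kind, age, person))
        self.person = person[order]
        self.age = age[order]
        self.kind = kind[order]
        self.flag = flag[order]

    def __len__(self) -> int:
        return self.person.size

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "person": self.person,
                "age": self.age,
                "kind": pd.Categorical.from_codes(self.kind, EVENT_KINDS),
                "flag": self.flag,
            }
        )

    def for_person(self, i: int) -> pd.DataFrame:
        m = self.person == i
        return pd.DataFrame(
            {
                "age": self.age[m],
                "kind": pd.Categorical.from_codes(self.kind[m], EVENT_KINDS),
                "flag": self.flag[m],
            }
        )

    def mask(self, kind: str) -> np.ndarray:
        return self.kind == _K[kind]


@dataclass
class StrategyRun:
    """Event log plus resolved outcomes for one strategy on one cohort."""

    strategy_name: str
    n: int
    events: EventLog
    outcomes: PersonOutcomes
    removed: Optional[np.ndarray] = None  # per-lesion removal mask


def no_screening_run(cohort: Cohort) -> StrategyRun:
    """Counterfactual arm: nobody is invited, histories resolve untouched."""
    empty = EventLog(
        np.empty(0, np.int64), np.empty(0, float), np.empty(0, np.int8), np.empty(0, np.int8)
    )
    return StrategyRun("no_screening", cohort.n, empty, cohort.no_screening_outcomes())


# ----------------------------------------------------------------------
def _lesion_classes(cohort: Cohort, idx: np.ndarray, a: float, horizon: float) -> np.ndarray:
    """Class codes (-1 absent, 0 small .. 4 late preclinical) at age ``a``."""
    cls = np.full(idx.size, -1, np.int8)
    present = cohort.onset_age[idx] <= a
    cls[present] = 0
    cls[present & (cohort.age_medium[idx] <= a)] = 1
    cls[present & (cohort.age_large[idx] <= a)] = 2
    pre = present & (cohort.age_malignant[idx] <= a)
    late = cohort.clin_age[idx] - a <= horizon
    cls[pre & ~late] = 3
    cls[pre & late] = 4
    return cls


def run_strategy(
    cohort: Cohort,
    strategy: Strategy,
    adherence: AdherenceScenario,
    profiles: Optional[Dict[str, TestProfile]] = None,
    seed: int = 0,
    fit_late_horizon: float = DEFAULT_FIT_LATE_HORIZON,
) -> StrategyRun:
    """Replay every life history under ``strategy`` and resolve outcomes."""
    profiles = profiles or load_default_profiles()
    if strategy.primary_test not in ("FIT", "CCE", "colonoscopy"):
        raise ValueError(f"unsupported primary test {strategy.primary_test!r}")
    pol = strategy.surveillance
    n = cohort.n
    pid = cohort.person_offset + np.arange(n, dtype=np.int64)
    inv_ages = invitation_ages(strategy).astype(np.int64)

    sens15 = profiles["FIT15"].sensitivity_vector()
    sens47 = profiles["FIT47"].sensitivity_vector()
    fp15 = 1.0 - profiles["FIT15"].specificity
    fp47 = 1.0 - profiles["FIT47"].specificity
    prof_cce, prof_colo = profiles["CCE"], profiles["colonoscopy"]
    sens_cce = prof_cce.sensitivity_vector()
    sens_colo = prof_colo.sensitivity_vector()
    fp_cce = 1.0 - prof_cce.specificity
    reach_cce = prof_cce.reach_by_lesion_segment()
    reach_colo = prof_colo.reach_by_lesion_segment()
    refer_large = "large_adenoma" in pol.referral_threshold

    next_age = np.full(n, int(strategy.age_range[0]), np.int64)
    action = np.zeros(n, np.int8)
    removed = np.zeros(cohort.n_lesions, bool)
    eff_clin = cohort.clin_age.copy()
    clin_min = cohort.min_clin_age()
    screen_age = np.full(n, np.inf)
    screen_stage = np.zeros(n, np.int8)
    screen_u = np.full(n, np.nan)

    ev_p, ev_a, ev_k, ev_f = [], [], [], []

    def rec(P: np.ndarray, a, kind: str, flag=0) -> None:
        if P.size == 0:
            return
        ev_p.append(P.astype(np.int64))
        ev_a.append(np.broadcast_to(np.asarray(a, float), P.shape).copy())
        ev_k.append(np.full(P.size, _K[kind], np.int8))
        ev_f.append(np.broadcast_to(np.asarray(flag, np.int8), P.shape).copy())

    def schedule_routine(P: np.ndarray, earliest) -> None:
        if P.size == 0:
            return
        j = np.searchsorted(inv_ages, np.broadcast_to(np.asarray(earliest), P.shape), side="left")
        has = j < inv_ages.size
        next_age[P] = np.where(has, inv_ages[np.minimum(j, inv_ages.size - 1)], _BIG)
        action[P] = _ROUTINE

    def schedule_followup(P: np.ndarray, a: int, interval: float, act: int) -> None:
        # surveillance may cross the upper age bound once
        if P.size == 0:
            return
        t = a + int(interval)
        if t <= strategy.age_range[1] or a <= strategy.age_range[1]:
            next_age[P] = t
            action[P] = act
        else:
            next_age[P] = _BIG

    def do_colonoscopy(P: np.ndarray, a: int) -> None:
        if P.size == 0:
            return
        rec(P, a, "colonoscopy")
        perf = _rng.uniform(seed, _CH_PERF, pid[P], a) < prof_colo.perforation_risk
        rec(P[perf], a, "perforation")

        idx, owner = cohort.lesions_of(P)
        cls = _lesion_classes(cohort, idx, a, fit_late_horizon)
        present = (cls >= 0) & ~removed[idx]
        u_reach = _rng.uniform(seed, _CH_COLO_REACH, pid[P], a)
        reached = u_reach[owner] < reach_colo[cohort.segment[idx]]
        z = _rng.uniform(cohort.les_key[idx], a, _CH_COLO_Z)
        det = present & reached & (z < sens_colo[np.maximum(cls, 0)])

        det_cancer = det & (cls >= 3)
        any_cancer = np.zeros(P.size, bool)
        any_cancer[owner[det_cancer]] = True
        if np.any(det_cancer):
            stages = np.zeros(idx.size, np.int8)
            stages[det_cancer] = cohort.stage_at(idx[det_cancer], a)
            max_stage = np.zeros(P.size, np.int8)
            np.maximum.at(max_stage, owner[det_cancer], stages[det_cancer])
            # lesion realising the max stage supplies the survival uniform
            pick = det_cancer & (stages == max_stage[owner])
            chosen = np.full(P.size, -1, np.int64)
            chosen[owner[pick][::-1]] = idx[pick][::-1]
            dxp = np.flatnonzero(any_cancer)
            screen_age[P[dxp]] = a
            screen_stage[P[dxp]] = max_stage[dxp]
            screen_u[P[dxp]] = cohort.surv_u[chosen[dxp]]
            rec(P[dxp], a, "diagnosis", max_stage[dxp])
            next_age[P[dxp]] = _BIG

        det_aden = det & (cls <= 2)
        if np.any(det_aden):
            removed[idx[det_aden]] = True
            eff_clin[idx[det_aden]] = np.inf
            touched = np.unique(owner[det_aden])
            m = np.full(P.size, np.inf)
            np.minimum.at(m, owner, np.where(removed[idx], np.inf, eff_clin[idx]))
            clin_min[P[touched]] = m[touched]
        any_aden = np.zeros(P.size, bool)
        any_aden[owner[det_aden]] = True
        rec(P[any_aden], a, "polypectomy")

        med_large = np.zeros(P.size, bool)
        med_large[owner[det_aden & (cls >= 1)]] = True
        live = ~any_cancer
        schedule_followup(
            P[live & med_large], a, pol.after_medium_risk_adenoma_at_colonoscopy, _SURV_COLO
        )
        schedule_routine(P[live & ~med_large], a + pol.after_negative_endoscopy)

    def do_cce(P: np.ndarray, a: int) -> None:
        if P.size == 0:
            return
        idx, owner = cohort.lesions_of(P)
        cls = _lesion_classes(cohort, idx, a, fit_late_horizon)
        present = (cls >= 0) & ~removed[idx]
        u_reach = _rng.uniform(seed, _CH_CCE_REACH, pid[P], a)
        reached = u_reach[owner] < reach_cce[cohort.segment[idx]]
        z = _rng.uniform(cohort.les_key[idx], a, _CH_CCE_Z)
        det = present & reached & (z < sens_cce[np.maximum(cls, 0)])

        any_det = np.zeros(P.size, bool)
        any_det[owner[det]] = True
        refer = np.zeros(P.size, bool)
        thresh = 3 if not refer_large else 2
        refer[owner[det & (cls >= thresh)]] = True
        med = np.zeros(P.size, bool)
        med[owner[det & (cls == 1)]] = True
        fp = ~any_det & (_rng.uniform(seed, _CH_CCE_FP, pid[P], a) < fp_cce)
        positive = any_det | fp
        rec(P, a, "cce", positive.astype(np.int8))

        refer |= fp  # a suspected finding is always verified by colonoscopy
        do_colonoscopy(P[refer], a)
        med_only = med & ~refer
        schedule_followup(P[med_only], a, pol.after_medium_risk_adenoma_at_cce, _REPEAT_CCE)
        neg = ~positive
        if strategy.primary_test == "CCE":
            schedule_routine(P[neg], a + pol.after_negative_endoscopy)
        else:
            schedule_routine(P[neg], a + 1)

    def do_fit(P: np.ndarray, a: int) -> None:
        idx, owner = cohort.lesions_of(P)
        cls = _lesion_classes(cohort, idx, a, fit_late_horizon)
        present = (cls >= 0) & ~removed[idx]
        v = _rng.uniform(cohort.les_key[idx], a, _CH_FIT_V)
        ge15 = np.zeros(P.size, bool)
        ge47 = np.zeros(P.size, bool)
        trig15 = present & (v < sens15[np.maximum(cls, 0)])
        trig47 = present & (v < sens47[np.maximum(cls, 0)])
        ge15[owner[trig15]] = True
        ge47[owner[trig47]] = True
        # background bleeding drives positivity only for persons without a
        # FIT-detectable lesion (small adenomas are invisible to the test)
        detectable = np.zeros(P.size, bool)
        detectable[owner[present & (sens15[np.maximum(cls, 0)] > 0)]] = True
        w = _rng.uniform(seed, _CH_FIT_FP, pid[P], a)
        ge15 |= ~detectable & (w < fp15)
        ge47 |= ~detectable & (w < fp47)
        band = ge15 & ~ge47

        rule = strategy.triage_rule
        if rule == "none":
            pos = ge47 if strategy.fit_cutoff == 47 else ge15
            rec(P, a, "fit", pos.astype(np.int8))
            do_colonoscopy(P[pos], a)
            schedule_routine(P[~pos], a + 1)
        elif rule == "cce_if_band_15_47":
            rec(P, a, "fit", ge15.astype(np.int8))
            do_colonoscopy(P[ge47], a)
            do_cce(P[band], a)
            schedule_routine(P[~ge15], a + 1)
        elif rule in ("cce_if_fit15_positive", "cce_if_fit47_positive"):
            pos = ge15 if rule == "cce_if_fit15_positive" else ge47
            rec(P, a, "fit", pos.astype(np.int8))
            do_cce(P[pos], a)
            schedule_routine(P[~pos], a + 1)

    # ------------------------------------------------------------------
    part_rate = adherence.rate_for(strategy.primary_test)
    for a in range(int(strategy.age_range[0]), int(cohort.params.max_age)):
        due = np.flatnonzero(next_age == a)
        if due.size == 0:
            continue
        dead = cohort.other_death_age[due] <= a
        next_age[due[dead]] = _BIG
        due = due[~dead]
        clin = clin_min[due] <= a
        next_age[due[clin]] = _BIG  # surfaced clinically before this contact
        due = due[~clin]
        if due.size == 0:
            continue

        act_due = action[due].copy()  # handlers reschedule via `action`
        surv = due[act_due == _SURV_COLO]
        do_colonoscopy(surv, a)
        rep = due[act_due == _REPEAT_CCE]
        do_cce(rep, a)

        routine = due[act_due == _ROUTINE]
        if routine.size:
            rec(routine, a, "invitation")
            att = _rng.uniform(seed, _CH_PART, pid[routine], a) < part_rate
            schedule_routine(routine[~att], a + 1)
            goers = routine[att]
            if strategy.primary_test == "FIT":
                do_fit(goers, a)
            elif strategy.primary_test == "CCE":
                do_cce(goers, a)
            else:
                do_colonoscopy(goers, a)

    outcomes = cohort.outcomes_given(
        removed=removed,
        screen_dx_age=screen_age,
        screen_dx_stage=screen_stage,
        screen_dx_u=screen_u,
    )
    # clinical diagnoses as events, for completeness of the log
    clin_p = np.flatnonzero(outcomes.dx_mode == 1)
    if ev_p or clin_p.size:
        ev_p.append(clin_p)
        ev_a.append(outcomes.dx_age[clin_p])
        ev_k.append(np.full(clin_p.size, _K["diagnosis"], np.int8))
        ev_f.append(outcomes.dx_stage[clin_p])
    log = EventLog(
        np.concatenate(ev_p) if ev_p else np.empty(0, np.int64),
        np.concatenate(ev_a) if ev_a else np.empty(0, float),
        np.concatenate(ev_k) if ev_k else np.empty(0, np.int8),
        np.concatenate(ev_f) if ev_f else np.empty(0, np.int8),
    )
    return StrategyRun(strategy.name, n, log, outcomes, removed)


# ----------------------------------------------------------------------
def count_tests(
    run: StrategyRun, discount_rate: float = 0.03, reference_age: float = 55.0
) -> dict:
    """Discounted and raw per-1000 counts of tests and complications.

    Each event contributes ``1 / (1 + r)^(age - reference)``; events before
    the reference age are not discounted.
    """
    if discount_rate < 0:
        raise ValueError("discount rate must be non-negative")
    ev = run.events
    w = np.where(
        ev.age > reference_age,
        (1.0 + discount_rate) ** -(ev.age - reference_age),
        1.0,
    )
    out = {}
    scale = 1000.0 / run.n
    for kind in ("fit", "cce", "colonoscopy", "perforation", "polypectomy"):
        m = ev.mask(kind)
        out[f"{kind}_per_1000"] = float(w[m].sum() * scale)
        out[f"{kind}_per_1000_raw"] = float(m.sum() * scale)
    return out
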