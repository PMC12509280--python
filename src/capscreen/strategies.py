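"""Screening strategies, invitation schedules, surveillance and adherence.

Eight strategies are evaluated against the same cohort: biennial stool
testing at two haemoglobin cutoffs (15 and 47 ug Hb/g), biennial and
triennial capsule endoscopy as the primary test, capsule triage of the
15-47 ug Hb/g band, capsule follow-up of positive stool tests at either
cutoff, and 10-yearly primary colonoscopy.  All invite from age 55 to 75.

Surveillance pathway: a negative endoscopic examination (capsule or
colonoscopy) defers the next contact by 10 years; a medium-risk adenoma
found at capsule endoscopy triggers a repeat capsule after 3 years; a
medium- or large-adenoma polypectomy at colonoscopy triggers a
surveillance colonoscopy after 5 years.  In the *biennial* capsule
strategy both capsule intervals collapse to the 2-year screening round.
Diagnostic follow-up and surveillance are always fully attended;
participation applies to primary invitations only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Tuple

import numpy as np

__all__ = [
    "SurveillancePolicy",
    "AdherenceScenario",
    "Strategy",
    "build_canonical_strategies",
    "invitation_ages",
    "ADHERENCE_SCENARIOS",
    "STRATEGY_NAMES",
]

TRIAGE_RULES = (
    "none",
    "cce_if_band_15_47",
    "cce_if_fit15_positive",
    "cce_if_fit47_positive",
)


@dataclass(frozen=True)
class SurveillancePolicy:
    after_negative_endoscopy: float = 10.0
    after_medium_risk_adenoma_at_colonoscopy: float = 5.0
    after_medium_risk_adenoma_at_cce: float = 3.0
    #: lesion classes at capsule endoscopy that trigger colonoscopy referral
    referral_threshold: Tuple[str, ...] = ("large_adenoma", "crc_preclinical")

    def __post_init__(self) -> None:
        for v in (
            self.after_negative_endoscopy,
            self.after_medium_risk_adenoma_at_colonoscopy,
            self.after_medium_risk_adenoma_at_cce,
        ):
            if v <= 0:
                raise ValueError("surveillance intervals must be positive")


@dataclass(frozen=True)
class AdherenceScenario:
    name: str
    fit: float
    cce: float
    colonoscopy: float
    diagnostic_and_surveillance: float = 1.0

    def __post_init__(self) -> None:
        for v in (self.fit, self.cce, self.colonoscopy):
            if not 0.0 <= v <= 1.0:
                raise ValueError("participation probabilities must lie in [0, 1]")
        if self.diagnostic_and_surveillance != 1.0:
            raise ValueError("diagnostic and surveillance adherence is fixed at 1.0")

    def rate_for(self, modality: str) -> float:
        return {"FIT": self.fit, "CCE": self.cce, "colonoscopy": self.colonoscopy}[
            modality
        ]


#: the three participation scenarios evaluated
ADHERENCE_SCENARIOS = {
    "full": AdherenceScenario("full", fit=1.0, cce=1.0, colonoscopy=1.0),
    "invasiveness": AdherenceScenario("invasiveness", fit=0.75, cce=0.25, colonoscopy=0.25),
    "intermediate": AdherenceScenario("intermediate", fit=0.75, cce=0.50, colonoscopy=0.25),
}


@dataclass(frozen=True)
class Strategy:
    name: str
    primary_test: str  # "FIT" | "CCE" | "colonoscopy"
    interval: float
    fit_cutoff: int = 0  # 15 or 47 when the primary test is FIT
    age_range: Tuple[float, float] = (55.0, 75.0)
    triage_rule: str = "none"
    surveillance: SurveillancePolicy = field(default_factory=SurveillancePolicy)

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValueError("screening interval must be positive")
        if not (0 <= self.age_range[0] <= self.age_range[1] <= 100):
            raise ValueError("age range must lie within [0, 100]")
        if self.triage_rule not in TRIAGE_RULES:
            raise ValueError(f"unknown triage rule {self.triage_rule!r}")
        if self.primary_test not in ("FIT", "CCE", "colonoscopy"):
            raise ValueError(f"unknown primary test {self.primary_test!r}")

    def with_policy(self, **changes) -> "Strategy":
        return replace(self, surveillance=replace(self.surveillance, **changes))


def build_canonical_strategies(
    policy: SurveillancePolicy = None,
) -> List[Strategy]:
    """The eight evaluated strategies, in their conventional order."""
    pol = policy or SurveillancePolicy()
    biennial_cce_pol = replace(
        pol, after_negative_endoscopy=2.0, after_medium_risk_adenoma_at_cce=2.0
    )
    return [
        Strategy("biennial_fit47", "FIT", 2, fit_cutoff=47, surveillance=pol),
        Strategy("biennial_fit15", "FIT", 2, fit_cutoff=15, surveillance=pol),
        Strategy("biennial_cce", "CCE", 2, surveillance=biennial_cce_pol),
        Strategy("triennial_cce", "CCE", 3, surveillance=pol),
        Strategy(
            "cce_triage", "FIT", 2, fit_cutoff=47,
            triage_rule="cce_if_band_15_47", surveillance=pol,
        ),
        Strategy(
            "cce_after_fit15", "FIT", 2, fit_cutoff=15,
            triage_rule="cce_if_fit15_positive", surveillance=pol,
        ),
        Strategy(
            "cce_after_fit47", "FIT", 2, fit_cutoff=47,
            triage_rule="cce_if_fit47_positive", surveillance=pol,
        ),
        Strategy("colonoscopy_10y", "colonoscopy", 10, surveillance=pol),
    ]


STRATEGY_NAMES = [s.name for s in build_canonical_strategies()]


def invitation_ages(strategy: Strategy) -> np.ndarray:
    """Arithmetic invitation schedule: start, start + interval, ... <= end."""
    lo, hi = strategy.age_range
    return np.arange(lo, hi + 1e-9, strategy.interval)
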