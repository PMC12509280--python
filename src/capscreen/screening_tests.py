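"""Screening-test characteristics and their application to a disease snapshot.

A :class:`TestProfile` bundles per-lesion-class sensitivity, specificity,
reach along the colon, per-procedure complication risk and a unit cost.
``apply_test`` evaluates a modality against one person's current lesions;
``fit_dual_cutoff`` evaluates the stool test at both haemoglobin cutoffs
with a single nested latent draw, which is what the triage pathway needs
(a FIT result in the 15-47 ug Hb/g band is "negative at 47 but positive at
15").

Reach is sampled with one uniform per procedure: the instrument visualises
a *prefix* of its travel order, so a segment is reached exactly when the
uniform falls below that segment's (monotone non-increasing) reach
probability.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .anatomy import (
    CCE_TRAVEL_ORDER,
    CLASSES,
    CLASS_INDEX,
    COLONOSCOPY_TRAVEL_ORDER,
    LESION_SEGMENTS,
    LESION_TO_REACH_LOCATION,
)

__all__ = [
    "TestProfile",
    "TestOutcome",
    "load_default_profiles",
    "interpolate_reach",
    "apply_test",
    "fit_dual_cutoff",
]


@dataclass
class TestProfile:
    name: str
    sensitivity: Dict[str, float]
    specificity: float
    reach_anchors: Dict[str, float]
    perforation_risk: float = 0.0
    unit_cost: float = 0.0

    def __post_init__(self) -> None:
        probs = list(self.sensitivity.values()) + list(self.reach_anchors.values())
        probs += [self.specificity, self.perforation_risk]
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError(f"{self.name}: probabilities must lie in [0, 1]")
        missing = set(CLASSES) - set(self.sensitivity)
        if missing:
            raise ValueError(f"{self.name}: missing sensitivities for {sorted(missing)}")

    @property
    def travel_order(self) -> Tuple[str, ...]:
        return CCE_TRAVEL_ORDER if self.name == "CCE" else COLONOSCOPY_TRAVEL_ORDER

    def sensitivity_vector(self) -> np.ndarray:
        return np.array([self.sensitivity[c] for c in CLASSES])

    def reach_by_lesion_segment(self) -> np.ndarray:
        """Reach probability per lesion segment (1.0 for whole-stool tests)."""
        if not self.reach_anchors:
            return np.ones(len(LESION_SEGMENTS))
        full = interpolate_reach(self, self.travel_order)
        return np.array(
            [full[LESION_TO_REACH_LOCATION[s]] for s in LESION_SEGMENTS]
        )


@dataclass
class TestOutcome:
    result: str  # "negative" | "positive"
    detected_lesions: List[int]
    false_positive: bool
    segments_reached: set
    complication: str = "none"  # "none" | "perforation"
    fit_band: Optional[str] = None  # below_15 | band_15_47 | at_or_above_47


def load_default_profiles() -> Dict[str, TestProfile]:
    """Shipped modality characteristics (stool test at both cutoffs,
    capsule, colonoscopy)."""
    ref = importlib.resources.files("capscreen.data") / "test_profiles.yaml"
    data = yaml.safe_load(ref.read_text())
    return {
        name: TestProfile(name=name, **spec) for name, spec in data["profiles"].items()
    }


# ----------------------------------------------------------------------
def interpolate_reach(
    profile: TestProfile, travel_order: Sequence[str]
) -> Dict[str, float]:
    """Reach probability for every location along ``travel_order``.

    Anchored locations keep their values; the rest are linearly
    interpolated by ordinal position between the nearest anchors.  The ends
    of the travel order clamp to the nearest anchor value.
    """
    anchors = {
        loc: p for loc, p in profile.reach_anchors.items() if loc in travel_order
    }
    if len(anchors) < 2:
        raise ValueError("reach interpolation needs at least 2 anchored locations")
    pos = np.array([travel_order.index(loc) for loc in anchors])
    vals = np.array([anchors[loc] for loc in anchors])
    order = np.argsort(pos)
    xi = np.arange(len(travel_order))
    yi = np.interp(xi, pos[order], vals[order])
    return dict(zip(travel_order, yi.tolist()))


# ----------------------------------------------------------------------
def _classify(snapshot: Iterable) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    ids, cls_idx, seg_idx = [], [], []
    for lesion_id, cls, segment in snapshot:
        if cls not in CLASS_INDEX:
            raise ValueError(f"unknown lesion class {cls!r}")
        if segment not in LESION_SEGMENTS:
            raise ValueError(f"unknown segment {segment!r}")
        ids.append(lesion_id)
        cls_idx.append(CLASS_INDEX[cls])
        seg_idx.append(LESION_SEGMENTS.index(segment))
    return np.array(ids, dtype=object), np.array(cls_idx, int), np.array(seg_idx, int)


def apply_test_batch(
    profile: TestProfile,
    snapshot: Sequence[Tuple[object, str, str]],
    n: int,
    rng: np.random.Generator,
) -> dict:
    """``n`` independent applications of a modality to the same snapshot.

    Returns arrays: ``detected`` (n, lesions), ``reached`` (n, segments),
    ``positive``, ``false_positive`` and ``perforation`` (n,).  Lesions in
    reached segments are detected independently with the class
    sensitivity; whole-stool tests ignore reach; if nothing is detected
    the test is positive with probability ``1 - specificity``; one
    perforation draw per procedure.
    """
    ids, cls_idx, seg_idx = _classify(snapshot)
    sens = profile.sensitivity_vector()
    reach_seg = profile.reach_by_lesion_segment()

    if profile.reach_anchors:
        u_reach = rng.uniform(size=(n, 1))
        reached = u_reach < reach_seg[None, :]  # prefix of the travel order
    else:
        reached = np.ones((n, len(LESION_SEGMENTS)), bool)

    if ids.size:
        z = rng.uniform(size=(n, ids.size))
        detected = reached[:, seg_idx] & (z < sens[cls_idx][None, :])
    else:
        detected = np.zeros((n, 0), bool)

    any_det = detected.any(axis=1)
    false_positive = ~any_det & (rng.uniform(size=n) < 1.0 - profile.specificity)
    positive = any_det | false_positive
    perforation = rng.uniform(size=n) < profile.perforation_risk
    return {
        "ids": ids,
        "detected": detected,
        "reached": reached,
        "positive": positive,
        "false_positive": false_positive,
        "perforation": perforation,
    }


def apply_test(
    profile: TestProfile,
    snapshot: Sequence[Tuple[object, str, str]],
    rng: np.random.Generator,
) -> TestOutcome:
    """Apply a modality once; see :func:`apply_test_batch` for the model."""
    b = apply_test_batch(profile, snapshot, 1, rng)
    segments_reached = {
        LESION_SEGMENTS[i]
        for i in range(len(LESION_SEGMENTS))
        if b["reached"][0, i]
    }
    detected = list(b["ids"][b["detected"][0]])
    return TestOutcome(
        result="positive" if b["positive"][0] else "negative",
        detected_lesions=detected,
        false_positive=bool(b["false_positive"][0]),
        segments_reached=segments_reached,
        complication="perforation" if b["perforation"][0] else "none",
    )


def fit_dual_cutoff(
    snapshot: Sequence[Tuple[object, str, str]],
    rng: np.random.Generator,
    profiles: Optional[Dict[str, TestProfile]] = None,
) -> str:
    """Evaluate the stool test at both cutoffs with one nested latent draw.

    Per lesion, a single uniform is compared against the 15- and 47-cutoff
    sensitivities, so a result at or above 47 always implies a result at
    or above 15 (the 47-cutoff sensitivities are nested below the
    15-cutoff ones).  Background (non-neoplastic) bleeding drives the
    result only when no FIT-detectable lesion is present: one person-level
    uniform against the two false-positive rates, nested the same way.
    Returns the haemoglobin band: ``below_15``, ``band_15_47`` or
    ``at_or_above_47``.
    """
    profiles = profiles or load_default_profiles()
    p15, p47 = profiles["FIT15"], profiles["FIT47"]
    ids, cls_idx, _ = _classify(snapshot)
    s15 = p15.sensitivity_vector()[cls_idx] if ids.size else np.empty(0)
    s47 = p47.sensitivity_vector()[cls_idx] if ids.size else np.empty(0)
    v = rng.uniform(size=ids.size)
    w = rng.uniform()
    if np.any(s15 > 0):
        ge15 = bool(np.any(v < s15))
        ge47 = bool(np.any(v < s47))
    else:
        ge15 = w < 1.0 - p15.specificity
        ge47 = w < 1.0 - p47.specificity
    if ge47:
        return "at_or_above_47"
    if ge15:
        return "band_15_47"
    return "below_15"
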