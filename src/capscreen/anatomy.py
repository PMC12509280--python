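"""Colorectal anatomy and lesion-class vocabulary shared across modules."""

from __future__ import annotations

# Lesion locations used by the natural-history model.  The ascending colon
# and cecum are pooled for lesion placement; test reach is interpolated on
# the finer 7-location travel orders below.
LESION_SEGMENTS = (
    "rectum",
    "rectosigmoid",
    "sigmoid",
    "descending",
    "transverse",
    "ascending_cecum",
)

#: capsule travels with peristalsis, cecum first
CCE_TRAVEL_ORDER = (
    "cecum",
    "ascending",
    "transverse",
    "descending",
    "sigmoid",
    "rectosigmoid",
    "rectum",
)

#: colonoscope is introduced per rectum
COLONOSCOPY_TRAVEL_ORDER = tuple(reversed(CCE_TRAVEL_ORDER))

#: map a lesion segment to the reach location used for visualisation
LESION_TO_REACH_LOCATION = {
    "rectum": "rectum",
    "rectosigmoid": "rectosigmoid",
    "sigmoid": "sigmoid",
    "descending": "descending",
    "transverse": "transverse",
    "ascending_cecum": "ascending",
}

# Detectable lesion classes, in progression order.  Preclinical cancer is
# split into "early" and "late" only for stool-based testing: the chance a
# cancer bleeds (and so the FIT sensitivity) rises as clinical diagnosis
# approaches.
CLASSES = (
    "small_adenoma",
    "medium_adenoma",
    "large_adenoma",
    "crc_early_preclinical",
    "crc_late_preclinical",
)

CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}

#: years-to-clinical-diagnosis threshold separating early from late
#: preclinical cancer for FIT sensitivity
DEFAULT_FIT_LATE_HORIZON = 5.0
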