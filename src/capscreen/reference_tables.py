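"""Published base-case results for the Dutch screening setting.

These are the reported lifetime outcomes (discounted at 3%, per 1000
individuals, 100% adherence) of the published microsimulation evaluation
of colon capsule endoscopy in the Dutch colorectal cancer screening
programme — the evaluation this package re-implements.  They serve as
*inputs* to the decision arithmetic (reductions, cost per QALY, efficient
frontier) and as reference points in the tests; they are not produced by
this package's simulator, whose calibrated parameter set is its own.
"""

from __future__ import annotations

#: lifetime CRC cases and deaths per 1000, no screening
NO_SCREENING_CASES_PER_1000 = 79.0
NO_SCREENING_DEATHS_PER_1000 = 36.0

#: per-1000 lifetime CRC cases and deaths at 100% adherence
CASES_DEATHS_FULL_ADHERENCE = {
    "biennial_fit47": (53.0, 21.0),
    "biennial_fit15": (46.0, 18.0),
    "biennial_cce": (49.0, 17.0),
    "colonoscopy_10y": (29.0, 11.0),
}

#: (qalys, total cost EUR, life years, life years gained, qalys gained)
#: per 1000, discounted at 3%, 100% adherence
TABLE_FULL_ADHERENCE = {
    "no_screening": (73_631.0, 1_200_737.0, 73_722.0, 0.0, 0.0),
    "biennial_fit47": (73_770.0, 1_144_410.0, 73_836.0, 115.0, 139.0),
    "biennial_fit15": (73_801.0, 1_154_074.0, 73_861.0, 140.0, 171.0),
    "cce_triage": (73_774.0, 1_206_442.0, 73_839.0, 118.0, 143.0),
    "cce_after_fit47": (73_730.0, 1_258_541.0, 73_804.0, 83.0, 99.0),
    "cce_after_fit15": (73_745.0, 1_294_641.0, 73_816.0, 95.0, 114.0),
    "triennial_cce": (73_748.0, 1_700_084.0, 73_818.0, 97.0, 118.0),
    "colonoscopy_10y": (73_855.0, 1_705_087.0, 73_908.0, 187.0, 224.0),
    "biennial_cce": (73_817.0, 3_178_861.0, 73_876.0, 155.0, 186.0),
}


def frontier_input_full_adherence():
    """(name, qalys, cost) rows for the 100%-adherence frontier analysis."""
    return [(name, v[0], v[1]) for name, v in TABLE_FULL_ADHERENCE.items()]
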