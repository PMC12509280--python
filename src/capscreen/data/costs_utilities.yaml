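# Unit costs (EUR, 2018 price level) and QALY decrements for screening
# events and colorectal cancer care.  Treatment costs follow three phases:
# the initial year after diagnosis, ongoing years in between, and the
# terminal (last) year of life, which differs by cause of death.
version: 1
costs:
  unit:
    fit: 22.0
    cce: 600.0
    colonoscopy: 686.0
    polypectomy: 295.0
    perforation: 2735.0
  cce_review: 0.0          # optional add-on per capsule recording review
  treatment:
    initial: {I: 22859.0, II: 19415.0, III: 36633.0, IV: 35513.0}
    ongoing_per_year: 483.0
    terminal_crc_death: {I: 24859.0, II: 24859.0, III: 26280.0, IV: 35513.0}
    terminal_other_death: {I: 6250.0, II: 5682.0, III: 7387.0, IV: 19887.0}
utilities:
  events:
    fit_positive: 0.00133
    fit_negative: 0.000063
    cce_finding: 0.001692
    cce_negative: 0.000425
    colonoscopy: 0.0055
    perforation: 0.0384
  phases:
    initial: {I: 0.12, II: 0.18, III: 0.24, IV: 0.7}
    ongoing: {I: 0.05, II: 0.05, III: 0.24, IV: 0.7}
    terminal_crc_death: {I: 0.7, II: 0.7, III: 0.7, IV: 0.7}
    terminal_other_death: {I: 0.05, II: 0.05, III: 0.24, IV: 0.7}
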