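"""Independent discrete-time simulator of the same disease hazards.

A deliberately naive monthly-step Markov walk over the lesion states,
driven by a plain numpy Generator.  Used as a brute-force oracle for the
continuous-time cohort simulator: both should give the same lifetime
incidence and mortality up to Monte-Carlo error.
"""

from __future__ import annotations

import numpy as np

DT = 1.0 / 12.0  # one month


def _p(rate: float) -> float:
    return 1.0 - np.exp(-rate * DT)


def simulate_discrete(params, life_table, n: int, seed: int) -> dict:
    """Monthly-step simulation; returns cases and deaths per 1000."""
    rng = np.random.default_rng(seed)
    max_age = params.max_age

    # pre-draw other-cause death ages via the life table
    death_other = np.minimum(
        life_table.sample_death_age(rng.uniform(size=n), rng.uniform(size=n)), max_age
    )

    cases = 0
    deaths = 0
    p_onset = [_p(r) for r in params.onset_bands]
    p_sm = _p(params.rate_small_to_medium)
    p_ml = _p(params.rate_medium_to_large)
    p_mal = _p(params.rate_large_to_malignant)
    p_prog = [_p(r) for r in params.stage_progression] + [0.0]
    p_det = [_p(r) for r in params.stage_detection]
    p_die = [_p(1.0 / m) for m in params.stage_survival_mean]

    n_steps = int(round(max_age / DT))
    for i in range(n):
        lesions = []  # state codes: 0 small, 1 medium, 2 large, 3..6 stages I-IV
        dx_stage = -1
        dx_time = np.inf
        t_death_other = death_other[i]
        death_time = t_death_other
        cause = 0
        for step in range(n_steps):
            t = step * DT
            if t >= death_time:
                break
            if dx_stage < 0:
                band = min(int(t // 10), 9)
                if rng.uniform() < p_onset[band]:
                    lesions.append(0)
                for j, st in enumerate(lesions):
                    if st == 0 and rng.uniform() < p_sm:
                        lesions[j] = 1
                    elif st == 1 and rng.uniform() < p_ml:
                        lesions[j] = 2
                    elif st == 2 and rng.uniform() < p_mal:
                        lesions[j] = 3
                    elif st >= 3:
                        stage = st - 3
                        if rng.uniform() < p_det[stage]:
                            dx_stage = stage
                            dx_time = t
                            break
                        if stage < 3 and rng.uniform() < p_prog[stage]:
                            lesions[j] = st + 1
            else:
                if rng.uniform() < p_die[dx_stage]:
                    death_time = t
                    cause = 1
                    break
        if dx_time < death_time or (dx_stage >= 0 and cause == 1):
            cases += 1
        if cause == 1:
            deaths += 1
    return {
        "crc_cases_per_1000": 1000.0 * cases / n,
        "crc_deaths_per_1000": 1000.0 * deaths / n,
    }
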