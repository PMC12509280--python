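"""Counter-based uniform random numbers keyed by integers.

The microsimulation needs random draws that are addressable: the draw used
for "does person i attend the invitation at age a" must be the same number
regardless of which strategy is being evaluated, how the cohort is chunked
across workers, or in which order rounds are processed.  That gives

* common random numbers across strategies (paired comparisons difference
  out Monte-Carlo noise), and
* results that are invariant to worker partitioning for a fixed seed.

A keyed hash (splitmix64 finaliser applied to a running combination of the
key parts) mapped to the unit interval provides exactly this.  Statistical
quality of splitmix64 as a bit mixer is well established; all structured
distributions (gamma draws for the probabilistic sensitivity analysis etc.)
still come from numpy generators.
"""

from __future__ import annotations

import numpy as np

__all__ = ["hash_u64", "uniform", "exponential"]

_C1 = np.uint64(0x9E3779B97F4A7C15)
_C2 = np.uint64(0xBF58476D1CE4E5B9)
_C3 = np.uint64(0x94D049BB133111EB)
_PRIME = np.uint64(0xD6E8FEB86659FD93)

_INV_2_53 = float(2.0**-53)


def _mix(z):
    """splitmix64 finaliser (vectorised over uint64 arrays)."""
    z = (z ^ (z >> np.uint64(30))) * _C2
    z = (z ^ (z >> np.uint64(27))) * _C3
    return z ^ (z >> np.uint64(31))


def hash_u64(*parts) -> np.ndarray:
    """Combine integer key parts (scalars or broadcastable arrays) to uint64."""
    with np.errstate(over="ignore"):
        acc = _C1
        for p in parts:
            a = np.asarray(p)
            if a.dtype.kind != "u":
                a = a.astype(np.int64).astype(np.uint64)
            acc = _mix((acc + _C1) * _PRIME ^ a)
        return acc


def uniform(*parts) -> np.ndarray:
    """Deterministic uniform(0, 1) draw keyed by the given integer parts.

    Values lie in the open interval (0, 1) so logs are always finite.
    """
    u = (hash_u64(*parts) >> np.uint64(11)).astype(np.float64) * _INV_2_53
    return np.clip(u, _INV_2_53, 1.0 - _INV_2_53)


def exponential(rate, *parts) -> np.ndarray:
    """Keyed exponential draw; ``rate`` 0 maps to +inf (event never occurs)."""
    u = uniform(*parts)
    with np.errstate(divide="ignore"):
        return -np.log(u) / rate
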