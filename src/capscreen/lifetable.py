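"""Other-cause mortality via a period/cohort life table.

The screening cohort dies of causes other than colorectal cancer according
to a table of one-year death probabilities ``qx``.  A synthetic
Gompertz-Makeham table approximating the mortality of a mid-20th-century
Dutch birth cohort ships as the default; any table can be supplied as YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from . import _rng

__all__ = ["LifeTable"]


@dataclass
class LifeTable:
    """One-year conditional death probabilities by age.

    Parameters
    ----------
    qx : array of shape (max_age + 1,)
        ``qx[a]`` is the probability of dying between exact ages ``a`` and
        ``a + 1`` given survival to ``a``.  Death is forced at ``max_age``.
    """

    qx: np.ndarray
    max_age: int = 100
    _surv: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.qx = np.asarray(self.qx, dtype=float)
        if self.qx.shape != (self.max_age + 1,):
            raise ValueError(
                f"qx must have length max_age + 1 = {self.max_age + 1}"
            )
        if np.any((self.qx < 0) | (self.qx > 1)):
            raise ValueError("qx entries must lie in [0, 1]")
        qx = self.qx.copy()
        qx[-1] = 1.0  # death certain in the final year
        self.qx = qx
        # survival to exact age a, S[0] = 1, length max_age + 2
        self._surv = np.concatenate([[1.0], np.cumprod(1.0 - qx)])

    # ------------------------------------------------------------------
    @classmethod
    def gompertz_makeham(
        cls,
        makeham: float = 4.0e-4,
        gompertz_b: float = 2.7e-5,
        gompertz_c: float = 1.098,
        max_age: int = 100,
    ) -> "LifeTable":
        """Synthetic table with hazard ``mu(x) = A + B * c**x``.

        Defaults give a life expectancy at birth of roughly 76 years,
        in the range of the 1938-1957 Dutch birth cohorts.
        """
        ages = np.arange(max_age + 1)
        mu = makeham + gompertz_b * gompertz_c**ages
        qx = 1.0 - np.exp(-mu)
        return cls(qx=qx, max_age=max_age)

    # ------------------------------------------------------------------
    @property
    def survival(self) -> np.ndarray:
        """Probability of surviving to each exact age 0..max_age + 1."""
        return self._surv

    def life_expectancy(self) -> float:
        """Expected age at death (mid-year approximation within years)."""
        # person-years lived: trapezoid of the survival curve
        s = self._surv
        return float(np.sum((s[:-1] + s[1:]) / 2.0))

    def sample_death_age(self, u_year: np.ndarray, u_frac: np.ndarray) -> np.ndarray:
        """Invert the survival curve at uniforms ``u_year``.

        The death year is the first age whose survival falls below the
        uniform; ``u_frac`` places the death uniformly within that year.
        """
        s = self._surv
        # s is decreasing; find a with s[a+1] <= u < s[a]
        year = np.searchsorted(-s, -np.asarray(u_year), side="right") - 1
        year = np.clip(year, 0, self.max_age)
        return year + np.asarray(u_frac)

    def sample_keyed(self, seed: int, person_ids: np.ndarray) -> np.ndarray:
        """Counter-based death-age draw (partition invariant)."""
        u_year = _rng.uniform(seed, 0xD0, person_ids)
        u_frac = _rng.uniform(seed, 0xD1, person_ids)
        return self.sample_death_age(u_year, u_frac)

    # ------------------------------------------------------------------
    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"max_age": int(self.max_age), "qx": [float(q) for q in self.qx]},
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "LifeTable":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(qx=np.asarray(data["qx"], dtype=float), max_age=int(data["max_age"]))
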