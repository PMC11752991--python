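"""Synthetic two-group clinical cohort generator.

Emulates the marginal structure of a multicenter cohort of 303 patients
treated endovascularly for intracranial aneurysm: a good prognosis group
(n = 207, Glasgow Outcome Scale 4-5 at six months) and a poor prognosis
group (n = 96, GOS 1-3).  Eight categorical and two continuous variables
differ between the groups (the informative set); seven laboratory /
anthropometric variables plus gender are drawn identically in both groups
(the noise set).  Variables are sampled independently within group —
published summaries give marginals only, so no inter-variable correlation
is emulated.

Ordinal gradings (Hunt-Hess, Fisher, ASA) are generated at the dichotomized
level at which group prevalences are reported (e.g. Hunt-Hess III-V vs
I-II), not on the full grade scale.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd

from .stats import TwoByTwoTable

__all__ = ["BinarySpec", "ContinuousSpec", "CohortConfig", "default_config",
           "generate", "expected_table", "INFORMATIVE_FEATURES",
           "NOISE_FEATURES", "OUTCOME_COLUMN"]

OUTCOME_COLUMN = "outcome"  # 1 = poor prognosis


@dataclass(frozen=True)
class BinarySpec:
    """A 0/1 variable with per-group probability of the positive level."""

    name: str
    p_good: float
    p_poor: float

    def __post_init__(self):
        for p in (self.p_good, self.p_poor):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.name}: probability {p} outside [0, 1]")


@dataclass(frozen=True)
class ContinuousSpec:
    """A normal variable with per-group mean and standard deviation."""

    name: str
    mean_good: float
    sd_good: float
    mean_poor: float
    sd_poor: float

    def __post_init__(self):
        if self.sd_good <= 0 or self.sd_poor <= 0:
            raise ValueError(f"{self.name}: standard deviations must be positive")


@dataclass(frozen=True)
class CohortConfig:
    n_good: int = 207
    n_poor: int = 96
    binary: tuple = ()
    continuous: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_good < 1 or self.n_poor < 1:
            raise ValueError("group sizes must be positive")
        object.__setattr__(self, "binary", tuple(self.binary))
        object.__setattr__(self, "continuous", tuple(self.continuous))

    def variable_names(self) -> list[str]:
        return [s.name for s in self.binary] + [s.name for s in self.continuous]

    def to_json(self) -> str:
        return json.dumps({
            "n_good": self.n_good, "n_poor": self.n_poor, "seed": self.seed,
            "binary": [asdict(s) for s in self.binary],
            "continuous": [asdict(s) for s in self.continuous],
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CohortConfig":
        raw = json.loads(text)
        return cls(n_good=raw["n_good"], n_poor=raw["n_poor"],
                   seed=raw.get("seed", 0),
                   binary=tuple(BinarySpec(**s) for s in raw["binary"]),
                   continuous=tuple(ContinuousSpec(**s) for s in raw["continuous"]))


def _frac(num: int, den: int) -> float:
    return float(Fraction(num, den))


# Informative categorical variables: positive-level prevalence per group,
# entered as exact published counts over group size.
_INFORMATIVE_BINARY = (
    BinarySpec("hypertension", _frac(111, 207), _frac(77, 96)),
    BinarySpec("preoperative_rupture", _frac(76, 207), _frac(74, 96)),
    BinarySpec("hunt_hess_high", _frac(62, 207), _frac(63, 96)),   # III-V
    BinarySpec("fisher_high", _frac(13, 207), _frac(26, 96)),      # 3-4
    BinarySpec("asa_high", _frac(76, 207), _frac(52, 96)),         # III-IV
    BinarySpec("multiple_aneurysms", _frac(41, 207), _frac(31, 96)),
    BinarySpec("etomidate", _frac(36, 207), _frac(7, 96)),
    BinarySpec("intubation", _frac(189, 207), _frac(49, 96)),
)

_INFORMATIVE_CONTINUOUS = (
    ContinuousSpec("age", 55.45, 10.34, 58.28, 11.23),
    ContinuousSpec("surgical_time", 156.34, 21.99, 40.23, 7.28),
)

# Group-invariant noise variables: gender plus seven routine laboratory /
# anthropometric measures at plausible adult reference values.
_NOISE_BINARY = (
    BinarySpec("gender", 0.5, 0.5),
)
_NOISE_CONTINUOUS = (
    ContinuousSpec("body_weight", 65.0, 10.0, 65.0, 10.0),            # kg
    ContinuousSpec("platelet_count", 220.0, 50.0, 220.0, 50.0),       # 1e9/L
    ContinuousSpec("platelet_distribution", 12.5, 2.0, 12.5, 2.0),    # fL
    ContinuousSpec("prothrombin_time", 12.0, 1.0, 12.0, 1.0),         # s
    ContinuousSpec("partial_thromboplastin_time", 30.0, 4.0, 30.0, 4.0),
    ContinuousSpec("thrombin_time", 16.0, 1.5, 16.0, 1.5),            # s
    ContinuousSpec("fibrinogen", 3.0, 0.6, 3.0, 0.6),                 # g/L
)

INFORMATIVE_FEATURES = tuple(s.name for s in _INFORMATIVE_BINARY) + \
    tuple(s.name for s in _INFORMATIVE_CONTINUOUS)
NOISE_FEATURES = tuple(s.name for s in _NOISE_BINARY) + \
    tuple(s.name for s in _NOISE_CONTINUOUS)


def default_config(seed: int = 0, n_good: int = 207,
                   n_poor: int = 96) -> CohortConfig:
    """The reference-cohort configuration (303 patients, 18 variables)."""
    return CohortConfig(
        n_good=n_good, n_poor=n_poor, seed=seed,
        binary=_INFORMATIVE_BINARY + _NOISE_BINARY,
        continuous=_INFORMATIVE_CONTINUOUS + _NOISE_CONTINUOUS)


def generate(config: CohortConfig) -> pd.DataFrame:
    """Draw a cohort; fully reproducible from ``config.seed``.

    Returns one row per patient with every configured variable plus the
    binary ``outcome`` column (1 = poor prognosis).  Rows are shuffled so
    group membership is not encoded in row order.
    """
    rng = np.random.default_rng(config.seed)
    frames = []
    for group, n in (("good", config.n_good), ("poor", config.n_poor)):
        cols = {}
        for s in config.binary:
            p = s.p_good if group == "good" else s.p_poor
            cols[s.name] = (rng.random(n) < p).astype(int)
        for s in config.continuous:
            mean = s.mean_good if group == "good" else s.mean_poor
            sd = s.sd_good if group == "good" else s.sd_poor
            cols[s.name] = rng.normal(mean, sd, size=n)
        cols[OUTCOME_COLUMN] = np.full(n, 0 if group == "good" else 1)
        frames.append(pd.DataFrame(cols))
    df = pd.concat(frames, ignore_index=True)
    order = rng.permutation(len(df))
    return df.iloc[order].reset_index(drop=True)


def _largest_remainder(n: int, probs: Sequence[float]) -> list[int]:
    raw = [n * p for p in probs]
    base = [int(np.floor(v)) for v in raw]
    short = n - sum(base)
    order = np.argsort([b - v for b, v in zip(base, raw)])  # largest remainder first
    for k in order[:short]:
        base[int(k)] += 1
    return base


def expected_table(config: CohortConfig, variable: str) -> TwoByTwoTable:
    """Expected 2x2 counts (rows = good/poor group, columns = no/yes level).

    Uses largest-remainder rounding so each row sums to its group size.
    """
    spec = next((s for s in config.binary if s.name == variable), None)
    if spec is None:
        raise KeyError(f"{variable!r} is not a categorical variable of this "
                       f"configuration")
    g_no, g_yes = _largest_remainder(config.n_good, [1 - spec.p_good, spec.p_good])
    p_no, p_yes = _largest_remainder(config.n_poor, [1 - spec.p_poor, spec.p_poor])
    return TwoByTwoTable(a=g_no, b=g_yes, c=p_no, d=p_yes)
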