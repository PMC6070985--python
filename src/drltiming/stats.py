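"""Effect sizes, exact two-sample KS statistic, and BEC utilities.

Effect sizes follow the independent-samples conversions: Cohen's d from a
t statistic via d = t * sqrt(1/n1 + 1/n2), and the point-biserial-style
correlation r = d / sqrt(d^2 + 4).  The Kolmogorov-Smirnov D is computed
exactly as the supremum of |ECDF_x - ECDF_y| over the pooled sample points
(appropriate for the small group sizes of cumulative progressive-ratio
curves); a seeded permutation p-value is available instead of the asymptotic
approximation.

Blood-ethanol utilities implement the instrument noise-floor correction
(subtract the mean technical error, 3.9 mg/dL, clamped at zero) and the
vapor-titration target-range check (125-250 mg/dL, bounds inclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "EffectSize",
    "BECCheck",
    "cohen_d_from_t",
    "effect_r_from_d",
    "effect_size_from_t",
    "ks_two_sample",
    "ks_permutation_pvalue",
    "bec_correct",
    "bec_in_range",
    "mgdl_to_mm",
    "DEFAULT_BEC_NOISE_FLOOR",
    "BEC_TARGET_RANGE_MGDL",
]

#: Mean instrument/technical error of the BEC analyzer, mg/dL.
DEFAULT_BEC_NOISE_FLOOR = 3.9

#: Vapor-titration target range, mg/dL (inclusive bounds).
BEC_TARGET_RANGE_MGDL = (125.0, 250.0)

#: Molecular weight of ethanol, g/mol (for the mg/dL -> mM convenience only).
_ETHANOL_MW = 46.07


def cohen_d_from_t(t: float, n1: int, n2: int) -> float:
    """Cohen's d from an independent-samples t: d = t * sqrt(1/n1 + 1/n2)."""
    if n1 < 2 or n2 < 2:
        raise InvalidInputError("both groups need n >= 2")
    return t * math.sqrt(1.0 / n1 + 1.0 / n2)


def effect_r_from_d(d: float) -> float:
    """Effect-size correlation from d: r = d / sqrt(d^2 + 4)."""
    return d / math.sqrt(d * d + 4.0)


@dataclass(frozen=True)
class EffectSize:
    """Effect-size record derived from a two-group t statistic."""

    t_value: float
    n1: int
    n2: int
    d: float
    r: float

    @property
    def df(self) -> int:
        return self.n1 + self.n2 - 2


def effect_size_from_t(t: float, n1: int, n2: int) -> EffectSize:
    """Full d -> r chain from a printed t statistic and group sizes."""
    d = cohen_d_from_t(t, n1, n2)
    return EffectSize(t_value=t, n1=n1, n2=n2, d=d, r=effect_r_from_d(d))


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact two-sample KS statistic: sup |ECDF_x - ECDF_y| over pooled points."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidInputError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    xs, ys = np.sort(x), np.sort(y)
    fx = np.searchsorted(xs, pooled, side="right") / x.size
    fy = np.searchsorted(ys, pooled, side="right") / y.size
    return float(np.max(np.abs(fx - fy)))


def ks_permutation_pvalue(
    x: Sequence[float],
    y: Sequence[float],
    n_permutations: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation p-value for the exact KS D (suited to small samples).

    Returns ``(D, p)`` where p is the fraction of label permutations whose D
    is at least the observed one (add-one correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d_obs = ks_two_sample(x, y)
    pooled = np.concatenate([x, y])
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        if ks_two_sample(perm[: x.size], perm[x.size :]) >= d_obs:
            n_ge += 1
    return d_obs, (n_ge + 1) / (n_permutations + 1)


def bec_correct(raw_mgdl: float, noise_floor: float = DEFAULT_BEC_NOISE_FLOOR) -> float:
    """Subtract the instrument noise floor from a raw BEC, clamped at zero."""
    if raw_mgdl < 0:
        raise InvalidInputError(f"raw BEC must be >= 0, got {raw_mgdl}")
    return max(0.0, raw_mgdl - noise_floor)


class BECCheck(NamedTuple):
    in_target: bool
    adjust: str  # "none", "up" (below range) or "down" (above range)


def bec_in_range(
    corrected_mgdl: float,
    lo: float = BEC_TARGET_RANGE_MGDL[0],
    hi: float = BEC_TARGET_RANGE_MGDL[1],
) -> BECCheck:
    """Is a corrected BEC within the vapor target range (bounds inclusive)?

    When out of range, ``adjust`` says which way vapor levels should move.
    """
    if corrected_mgdl < lo:
        return BECCheck(False, "up")
    if corrected_mgdl > hi:
        return BECCheck(False, "down")
    return BECCheck(True, "none")


def mgdl_to_mm(mgdl: float) -> float:
    """Convenience conversion of an ethanol concentration from mg/dL to mM."""
    return mgdl * 10.0 / _ETHANOL_MW
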