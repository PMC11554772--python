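"""Semi-quantitative immunohistochemistry (IHC) H-score arithmetic.

The H-score summarises a stained slide by the percentage of tumor cells at
each staining intensity level — absent (0), mild (1+), moderate (2+) and
strong (3+) — as

    H = sum_i  i * percent_of_cells_at_intensity_i,   i in {0, 1, 2, 3}

giving a value between 0 (all cells unstained) and 300 (all cells strongly
stained).  The same construction is used in reverse by the cohort simulator:
a latent per-sample protein level is spread over cells with a normal
dispersion and binned into the four intensity levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

INTENSITY_LEVELS = (0, 1, 2, 3)

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class StainProfile:
    """Percentage of cells at each staining intensity level.

    Parameters
    ----------
    percent_at_intensity
        Mapping from intensity level (0-3) to the percentage of cells
        (0-100) at that level.  Omitted levels count as 0%.  Percentages
        must be non-negative and sum to 100 (within 1e-9, so fractional
        entry is fine).
    """

    percent_at_intensity: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pct = dict(self.percent_at_intensity)
        unknown = set(pct) - set(INTENSITY_LEVELS)
        if unknown:
            raise ValueError(f"unknown intensity levels: {sorted(unknown)}")
        values = [float(pct.get(i, 0.0)) for i in INTENSITY_LEVELS]
        if any(v < 0 for v in values):
            raise ValueError("intensity percentages must be non-negative")
        total = sum(values)
        if abs(total - 100.0) > _SUM_TOL:
            raise ValueError(
                f"intensity percentages must sum to 100, got {total!r}"
            )
        object.__setattr__(self, "percent_at_intensity", dict(zip(INTENSITY_LEVELS, values)))

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.percent_at_intensity[i] for i in INTENSITY_LEVELS], dtype=float
        )


def h_score(profile: StainProfile) -> int:
    """Compute the H-score (0-300) of a stain profile.

    Returns ``round(sum_i i * percent_at_intensity[i])``, rounding halves up.
    Equivalently 100 times the mean intensity over cells.
    """
    raw = sum(i * profile.percent_at_intensity[i] for i in INTENSITY_LEVELS)
    return int(min(300, max(0, math.floor(raw + 0.5))))


def intensity_bin_masses(
    latents: np.ndarray,
    thresholds: Sequence[float],
    dispersion: float,
) -> np.ndarray:
    """Normal-distribution mass of each intensity bin for a batch of latents.

    Cells of a sample with latent protein level ``m`` are modelled as
    ``Normal(m, dispersion)``; the three ascending ``thresholds`` carve the
    real line into the four intensity bins.  Returns an ``(n, 4)`` array of
    bin probabilities summing to 1 per row.  Mass sitting exactly on a bin
    boundary belongs to the higher bin (measure-zero for dispersion > 0, but
    it fixes the dispersion -> 0 limit).
    """
    t = np.asarray(thresholds, dtype=float)
    if t.shape != (3,):
        raise ValueError("exactly three intensity thresholds are required")
    if not np.all(np.diff(t) > 0):
        raise ValueError("intensity thresholds must be strictly ascending")
    if not dispersion > 0:
        raise ValueError("dispersion must be positive")
    latents = np.atleast_1d(np.asarray(latents, dtype=float))
    # P(cell < t_k) for each threshold; bins are [t_{k-1}, t_k)
    cdf = norm.cdf((t[None, :] - latents[:, None]) / dispersion)
    masses = np.empty((latents.shape[0], 4))
    masses[:, 0] = cdf[:, 0]
    masses[:, 1] = cdf[:, 1] - cdf[:, 0]
    masses[:, 2] = cdf[:, 2] - cdf[:, 1]
    masses[:, 3] = 1.0 - cdf[:, 2]
    return np.clip(masses, 0.0, 1.0)


def discretize_latent(
    latent: float,
    thresholds: Sequence[float],
    dispersion: float,
) -> StainProfile:
    """Turn a latent protein level into a stain profile.

    The percentages are the normal masses of the four intensity bins for a
    cell population centred at ``latent`` with standard deviation
    ``dispersion``; they sum to 100 by construction.
    """
    masses = intensity_bin_masses(np.array([latent]), thresholds, dispersion)[0]
    pct = masses * 100.0
    # absorb float round-off into the largest bin so the sum is exactly 100
    pct[np.argmax(pct)] += 100.0 - pct.sum()
    return StainProfile(dict(zip(INTENSITY_LEVELS, pct)))


def h_scores_from_latents(
    latents: np.ndarray,
    thresholds: Sequence[float],
    dispersion: float,
) -> np.ndarray:
    """Vectorised ``h_score(discretize_latent(...))`` for the simulator."""
    masses = intensity_bin_masses(latents, thresholds, dispersion)
    raw = 100.0 * masses @ np.array(INTENSITY_LEVELS, dtype=float)
    return np.clip(np.floor(raw + 0.5), 0, 300).astype(int)
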