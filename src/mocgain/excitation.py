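"""Dual-roex excitation patterns with level-dependent tip gain.

Each cochlear place is modelled by two rounded-exponential (roex) filters:
an active *tip* filter centered at the place's characteristic frequency
(CF) with the normal auditory-filter bandwidth ERB_n, and a passive *tail*
filter centered a quarter octave below CF with a bandwidth of 3 ERB_n.
The tip path receives the level-dependent gain of the cochlear IO model;
the tail path has zero gain.  Tip and tail path intensities are summed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_model import CochlearIOParams, gain_at_level

__all__ = [
    "RoexFilterSpec",
    "erb_at_cf",
    "roex_weight",
    "excitation_pattern",
    "default_cf_grid",
]

#: Tail filter center relative to CF (a quarter octave below).
TAIL_CENTER_RATIO = 2.0 ** (-0.25)
#: Tail filter bandwidth relative to the place ERB.
TAIL_ERB_FACTOR = 3.0


def erb_at_cf(cf_khz) -> float:
    """Normal auditory-filter ERB in Hz at characteristic frequency ``cf_khz``.

    ERB_n = 24.67 * (4.37 * CF + 1) Hz with CF in kHz.
    """
    cf = np.asarray(cf_khz, dtype=float)
    if np.any(cf <= 0):
        raise ValueError("characteristic frequency must be positive")
    return (24.67 * (4.37 * cf + 1.0))[()]


@dataclass(frozen=True)
class RoexFilterSpec:
    """A single roex filter: center frequency, bandwidth and gain rule.

    ``gain_rule`` carries the IO-model parameters applied to the filtered
    level (``None`` for a passive, zero-gain filter).
    """

    center_hz: float
    erb_hz: float
    gain_rule: Optional[CochlearIOParams] = None

    def __post_init__(self) -> None:
        if self.center_hz <= 0 or self.erb_hz <= 0:
            raise ValueError("center_hz and erb_hz must be positive")

    @property
    def p(self) -> float:
        """Roex slope parameter p = 4 * center / ERB."""
        return 4.0 * self.center_hz / self.erb_hz

    def weight(self, freq_hz) -> np.ndarray:
        """Filter weight at stimulus frequency ``freq_hz``."""
        g = (np.asarray(freq_hz, dtype=float) - self.center_hz) / self.center_hz
        return roex_weight(self.p, g)


def roex_weight(p: float, g):
    """Rounded-exponential filter weight W(g) = (1 + p|g|) exp(-p|g|).

    ``g`` is the normalized frequency deviation from the filter center;
    symmetric, W(0) = 1, strictly decreasing in |g|.
    """
    if p <= 0:
        raise ValueError("p must be positive")
    pg = p * np.abs(np.asarray(g, dtype=float))
    return ((1.0 + pg) * np.exp(-pg))[()]


def default_cf_grid(
    center_hz: float = 2000.0, n: int = 101, octaves: float = 1.0
) -> np.ndarray:
    """Log-spaced CF grid spanning +/- ``octaves`` around ``center_hz``."""
    return center_hz * 2.0 ** np.linspace(-octaves, octaves, n)


def excitation_pattern(
    stimulus_freq_hz: float,
    stimulus_level_db_spl: float,
    params: CochlearIOParams,
    cf_grid_hz: Sequence[float],
) -> pd.DataFrame:
    """Excitation pattern of a pure tone across a grid of cochlear places.

    For each place CF the stimulus level is passed through the tip filter
    (centered at CF, bandwidth ERB_n) and through the tail filter (centered
    a quarter octave below CF, bandwidth 3 ERB_n).  The tip path then
    receives the level-dependent gain ``G`` evaluated at the tip-filtered
    level; the tail path has no gain.  The two path intensities are summed.

    Returns a frame with columns ``cf_hz``, ``tip_db``, ``tail_db``,
    ``excitation_db``.
    """
    cfs = np.asarray(cf_grid_hz, dtype=float)
    if cfs.size == 0:
        raise ValueError("cf_grid_hz must be non-empty")
    if np.any(np.diff(cfs) <= 0):
        raise ValueError("cf_grid_hz must be sorted ascending")

    erbs = np.asarray(erb_at_cf(cfs / 1000.0), dtype=float)

    # tip path: roex at CF, then compressive gain on the filtered level
    g_tip = (stimulus_freq_hz - cfs) / cfs
    w_tip = np.array(
        [roex_weight(4.0 * cf / erb, g) for cf, erb, g in zip(cfs, erbs, g_tip)]
    )
    tip_level = stimulus_level_db_spl + 10.0 * np.log10(w_tip)
    tip_db = tip_level + gain_at_level(params, tip_level)

    # tail path: roex a quarter octave below CF, 3x wider, zero gain
    tail_centers = cfs * TAIL_CENTER_RATIO
    g_tail = (stimulus_freq_hz - tail_centers) / tail_centers
    w_tail = np.array(
        [
            roex_weight(4.0 * ctr / (TAIL_ERB_FACTOR * erb), g)
            for ctr, erb, g in zip(tail_centers, erbs, g_tail)
        ]
    )
    tail_db = stimulus_level_db_spl + 10.0 * np.log10(w_tail)

    total_db = 10.0 * np.log10(
        10.0 ** (tip_db / 10.0) + 10.0 ** (tail_db / 10.0)
    )
    return pd.DataFrame(
        {
            "cf_hz": cfs,
            "tip_db": tip_db,
            "tail_db": tail_db,
            "excitation_db": total_db,
        }
    )


def write_pattern(pattern: pd.DataFrame, path) -> None:
    """Export a pattern as delimited text (cf_hz, excitation_db)."""
    pattern[["cf_hz", "excitation_db"]].to_csv(path, index=False)
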