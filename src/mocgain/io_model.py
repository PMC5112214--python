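"""Piecewise-linear cochlear input-output model and forward predictions.

The model describes the basilar-membrane response at the signal place with
two input-output (IO) functions:

* the *tip* response ``f_a(L) = L + G(L)`` (dB), where the level-dependent
  active gain ``G(L)`` is maximal (``G_max``) below a lower break point
  ``BP1``, falls linearly with slope ``c - 1`` between ``BP1`` and ``BP2``,
  and is zero above ``BP2`` — so the IO function has slope 1, then the
  compression exponent ``c``, then 1 again;
* the *tail* response ``f_p(L) = L - P`` (dB), a linear response attenuated
  by a constant passive factor ``P`` (not constrained to be positive).

Forward masking is modelled by requiring a fixed intensity ratio ``k``
between the signal response and the masker's internal effect, which decays
at ``mu`` dB/ms with the masker-signal gap.  Masked thresholds follow by
inverting the relevant IO function.  A contralateral efferent elicitor is
modelled as a reduction of ``G_max`` by ``delta_G`` with the break points
held fixed, which raises the compression exponent to ``c_tilde``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np

__all__ = [
    "CochlearIOParams",
    "MaskingContext",
    "ElicitorEffect",
    "IOPoint",
    "gain_at_level",
    "tip_output",
    "tail_output",
    "invert_tip_output",
    "predict_threshold",
    "predict_tmc",
    "predict_gom",
    "apply_excitatory_masking",
    "infer_io_function",
]

#: Smallest admissible compression exponent; keeps the tip inverse
#: well-conditioned (slope 1/c).
C_MIN = 1e-3


@dataclass(frozen=True)
class CochlearIOParams:
    """Parameters of the piecewise-linear cochlear IO functions.

    ``g_max``, ``c`` and the break points are mutually constrained through
    ``g_max = (1 - c) * (bp2 - bp1)``; the canonical constructor stores
    ``(g_max, c, bp1)`` and derives ``bp2``.  ``p`` is the passive
    attenuation of the tail response in dB (may be negative).
    """

    g_max: float
    c: float
    bp1: float
    p: float = 0.0
    bp2: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("g_max", "c", "bp1", "p"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.g_max < 0:
            raise ValueError(f"g_max must be >= 0, got {self.g_max}")
        if not (C_MIN <= self.c <= 1.0):
            raise ValueError(f"c must lie in [{C_MIN}, 1], got {self.c}")
        if self.bp2 is None:
            if self.c >= 1.0:
                if self.g_max > 0:
                    raise ValueError("c == 1 requires g_max == 0")
                # zero-gain limit: any compressive range works; pick 1 dB
                object.__setattr__(self, "bp2", self.bp1 + 1.0)
            else:
                object.__setattr__(
                    self, "bp2", self.bp1 + self.g_max / (1.0 - self.c)
                )
        else:
            if self.bp2 <= self.bp1:
                raise ValueError("bp2 must exceed bp1")
            if abs(self.g_max - (1.0 - self.c) * (self.bp2 - self.bp1)) > 1e-6:
                raise ValueError(
                    "inconsistent parameters: g_max != (1-c)*(bp2-bp1)"
                )

    @classmethod
    def from_bp_ctr(
        cls, g_max: float, c: float, bp_ctr: float, p: float = 0.0
    ) -> "CochlearIOParams":
        """Construct from the center of the compressive range."""
        if c >= 1.0:
            return cls(g_max=g_max, c=c, bp1=bp_ctr - 0.5, p=p)
        half_width = 0.5 * g_max / (1.0 - c)
        return cls(g_max=g_max, c=c, bp1=bp_ctr - half_width, p=p)

    @property
    def bp_ctr(self) -> float:
        """Center of the compressive range, (BP1 + BP2) / 2."""
        return 0.5 * (self.bp1 + self.bp2)

    def with_gain_reduced(self, delta_g: float) -> "CochlearIOParams":
        """Tip IO function with ``G_max`` reduced by ``delta_g``.

        Break points are held fixed; the effective gain is floored at zero,
        so the with-elicitor compression exponent satisfies ``c_tilde <= 1``.
        Gain *enhancement* (negative ``delta_g``) is capped where the
        with-elicitor slope would fall below ``C_MIN``.
        """
        width = self.bp2 - self.bp1
        g_eff = min(max(self.g_max - delta_g, 0.0), (1.0 - C_MIN) * width)
        c_tilde = min(max(1.0 - g_eff / width, C_MIN), 1.0)
        g_eff = (1.0 - c_tilde) * width  # keep the constraint exact
        return CochlearIOParams(
            g_max=g_eff, c=c_tilde, bp1=self.bp1, p=self.p, bp2=self.bp2
        )


@dataclass(frozen=True)
class MaskingContext:
    """Signal level and masking-criterion parameters.

    ``l_s``: signal level in dB SPL.  ``k``: signal-to-masker response ratio
    at threshold, a linear intensity ratio (> 0).  ``mu``: decay rate of the
    masker effect in dB/ms (>= 0), equal to the off-frequency TMC slope.
    """

    l_s: float
    k: float
    mu: float

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.l_s, self.k, self.mu))):
            raise ValueError("masking context fields must be finite")
        if self.k <= 0:
            raise ValueError(f"k must be > 0, got {self.k}")
        if self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")


class ElicitorEffect(NamedTuple):
    """Elicitor-induced gain reduction and the derived compression change."""

    delta_g: float
    c_tilde: float

    @classmethod
    def from_params(
        cls, params: CochlearIOParams, delta_g: float
    ) -> "ElicitorEffect":
        """Derive ``c_tilde`` from ``delta_g`` under fixed break points."""
        g_eff = max(params.g_max - delta_g, 0.0)
        return cls(delta_g, 1.0 - g_eff / (params.bp2 - params.bp1))


class IOPoint(NamedTuple):
    """One point of an inferred IO function (input level, output level)."""

    input_level: float
    output_level: float


# ---------------------------------------------------------------------------
# IO functions


def gain_at_level(params: CochlearIOParams, level):
    """Active tip gain G(L) in dB at input level(s) ``level`` (dB SPL)."""
    level = np.asarray(level, dtype=float)
    g = (params.c - 1.0) * (level - params.bp1) + params.g_max
    return np.clip(g, 0.0, params.g_max)[()]


def tip_output(params: CochlearIOParams, level):
    """Tip response output f_a(L) = L + G(L) in dB."""
    level = np.asarray(level, dtype=float)
    return (level + gain_at_level(params, level))[()]


def tail_output(params: CochlearIOParams, level):
    """Tail response output f_p(L) = L - P in dB."""
    return (np.asarray(level, dtype=float) - params.p)[()]


def invert_tip_output(params: CochlearIOParams, output):
    """Input level producing tip output ``output`` (dB); inverse of f_a.

    Piecewise-linear with slopes 1, 1/c, 1 over the output ranges
    (-inf, BP1 + G_max], [BP1 + G_max, BP2], [BP2, inf).
    """
    o = np.asarray(output, dtype=float)
    knee_lo = params.bp1 + params.g_max  # f_a(BP1)
    knee_hi = params.bp2  # f_a(BP2)
    lo = o - params.g_max
    mid = params.bp1 + (o - knee_lo) / params.c
    out = np.where(o <= knee_lo, lo, np.where(o >= knee_hi, o, mid))
    return out[()]


def invert_tail_output(params: CochlearIOParams, output):
    """Input level producing tail output ``output``; inverse of f_p."""
    return (np.asarray(output, dtype=float) + params.p)[()]


# ---------------------------------------------------------------------------
# Forward-masking predictions


def _required_masker_output(
    params: CochlearIOParams,
    ctx: MaskingContext,
    gap_ms,
    effect: Optional[ElicitorEffect],
):
    """Masker output (dB) whose decayed effect just masks the signal.

    The threshold criterion in intensity units is
    ``f(signal) = k * masker_effect(gap)``, with the masker effect decaying
    by ``mu`` dB/ms of gap; in dB the required masker output is
    ``f_a(L_s) - 10*log10(k) + mu * gap``.  With an elicitor, the signal
    response goes through the gain-reduced tip function.
    """
    gap_ms = np.asarray(gap_ms, dtype=float)
    if not np.all(np.isfinite(gap_ms)):
        raise ValueError("gap_ms must be finite")
    tip = params.with_gain_reduced(effect.delta_g) if effect else params
    sig_out = tip_output(tip, ctx.l_s)
    return sig_out - 10.0 * math.log10(ctx.k) + ctx.mu * gap_ms


def predict_threshold(
    params: CochlearIOParams,
    ctx: MaskingContext,
    gap_ms: float,
    masker: str = "on",
    effect: Optional[ElicitorEffect] = None,
) -> float:
    """Predicted masked threshold (dB SPL) at one masker-signal gap.

    ``masker='on'`` inverts the tip IO function (gain-reduced under an
    elicitor effect), ``masker='off'`` inverts the linear tail function
    (unchanged by the elicitor).
    """
    if masker not in ("on", "off"):
        raise ValueError(f"masker must be 'on' or 'off', got {masker!r}")
    o = _required_masker_output(params, ctx, gap_ms, effect)
    if masker == "off":
        return invert_tail_output(params, o)
    tip = params.with_gain_reduced(effect.delta_g) if effect else params
    return invert_tip_output(tip, o)


def predict_tmc(
    params: CochlearIOParams,
    ctx: MaskingContext,
    gaps_ms: Sequence[float],
    masker: str = "on",
    effect: Optional[ElicitorEffect] = None,
) -> np.ndarray:
    """Predicted temporal masking curve over ``gaps_ms``."""
    gaps = np.asarray(gaps_ms, dtype=float)
    if gaps.size == 0:
        return np.empty(0)
    return np.asarray(predict_threshold(params, ctx, gaps, masker, effect))


def predict_gom(
    params: CochlearIOParams,
    ctx: MaskingContext,
    gap_ms: float,
    signal_levels: Sequence[float],
    effect: Optional[ElicitorEffect] = None,
) -> np.ndarray:
    """Off-frequency growth-of-masking function at a fixed gap.

    Threshold versus signal level has unit slope where the signal sits on a
    linear part of the tip IO function and slope ``c`` inside the
    compressive range.
    """
    levels = np.asarray(signal_levels, dtype=float)
    if levels.size == 0:
        return np.empty(0)
    tip = params.with_gain_reduced(effect.delta_g) if effect else params
    sig_out = tip_output(tip, levels)
    o = sig_out - 10.0 * math.log10(ctx.k) + ctx.mu * float(gap_ms)
    return np.asarray(invert_tail_output(params, o))


def apply_excitatory_masking(
    ctx: MaskingContext, attenuation_db: float
) -> MaskingContext:
    """Context with the signal response attenuated by ``attenuation_db``.

    Direct (central) excitatory masking by the elicitor is equivalent to
    dividing the signal response intensity by ``10**(A/10)``, i.e. to
    scaling the threshold criterion ``k`` up by the same factor.  Both TMCs
    then drop by ``A`` dB wherever the masker sits on a linear IO segment,
    and the inferred IO function is unchanged.
    """
    if attenuation_db < 0:
        raise ValueError("attenuation_db must be >= 0")
    return MaskingContext(
        l_s=ctx.l_s, k=ctx.k * 10.0 ** (attenuation_db / 10.0), mu=ctx.mu
    )


def infer_io_function(
    on_thresholds: Sequence[float],
    off_thresholds: Sequence[float],
    p: float,
) -> list[IOPoint]:
    """Inferred tip IO function from gap-aligned on/off thresholds.

    Plots each off-frequency threshold, corrected for the passive tail
    attenuation ``p``, against the on-frequency threshold at the same gap.
    No smoothing or reordering is applied.
    """
    on = np.asarray(on_thresholds, dtype=float)
    off = np.asarray(off_thresholds, dtype=float)
    if on.shape != off.shape or on.ndim != 1:
        raise ValueError("on/off threshold sequences must be 1-d and aligned")
    return [IOPoint(float(i), float(o - p)) for i, o in zip(on, off)]
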