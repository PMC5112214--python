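"""Synthetic cohorts, adaptive-track threshold simulation and CEOAE waveforms.

Subjects are sampled from parameter ranges bracketing those reported for
normal-hearing listeners.  Each masking threshold is produced by simulating
the experimental three-interval, three-alternative forced-choice (3-AFC)
adaptive tracking procedure: the masker level follows a two-up, one-down
rule (converging on 70.7 % correct), with step sizes of 10 dB up to the
first reversal, 5 dB up to the second, and 2.5 dB for the remaining ten;
the track ends after 12 reversals and the threshold estimate is the mean of
the last ten reversal levels.  Six estimates are acquired per condition and
the subset (size >= 3) with the minimum standard error is averaged.

CEOAE recordings are emulated as a deterministic emission (a sum of
decaying tone bursts with latencies inside the 6-16 ms analysis window)
plus independent replicate noise scaled as 1/sqrt(n_trials); a with-
elicitor recording scales the emission by a controllable suppression
factor.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from . import ceoae as _ceoae
from .io_model import (
    CochlearIOParams,
    ElicitorEffect,
    MaskingContext,
    predict_threshold,
)

__all__ = [
    "PopulationSpec",
    "TrackConfig",
    "SubjectRecord",
    "EmissionSpec",
    "sample_subject",
    "simulate_track",
    "select_estimate",
    "default_design",
    "generate_tmc_dataset",
    "generate_cohort",
    "generate_ceoae_recording",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Uniform sampling ranges for true subject parameters.

    Defaults bracket the parameter ranges reported for a 12-subject
    normal-hearing cohort (G_max 13-36 dB, c 0.05-0.65, BP_ctr 37-53 dB
    SPL, k 0.69-3.0, mu 0.12-0.97 dB/ms, P 11-35 dB, dG -1-22 dB).  The
    signal level range corresponds to 10 dB SL on quiet thresholds of
    ~18-29 dB SPL.  ``dG`` draws are additionally capped at 0.9 G_max: a
    reduction at or beyond the available gain floors the with-elicitor
    gain at zero, where the TMCs no longer determine dG uniquely.
    ``noise_sd`` is the simulated observer's internal noise in dB (the
    psychometric-function spread); 0 disables track simulation and returns
    exact model thresholds.
    """

    g_max: tuple[float, float] = (13.0, 36.0)
    c: tuple[float, float] = (0.05, 0.65)
    bp_ctr: tuple[float, float] = (37.0, 53.0)
    k: tuple[float, float] = (0.69, 3.0)
    mu: tuple[float, float] = (0.12, 0.97)
    p: tuple[float, float] = (11.0, 35.0)
    delta_g: tuple[float, float] = (-1.0, 22.0)
    l_s: tuple[float, float] = (28.0, 39.0)
    noise_sd: float = 2.0
    delta_g_gain_cap: float = 0.9

    def __post_init__(self) -> None:
        for name in ("g_max", "c", "bp_ctr", "k", "mu", "p", "delta_g", "l_s"):
            lo, hi = getattr(self, name)
            if not (lo <= hi):
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class TrackConfig:
    """Adaptive-track rules and estimate selection."""

    rule: str = "two_up_one_down"
    step_schedule: tuple[float, float, float] = (10.0, 5.0, 2.5)
    n_reversals: int = 12
    average_last: int = 10
    n_estimates: int = 6
    min_subset: int = 3
    start_offset_db: float = -20.0  # track starts below the true threshold

    def __post_init__(self) -> None:
        if self.rule not in ("two_up_one_down", "two_down_one_up"):
            raise ValueError(f"unknown rule {self.rule!r}")
        if self.average_last >= self.n_reversals + 1:
            raise ValueError("average_last must be <= n_reversals")
        if self.min_subset > self.n_estimates:
            raise ValueError("min_subset must be <= n_estimates")


@dataclass(frozen=True)
class SubjectRecord:
    """True generating parameters of one synthetic subject."""

    subject_id: str
    params: CochlearIOParams
    ctx: MaskingContext
    delta_g: float
    noise_sd: float

    @property
    def effect(self) -> ElicitorEffect:
        return ElicitorEffect.from_params(self.params, self.delta_g)

    @property
    def record(self) -> dict:
        eff = self.effect
        return {
            "subject_id": self.subject_id,
            "G_max": self.params.g_max,
            "c": self.params.c,
            "BP_ctr": self.params.bp_ctr,
            "k": self.ctx.k,
            "mu": self.ctx.mu,
            "P": self.params.p,
            "dG": eff.delta_g,
            "c_tilde": min(eff.c_tilde, 1.0),
        }


def sample_subject(
    spec: PopulationSpec, rng: np.random.Generator, subject_id: str = "SYN1"
) -> SubjectRecord:
    """Draw one subject's true parameters from ``spec`` (uniform ranges)."""
    u = lambda r: float(rng.uniform(*r))
    g_max = u(spec.g_max)
    params = CochlearIOParams.from_bp_ctr(
        g_max, u(spec.c), u(spec.bp_ctr), p=u(spec.p)
    )
    # the TMC method presumes a low-level signal whose response sits on the
    # linear segment below BP1; a signal inside the compressive range makes
    # (G_max, BP1) jointly unidentifiable from the TMCs
    l_s = min(u(spec.l_s), params.bp1 - 2.0)
    ctx = MaskingContext(l_s=l_s, k=u(spec.k), mu=u(spec.mu))
    dg = min(u(spec.delta_g), spec.delta_g_gain_cap * g_max)
    return SubjectRecord(
        subject_id=subject_id,
        params=params,
        ctx=ctx,
        delta_g=dg,
        noise_sd=spec.noise_sd,
    )


# 3-AFC psychometric function: chance 1/3, tracking target 70.7 % correct
_CHANCE = 1.0 / 3.0
_TARGET = 1.0 / math.sqrt(2.0)
# offset placing the 70.7 %-correct point at the true threshold
_Z_TARGET = float(ndtri((_TARGET - _CHANCE) / (1.0 - _CHANCE)))


def _p_correct(masker_level: float, true_threshold: float, sd: float) -> float:
    """Probability of a correct 3-AFC response at a given masker level.

    Cumulative-Gaussian psychometric function of the masker level with
    spread ``sd`` (dB); detectability falls as the masker level rises.  At
    ``masker_level == true_threshold`` the probability is exactly the
    70.7 %-correct tracking target; ``sd -> 0`` gives a step observer that
    guesses (p = 1/3) above threshold.
    """
    if sd <= 0:
        return 1.0 if masker_level < true_threshold else _CHANCE
    z = (true_threshold - masker_level) / sd + _Z_TARGET
    return _CHANCE + (1.0 - _CHANCE) * float(ndtr(z))


def simulate_track(
    true_threshold_db: float,
    config: TrackConfig,
    observer_sd_db: float,
    rng: np.random.Generator,
) -> float:
    """Simulate one adaptive track and return its threshold estimate (dB).

    The adaptive variable starts ``config.start_offset_db`` from the true
    threshold (below it for masker tracks, which ascend under the two-up,
    one-down rule from a weakly masking start) and moves by the reversal-
    keyed step schedule; the estimate is the mean of the last
    ``average_last`` reversal levels.
    """
    up_after_correct = config.rule == "two_up_one_down"
    level = true_threshold_db + config.start_offset_db
    steps = config.step_schedule
    n_correct = 0
    direction = 0  # +1 moving up, -1 moving down
    reversals: list[float] = []
    while len(reversals) < config.n_reversals:
        correct = rng.random() < _p_correct(
            level, true_threshold_db, observer_sd_db
        )
        move = 0
        if correct:
            n_correct += 1
            if n_correct == 2:
                n_correct = 0
                move = 1 if up_after_correct else -1
        else:
            n_correct = 0
            move = -1 if up_after_correct else 1
        if move:
            if direction and move != direction:
                reversals.append(level)
            step = steps[min(len(reversals), len(steps) - 1)]
            level += move * step
            direction = move
    return float(np.mean(reversals[-config.average_last :]))


def select_estimate(
    estimates: Sequence[float], min_subset: int = 3
) -> float:
    """Average of the estimate subset with the minimum standard error.

    All subsets of size ``min_subset`` to n are considered; the standard
    error is sd(ddof=1)/sqrt(n).  Ties prefer the larger subset, then the
    lexicographically first index combination.
    """
    est = np.asarray(estimates, dtype=float)
    n = est.size
    if n < min_subset:
        raise ValueError(f"need at least {min_subset} estimates")
    best_key = None
    best_mean = math.nan
    for size in range(min_subset, n + 1):
        for idx in itertools.combinations(range(n), size):
            sub = est[list(idx)]
            sem = float(np.std(sub, ddof=1)) / math.sqrt(size)
            key = (sem, -size, idx)
            if best_key is None or key < best_key:
                best_key = key
                best_mean = float(sub.mean())
    return best_mean


def default_design(
    gaps_ms: Sequence[float] = (5, 10, 15, 20, 25, 30),
    full: bool = True,
) -> list[tuple[float, str, str]]:
    """Condition cells (gap, masker, elicitor) of the TMC experiment.

    ``full=True`` is the complete 2x2 design; ``full=False`` is the reduced
    design omitting the with-elicitor off-frequency cell.
    """
    cells = []
    for gap in gaps_ms:
        for masker in ("on", "off"):
            for elicitor in ("without", "with"):
                if not full and masker == "off" and elicitor == "with":
                    continue
                cells.append((float(gap), masker, elicitor))
    return cells


def generate_tmc_dataset(
    subject: SubjectRecord,
    design: Sequence[tuple[float, str, str]],
    config: TrackConfig = TrackConfig(),
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Simulated TMC threshold table for one subject.

    Per condition cell the true threshold comes from the IO model; with
    ``noise_sd > 0``, ``n_estimates`` adaptive tracks are simulated and the
    minimum-standard-error subset averaged.  ``noise_sd == 0`` returns the
    exact model predictions.
    """
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    for gap, masker, elicitor in design:
        effect = subject.effect if elicitor == "with" else None
        true = predict_threshold(
            subject.params, subject.ctx, gap, masker, effect
        )
        if subject.noise_sd <= 0:
            thr = float(true)
        else:
            ests = [
                simulate_track(float(true), config, subject.noise_sd, rng)
                for _ in range(config.n_estimates)
            ]
            thr = select_estimate(ests, config.min_subset)
        rows.append(
            {
                "subject_id": subject.subject_id,
                "gap_ms": gap,
                "masker": masker,
                "elicitor": elicitor,
                "threshold_db_spl": thr,
                "signal_level_db_spl": subject.ctx.l_s,
            }
        )
    return pd.DataFrame(rows)


def generate_cohort(
    spec: PopulationSpec,
    n_subjects: int,
    design: Optional[Sequence[tuple[float, str, str]]] = None,
    config: TrackConfig = TrackConfig(),
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample a cohort and simulate its TMC tables.

    Returns (truth table, TMC threshold table).
    """
    if rng is None:
        rng = np.random.default_rng()
    truths, tables = [], []
    for i in range(n_subjects):
        subject = sample_subject(spec, rng, subject_id=f"SYN{i + 1}")
        truths.append(subject.record)
        cells = design if design is not None else identifiable_design(subject)
        tables.append(generate_tmc_dataset(subject, cells, config, rng))
    truth = pd.DataFrame(
        truths,
        columns=[
            "subject_id",
            "G_max",
            "c",
            "BP_ctr",
            "k",
            "mu",
            "P",
            "dG",
            "c_tilde",
        ],
    )
    table_cols = [
        "subject_id",
        "gap_ms",
        "masker",
        "elicitor",
        "threshold_db_spl",
        "signal_level_db_spl",
    ]
    if tables:
        tmc = pd.concat(tables, ignore_index=True)
    else:
        tmc = pd.DataFrame(columns=table_cols)
    return truth, tmc


def identifiable_design(
    subject: SubjectRecord,
) -> list[tuple[float, str, str]]:
    """Gap grid sampling all three segments of the subject's IO function.

    All six baseline parameters are identifiable only when the required
    on-frequency masker output traverses the compressive range: the knee
    positions pin the break points and the mid-segment slope pins c.  The
    grid places several gaps below the lower knee, inside the compressive
    range, and above the upper break point (the last segment separates
    G_max from the passive attenuation P).
    """
    params, ctx = subject.params, subject.ctx
    from .io_model import tip_output  # local import to avoid cycle at top

    o_start = tip_output(params, ctx.l_s) - 10.0 * math.log10(ctx.k)
    knee_lo = params.bp1 + params.g_max
    t_knee = max((knee_lo - o_start) / ctx.mu, 0.0)
    t_bp2 = (params.bp2 - o_start) / ctx.mu
    t_end = t_bp2 + max(5.0 / ctx.mu, 0.2 * (t_bp2 - t_knee))
    gaps = np.concatenate(
        [
            np.linspace(0.0, t_knee, 4),
            np.linspace(t_knee, t_bp2, 6)[1:-1],
            np.linspace(t_bp2, t_end, 4),
        ]
    )
    gaps = np.unique(np.round(gaps, 2))
    return default_design(gaps_ms=gaps, full=True)


# ---------------------------------------------------------------------------
# CEOAE generation


@dataclass(frozen=True)
class EmissionSpec:
    """Deterministic CEOAE emission model plus replicate noise level.

    The emission is a sum of exponentially decaying tone bursts whose
    latencies fall inside the 6-16 ms analysis window (longer latencies
    for lower frequencies, echoing cochlear travel time).  ``components``
    are (frequency Hz, latency ms, peak amplitude Pa, decay ms) tuples.
    ``trial_noise_sd`` is the per-trial noise sd in Pa; replicate noise
    scales as 1/sqrt(n_trials).
    """

    components: tuple = (
        (1000.0, 12.0, 1.2e-4, 2.5),
        (1500.0, 10.5, 1.5e-4, 2.0),
        (2000.0, 9.0, 1.5e-4, 1.8),
        (3000.0, 7.5, 1.0e-4, 1.5),
    )
    duration_ms: float = 20.0
    fs: float = _ceoae.SAMPLE_RATE_HZ
    # per-trial noise giving a post-filter replicate SNR near 20 at 2000
    # averaged trials, i.e. replicate reproducibility around 0.95
    trial_noise_sd: float = 1.0e-3

    def waveform(self) -> np.ndarray:
        n = int(round(self.duration_ms / 1000.0 * self.fs))
        t = np.arange(n) / self.fs
        wave = np.zeros(n)
        for f, lat_ms, amp, tau_ms in self.components:
            t0 = lat_ms / 1000.0
            env = np.where(
                t >= t0, np.exp(-(t - t0) / (tau_ms / 1000.0)), 0.0
            )
            wave += amp * env * np.sin(2.0 * np.pi * f * (t - t0))
        return wave


def generate_ceoae_recording(
    spec: EmissionSpec,
    suppression_factor: float,
    n_trials: int = 2000,
    rng: Optional[np.random.Generator] = None,
    elicitor: str = "without",
    click_level: int = 60,
    session: str = "interleaved",
    n_artifact_trials: int = 0,
    return_trials: bool = False,
):
    """Two replicate CEOAE averages with a controllable suppression factor.

    ``suppression_factor`` (0 < s <= 1) scales the emission amplitude when
    ``elicitor == 'with'``.  Each replicate is the deterministic emission
    plus independent Gaussian noise with sd ``trial_noise_sd/sqrt(n_trials)``
    (online averaging emulated).  With ``return_trials`` a small set of raw
    trial buffers is also returned, including ``n_artifact_trials`` trials
    carrying > 5 mPa artifacts inside the 6-16 ms scoring window.
    """
    if not (0.0 < suppression_factor <= 1.0):
        raise ValueError("suppression_factor must lie in (0, 1]")
    if rng is None:
        rng = np.random.default_rng()
    emission = spec.waveform()
    if elicitor == "with":
        emission = emission * suppression_factor
    sd = spec.trial_noise_sd / math.sqrt(n_trials)
    rec = _ceoae.CEOAERecording(
        replicate_a=emission + rng.normal(0.0, sd, emission.size),
        replicate_b=emission + rng.normal(0.0, sd, emission.size),
        click_level=click_level,
        elicitor=elicitor,
        session=session,
        fs=spec.fs,
    )
    if not return_trials:
        return rec
    trials = [
        emission + rng.normal(0.0, spec.trial_noise_sd, emission.size)
        for _ in range(8)
    ]
    i_spike = int(round(0.010 * spec.fs))  # 10 ms, inside the window
    for _ in range(n_artifact_trials):
        buf = emission + rng.normal(0.0, spec.trial_noise_sd, emission.size)
        buf[i_spike] += 10e-3
        trials.append(buf)
    return rec, trials
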