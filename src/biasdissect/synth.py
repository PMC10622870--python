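"""Synthetic two-task line-length experiments.

Generates trial-level datasets with the statistical structure of the
categorize/reproduce paradigm: a 350 px reference line, per-subject
difficulty calibrated by a weighted up-down staircase to 75% accuracy,
and three bias manipulations —

* ``muller_lyer``: arrowhead flankers shift the *perceived* length, so both
  choices and reproductions move with the bias direction;
* ``base_rate``: one category is three times more prevalent, shifting only
  the decision rule;
* ``payoff``: asymmetric penalties (5 vs 1 point) for the two error types,
  again shifting only the decision rule.

Two observer families are provided.  :class:`ObserverSDT` draws a noisy
internal length, compares it to the reference plus a criterion shift for
the choice, and reads the same internal length back out (plus motor noise)
for the reproduction — the minimal architecture realising the
perceptual/decisional dichotomy.  :class:`ObserverDDM` produces choices and
reaction times from a drift-diffusion process with condition-dependent
starting point and drift criterion (see :mod:`biasdissect.ddm`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom, norm

from .staircase import StaircaseConfig, run_staircase

__all__ = [
    "REFERENCE_PX",
    "StimulusDistribution",
    "PayoffScheme",
    "DesignSpec",
    "ObserverSDT",
    "ObserverDDM",
    "build_stimulus_distribution",
    "score_payoff",
    "generate_dataset",
    "make_sdt_cohort",
    "make_ddm_cohort",
]

REFERENCE_PX = 350.0

BIAS_SOURCES = ("muller_lyer", "base_rate", "payoff")
DIRECTIONS = ("short", "long")


@dataclass(frozen=True)
class StimulusDistribution:
    """Two five-value target distributions straddling the reference.

    Values are ``center + {-2,-1,0,1,2} * threshold/4`` with binomial(4, .5)
    weights — a discrete normal-shaped distribution whose mean equals the
    reference minus (short set) or plus (long set) the staircase threshold.
    """

    reference_px: float
    threshold_px: float
    short_values: np.ndarray
    long_values: np.ndarray
    weights: np.ndarray

    def sample(self, category: str, size: int, rng: np.random.Generator) -> np.ndarray:
        values = self.long_values if category == "long" else self.short_values
        return rng.choice(values, size=size, p=self.weights)

    def mean(self, category: str) -> float:
        values = self.long_values if category == "long" else self.short_values
        return float(np.dot(values, self.weights))


def build_stimulus_distribution(reference_px: float, threshold_px: float) -> StimulusDistribution:
    """Build the short/long five-value target distributions.

    Raises ``ValueError`` when the staircase threshold is not a valid
    calibration (non-positive, or at least as large as the reference).
    """
    if reference_px <= 0 or threshold_px <= 0:
        raise ValueError("reference_px and threshold_px must be positive")
    if threshold_px >= reference_px:
        raise ValueError("threshold_px >= reference_px: invalid calibration")
    offsets = np.arange(-2, 3) * (threshold_px / 4.0)
    weights = binom.pmf(np.arange(5), 4, 0.5)
    weights = weights / weights.sum()
    return StimulusDistribution(
        reference_px=float(reference_px),
        threshold_px=float(threshold_px),
        short_values=reference_px - threshold_px + offsets,
        long_values=reference_px + threshold_px + offsets,
        weights=weights,
    )


@dataclass(frozen=True)
class PayoffScheme:
    """Points lost for each error type; asymmetric only in payoff blocks."""

    penalty_incorrect_long: float = 0.0
    penalty_incorrect_short: float = 0.0

    def __post_init__(self) -> None:
        if self.penalty_incorrect_long < 0 or self.penalty_incorrect_short < 0:
            raise ValueError("penalties must be non-negative")


def payoff_scheme_for(direction: str, penalties: tuple[float, float] = (5.0, 1.0)) -> PayoffScheme:
    """The study's penalty scheme for a bias direction.

    With the (5, 1) default and direction ``short``, an incorrect 'long'
    costs 5 points and an incorrect 'short' costs 1 — pushing responses
    toward 'short'; mirrored for direction ``long``.
    """
    heavy, light = penalties
    if direction == "short":
        return PayoffScheme(penalty_incorrect_long=heavy, penalty_incorrect_short=light)
    return PayoffScheme(penalty_incorrect_long=light, penalty_incorrect_short=heavy)


def score_payoff(choice: str, true_category: str, scheme: PayoffScheme) -> float:
    """Points lost on one decision trial: 0 when correct, else the scheme penalty."""
    if choice == true_category:
        return 0.0
    if choice == "long":
        return scheme.penalty_incorrect_long
    return scheme.penalty_incorrect_short


@dataclass(frozen=True)
class DesignSpec:
    """One block design: a bias source and direction plus trial bookkeeping.

    ``base_rate_ratio`` is majority:minority category prevalence (3 in
    base-rate blocks, 1 otherwise); ``task_mix`` the fraction of
    reproduction trials; ``arrowhead_px`` the Müller-Lyer arrowhead length
    (None outside that condition); ``jitter_px`` the horizontal off-center
    jitter range in pixels.
    """

    bias_source: str
    bias_direction: str
    n_trials: int = 300
    task_mix: float = 0.5
    base_rate_ratio: float = 1.0
    payoff_scheme: PayoffScheme = PayoffScheme()
    arrowhead_px: float | None = None
    jitter_px: tuple[int, int] | None = (5, 9)
    block_index: int = 0

    def __post_init__(self) -> None:
        if self.bias_source not in BIAS_SOURCES:
            raise ValueError(f"unknown bias_source {self.bias_source!r}")
        if self.bias_direction not in DIRECTIONS:
            raise ValueError(f"unknown bias_direction {self.bias_direction!r}")
        if not (0.0 <= self.task_mix <= 1.0):
            raise ValueError("task_mix must lie in [0, 1]")
        if self.base_rate_ratio != 1.0 and self.bias_source != "base_rate":
            raise ValueError("base_rate_ratio != 1 only in base_rate blocks")
        if self.arrowhead_px is not None and self.bias_source != "muller_lyer":
            raise ValueError("arrowhead_px only applies to muller_lyer blocks")
        if self.jitter_px is not None and not (5 <= self.jitter_px[0] <= self.jitter_px[1] <= 9):
            raise ValueError("jitter range must lie within [5, 9]")

    @property
    def p_long(self) -> float:
        """Probability that a trial's true category is 'long'."""
        if self.bias_source != "base_rate":
            return 0.5
        r = self.base_rate_ratio
        return r / (r + 1.0) if self.bias_direction == "long" else 1.0 / (r + 1.0)


def study_design(bias_source: str, bias_direction: str, **overrides) -> DesignSpec:
    """Block design with the study's manipulation constants filled in."""
    kwargs: dict = dict(bias_source=bias_source, bias_direction=bias_direction)
    if bias_source == "base_rate":
        kwargs["base_rate_ratio"] = 3.0
    if bias_source == "payoff":
        kwargs["payoff_scheme"] = payoff_scheme_for(bias_direction)
    if bias_source == "muller_lyer":
        kwargs["arrowhead_px"] = 40.0
    kwargs.update(overrides)
    return DesignSpec(**kwargs)


@dataclass(frozen=True)
class ObserverSDT:
    """Noisy-length observer with separable perceptual and decisional biases.

    On each trial the perceived length is ``target + perceptual_shift +
    N(0, sensory_noise_sd)``.  The choice is 'long' when the perceived
    length exceeds ``reference + criterion_shift + N(0,
    criterion_noise_sd)`` — the criterion jitter captures comparison and
    memory noise that degrades the 2AFC without blurring the percept
    itself, which is what lets reproduction track the target more tightly
    than discrimination accuracy alone would allow.  The reproduction is
    the perceived length plus ``N(0, reproduction_noise_sd)``.  Perceptual
    shifts are keyed by ``(bias_source, bias_direction)`` (optionally
    scaled with arrowhead length) and must be zero outside the Müller-Lyer
    condition; criterion shifts must be zero outside payoff/base-rate —
    the ground-truth dissociation the paradigm is built to detect.
    """

    sensory_noise_sd: float = 24.0
    criterion_noise_sd: float = 37.4
    perceptual_shift: Mapping[tuple[str, str], float] = field(default_factory=dict)
    criterion_shift: Mapping[tuple[str, str], float] = field(default_factory=dict)
    arrowhead_scale: Mapping[float, float] = field(default_factory=dict)
    reproduction_noise_sd: float = 14.0
    lapse_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lapse_rate <= 0.1):
            raise ValueError("lapse_rate must lie in [0, 0.1]")
        if self.sensory_noise_sd <= 0 or self.criterion_noise_sd < 0:
            raise ValueError("noise SDs must be positive")
        for (src, _), val in self.perceptual_shift.items():
            if src != "muller_lyer" and val != 0.0:
                raise ValueError("perceptual_shift must be zero outside muller_lyer")
        for (src, _), val in self.criterion_shift.items():
            if src == "muller_lyer" and val != 0.0:
                raise ValueError("criterion_shift must be zero for muller_lyer")

    def shifts(self, design: DesignSpec) -> tuple[float, float]:
        key = (design.bias_source, design.bias_direction)
        p = self.perceptual_shift.get(key, 0.0)
        if design.arrowhead_px is not None and self.arrowhead_scale:
            p = p * self.arrowhead_scale.get(design.arrowhead_px, 1.0)
        return p, self.criterion_shift.get(key, 0.0)

    @property
    def discrimination_sd(self) -> float:
        """Total noise limiting the 2AFC (encoding plus criterion jitter)."""
        return float(np.hypot(self.sensory_noise_sd, self.criterion_noise_sd))

    def prob_correct(self, offset_px: float) -> float:
        """Unbiased two-category accuracy at a symmetric target offset."""
        p = norm.cdf(offset_px / self.discrimination_sd)
        return (1.0 - self.lapse_rate) * p + self.lapse_rate * 0.5

    def offset_at_accuracy(self, accuracy: float) -> float:
        """Offset (px) at which ``prob_correct`` equals ``accuracy``."""
        core = (accuracy - self.lapse_rate * 0.5) / (1.0 - self.lapse_rate)
        return float(self.discrimination_sd * norm.ppf(core))


@dataclass(frozen=True)
class ObserverDDM:
    """Drift-diffusion observer for the decision-only experiments.

    ``v`` is the stimulus drift magnitude (sign set by the true category);
    ``z_map``/``dc_map`` give the starting point and drift criterion per
    ``(bias_source, bias_direction)`` cell (keys extend to
    ``(source, direction, arrowhead_px)`` in arrowhead designs).
    """

    a: float = 2.0
    v: float = 1.0
    t0: float = 0.3
    sv: float = 0.0
    z_map: Mapping[tuple, float] = field(default_factory=dict)
    dc_map: Mapping[tuple, float] = field(default_factory=dict)

    def cell_params(self, design: DesignSpec) -> tuple[float, float]:
        key3 = (design.bias_source, design.bias_direction, design.arrowhead_px)
        key2 = (design.bias_source, design.bias_direction)
        z = self.z_map.get(key3, self.z_map.get(key2, 0.5))
        dc = self.dc_map.get(key3, self.dc_map.get(key2, 0.0))
        return z, dc


TRIAL_COLUMNS = [
    "subject_id",
    "bias_source",
    "bias_direction",
    "arrowhead_px",
    "block_index",
    "trial_index",
    "target_px",
    "true_category",
    "task",
    "choice",
    "rt_s",
    "reproduction_px",
    "points_lost",
]


def _categories(design: DesignSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    return np.where(rng.random(n) < design.p_long, "long", "short")


def _tasks(design: DesignSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    n_repro = int(round(design.task_mix * n))
    tasks = np.array(["decision"] * (n - n_repro) + ["reproduction"] * n_repro)
    rng.shuffle(tasks)
    return tasks


def _sdt_block(subject_id, observer: ObserverSDT, design: DesignSpec,
               stim: StimulusDistribution, rng: np.random.Generator) -> pd.DataFrame:
    n = design.n_trials
    cats = _categories(design, n, rng)
    tasks = _tasks(design, n, rng)
    targets = np.empty(n)
    for cat in DIRECTIONS:
        m = cats == cat
        targets[m] = stim.sample(cat, int(m.sum()), rng)
    pshift, cshift = observer.shifts(design)
    internal = targets + pshift + rng.normal(0.0, observer.sensory_noise_sd, n)

    cut = stim.reference_px + cshift + rng.normal(0.0, observer.criterion_noise_sd, n)
    choice = np.where(internal > cut, "long", "short")
    if observer.lapse_rate > 0:
        lapse = rng.random(n) < observer.lapse_rate
        guesses = np.where(rng.random(n) < 0.5, "long", "short")
        choice = np.where(lapse, guesses, choice)
    repro = internal + rng.normal(0.0, observer.reproduction_noise_sd, n)

    dec = tasks == "decision"
    points = np.array([
        score_payoff(c, t, design.payoff_scheme) if d else np.nan
        for c, t, d in zip(choice, cats, dec)
    ])
    return pd.DataFrame({
        "subject_id": subject_id,
        "bias_source": design.bias_source,
        "bias_direction": design.bias_direction,
        "arrowhead_px": np.nan if design.arrowhead_px is None else float(design.arrowhead_px),
        "block_index": design.block_index,
        "trial_index": np.arange(n),
        "target_px": targets,
        "true_category": cats,
        "task": tasks,
        "choice": np.where(dec, choice, None),
        "rt_s": np.nan,
        "reproduction_px": np.where(dec, np.nan, repro),
        "points_lost": points,
    })


def _ddm_block(subject_id, observer: ObserverDDM, design: DesignSpec,
               stim: StimulusDistribution, rng: np.random.Generator) -> pd.DataFrame:
    from .ddm import DDMParams, simulate

    n = design.n_trials
    cats = _categories(design, n, rng)
    targets = np.empty(n)
    for cat in DIRECTIONS:
        m = cats == cat
        targets[m] = stim.sample(cat, int(m.sum()), rng)
    z, dc = observer.cell_params(design)
    sign = np.where(cats == "long", 1.0, -1.0)

    choice = np.empty(n, dtype=object)
    rt = np.empty(n)
    for cat_sign in (1.0, -1.0):
        m = sign == cat_sign
        params = DDMParams(a=observer.a, v=cat_sign * observer.v, t0=observer.t0,
                           z=z, dc=dc, sv=observer.sv)
        ch, rts = simulate(params, int(m.sum()), seed=rng)
        choice[m] = np.where(ch == 1, "long", "short")
        rt[m] = rts
    points = np.array([
        score_payoff(c, t, design.payoff_scheme) for c, t in zip(choice, cats)
    ])
    return pd.DataFrame({
        "subject_id": subject_id,
        "bias_source": design.bias_source,
        "bias_direction": design.bias_direction,
        "arrowhead_px": np.nan if design.arrowhead_px is None else float(design.arrowhead_px),
        "block_index": design.block_index,
        "trial_index": np.arange(n),
        "target_px": targets,
        "true_category": cats,
        "task": "decision",
        "choice": choice,
        "rt_s": rt,
        "reproduction_px": np.nan,
        "points_lost": points,
    })


def generate_dataset(designs: DesignSpec | Sequence[DesignSpec], observers: Sequence,
                     seed=0, thresholds: Sequence[float] | None = None,
                     reference_px: float = REFERENCE_PX,
                     staircase_cfg: StaircaseConfig = StaircaseConfig()) -> pd.DataFrame:
    """Generate a trial table for a list of observers over one or more block designs.

    SDT observers are staircase-calibrated first (unless per-observer
    ``thresholds`` are given); DDM observers use a nominal threshold since
    their difficulty is carried by the drift magnitude.  Per-subject
    sub-seeds are drawn from ``seed`` via ``SeedSequence.spawn`` and
    recorded in the returned table's ``attrs``.
    """
    if len(observers) == 0:
        raise ValueError("need at least one observer")
    if isinstance(designs, DesignSpec):
        designs = [designs]
    designs = list(designs)
    for i, d in enumerate(designs):
        if d.block_index == 0 and i > 0:
            designs[i] = DesignSpec(**{**d.__dict__, "block_index": i})

    root = np.random.SeedSequence(seed)
    subject_seqs = root.spawn(len(observers))
    frames = []
    sub_seeds = {}
    for sid, (obs, seq) in enumerate(zip(observers, subject_seqs)):
        rng = np.random.default_rng(seq)
        sub_seeds[sid] = seq.entropy
        if thresholds is not None:
            thr = thresholds[sid]
        elif isinstance(obs, ObserverSDT):
            thr = run_staircase(obs, staircase_cfg,
                                seed=np.random.default_rng(seq.spawn(1)[0])).threshold_px
        else:
            thr = 20.0
        stim = build_stimulus_distribution(reference_px, thr)
        for design in designs:
            if isinstance(obs, ObserverSDT):
                frames.append(_sdt_block(sid, obs, design, stim, rng))
            else:
                frames.append(_ddm_block(sid, obs, design, stim, rng))
    table = pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]
    table.attrs["seed"] = seed
    table.attrs["subject_seeds"] = sub_seeds
    return table


def make_sdt_cohort(n_subjects: int, bias_source: str, seed=0,
                    perceptual_shift_px: float = 8.0, perceptual_shift_sd: float = 8.0,
                    criterion_shift_px: float = 10.0, criterion_shift_sd: float = 8.0,
                    sensory_noise_sd: float = 24.0, criterion_noise_sd: float = 37.4,
                    sensory_noise_cv: float = 0.15,
                    reproduction_noise_sd: float = 14.0) -> list[ObserverSDT]:
    """Draw a cohort of SDT observers for one between-subjects bias source.

    Müller-Lyer subjects get a perceptual shift of ±``perceptual_shift_px``
    (long/short) with between-subject SD; payoff/base-rate subjects get a
    criterion shift instead.  Individual sensory noise varies lognormally.
    """
    rng = np.random.default_rng(seed)
    cohort = []
    for _ in range(n_subjects):
        scale = np.exp(rng.normal(0.0, sensory_noise_cv))
        pshift: dict = {}
        cshift: dict = {}
        if bias_source == "muller_lyer":
            mag = rng.normal(perceptual_shift_px, perceptual_shift_sd)
            pshift = {("muller_lyer", "long"): mag, ("muller_lyer", "short"): -mag}
        else:
            mag = rng.normal(criterion_shift_px, criterion_shift_sd)
            # a criterion shift toward 'long' responses lowers the cut point
            cshift = {(bias_source, "long"): -mag, (bias_source, "short"): mag}
        cohort.append(ObserverSDT(
            sensory_noise_sd=sensory_noise_sd * scale,
            criterion_noise_sd=criterion_noise_sd * scale,
            perceptual_shift=pshift,
            criterion_shift=cshift,
            reproduction_noise_sd=reproduction_noise_sd,
        ))
    return cohort


def make_ddm_cohort(n_subjects: int, bias_source: str, seed=0,
                    a: float = 2.0, v: float = 1.0, t0: float = 0.3, sv: float = 0.0,
                    z_contrast: float = 0.0, dc_contrast: float = 0.0,
                    subject_sd: Mapping[str, float] | None = None) -> list[ObserverDDM]:
    """Draw DDM observers whose bias cell parameters realise given contrasts.

    ``z_contrast`` / ``dc_contrast`` are the long-minus-short differences of
    the starting point and drift criterion; each subject's half-contrast is
    jittered by the (small) between-subject SDs in ``subject_sd``.
    """
    sds = {"a": 0.1, "v": 0.1, "t0": 0.02, "z": 0.02, "dc": 0.05}
    if subject_sd:
        sds.update(subject_sd)
    rng = np.random.default_rng(seed)
    cohort = []
    for _ in range(n_subjects):
        dz = rng.normal(z_contrast / 2.0, sds["z"])
        ddc = rng.normal(dc_contrast / 2.0, sds["dc"])
        cohort.append(ObserverDDM(
            a=max(0.5, rng.normal(a, sds["a"])),
            v=rng.normal(v, sds["v"]),
            t0=max(0.1, rng.normal(t0, sds["t0"])),
            sv=sv,
            z_map={(bias_source, "long"): min(0.95, max(0.05, 0.5 + dz)),
                   (bias_source, "short"): min(0.95, max(0.05, 0.5 - dz))},
            dc_map={(bias_source, "long"): ddc, (bias_source, "short"): -ddc},
        ))
    return cohort
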