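"""Adaptive weighted up-down staircase for titrating line-length discriminability.

The staircase adjusts the offset between target and reference line (in
pixels) on a trial-by-trial basis.  Step sizes are asymmetric so that the
procedure converges on the difficulty at which the observer is correct at
``target_rate``: after a correct response the offset shrinks by the down
step, after an error it grows by the up step, with

    up_step / down_step = target_rate / (1 - target_rate)

(3:1 for the default 75% target), the equilibrium condition of the weighted
up-down method.  The base step shrinks geometrically at each reversal down
to ``step_floor`` so the track settles; the threshold is the mean offset at
the last ``n_reversals_used`` reversals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StaircaseConfig", "StaircaseResult", "run_staircase"]


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of the weighted up-down track.

    start_step is the offset (px) at which the track starts; the paper's
    paradigm starts 20 px from the reference length.
    """

    start_step: float = 20.0
    n_reversals_total: int = 25
    n_reversals_used: int = 20
    target_rate: float = 0.75
    step_floor: float = 1.0
    initial_step: float = 4.0
    step_decay: float = 0.85
    max_trials: int = 10_000

    def __post_init__(self) -> None:
        if not (0 < self.n_reversals_used <= self.n_reversals_total):
            raise ValueError("need 0 < n_reversals_used <= n_reversals_total")
        if not (0.0 < self.target_rate < 1.0):
            raise ValueError("target_rate must lie in (0, 1)")
        if self.start_step <= 0:
            raise ValueError("start_step must be positive")
        if self.step_floor <= 0 or self.initial_step < self.step_floor:
            raise ValueError("need initial_step >= step_floor > 0")


@dataclass(frozen=True)
class StaircaseResult:
    threshold_px: float
    n_trials: int
    reversal_values: np.ndarray
    track: np.ndarray


class StaircaseError(RuntimeError):
    """The track failed to accumulate the requested reversals.

    Carries the partial ``track`` for inspection of degenerate observers.
    """

    def __init__(self, message: str, track: np.ndarray | None = None):
        super().__init__(message)
        self.track = track


def run_staircase(observer, cfg: StaircaseConfig = StaircaseConfig(), seed=0) -> StaircaseResult:
    """Run the weighted up-down staircase against a simulated observer.

    Parameters
    ----------
    observer
        Anything exposing ``prob_correct(offset_px)``, the probability of a
        correct short/long judgement when the target differs from the
        reference by ``offset_px`` (must increase with the offset).
    cfg
        Track configuration; defaults follow the study paradigm
        (start 20 px, 25 reversals, last 20 averaged, 75% target).
    seed
        Seed (or ``numpy`` Generator) controlling the Bernoulli responses.

    Returns
    -------
    StaircaseResult
        With ``threshold_px`` the mean offset over the last
        ``n_reversals_used`` reversals.
    """
    rng = np.random.default_rng(seed)
    ratio = cfg.target_rate / (1.0 - cfg.target_rate)

    level = float(cfg.start_step)
    step = float(cfg.initial_step)
    direction = 0  # -1 moving down, +1 moving up, 0 before the first move
    reversals: list[float] = []
    track: list[float] = [level]

    for _ in range(cfg.max_trials):
        correct = rng.random() < observer.prob_correct(level)
        move = -1 if correct else +1
        if direction != 0 and move != direction:
            reversals.append(level)
            step = max(cfg.step_floor, step * cfg.step_decay)
            if len(reversals) >= cfg.n_reversals_total:
                break
        direction = move
        delta = step if correct else step * ratio
        level = max(cfg.step_floor * 0.5, level + move * delta)
        track.append(level)
    else:
        raise StaircaseError(
            f"staircase did not reach {cfg.n_reversals_total} reversals "
            f"within {cfg.max_trials} trials; degenerate observer?",
            track=np.asarray(track),
        )

    used = np.asarray(reversals[-cfg.n_reversals_used:])
    return StaircaseResult(
        threshold_px=float(used.mean()),
        n_trials=len(track) - 1,
        reversal_values=np.asarray(reversals),
        track=np.asarray(track),
    )
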