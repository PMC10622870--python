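"""Drift-diffusion primitives: parameters, densities, closed forms, simulation.

Parameterization: evidence accumulates between a lower ('short') and upper
('long') boundary separated by ``a``, starting at relative point ``z``
(0.5 = unbiased), with within-trial diffusion SD fixed at 1 (the modern
convention — parameter magnitudes are on that scale).  The mean drift on a
trial is the stimulus drift ``v`` (sign set by the true category, positive
toward 'long') plus the drift criterion ``dc``; ``sv`` is the across-trial
SD of the drift.  RT = first-passage time + non-decision time ``t0``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._wfpt import simulate_kernel, wfpt_logpdf

__all__ = [
    "DDMParams",
    "wfpt_density",
    "p_upper",
    "mean_decision_time",
    "simulate",
    "filter_contaminants",
    "gelman_rubin",
]


@dataclass(frozen=True)
class DDMParams:
    """One condition's diffusion parameters (diffusion SD = 1)."""

    a: float = 2.0
    v: float = 1.0
    t0: float = 0.3
    z: float = 0.5
    dc: float = 0.0
    sv: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("boundary separation a must be positive")
        if not (0.0 < self.z < 1.0):
            raise ValueError("relative start point z must lie in (0, 1)")
        if self.t0 < 0:
            raise ValueError("non-decision time t0 must be >= 0")
        if self.sv < 0:
            raise ValueError("across-trial drift SD sv must be >= 0")

    @property
    def drift(self) -> float:
        """Mean effective drift toward the upper boundary."""
        return self.v + self.dc

    def replace(self, **kw) -> "DDMParams":
        return replace(self, **kw)


def wfpt_density(t, boundary: str, params: DDMParams, err: float = 1e-12):
    """First-passage-time density at the named boundary ('upper'/'lower').

    Vectorized over ``t`` (seconds, including t0); zero for t <= t0.
    ``params.sv`` may be nonzero — the drift mixture is integrated
    analytically.
    """
    if boundary not in ("upper", "lower"):
        raise ValueError("boundary must be 'upper' or 'lower'")
    up = boundary == "upper"
    ts = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty_like(ts)
    for i, ti in enumerate(ts):
        lp = wfpt_logpdf(ti, up, params.a, params.drift, params.t0,
                         params.z, params.sv, err)
        out[i] = 0.0 if lp < -1e250 else np.exp(lp)
    return out if np.ndim(t) else float(out[0])


def p_upper(params: DDMParams) -> float:
    """Analytic probability of absorption at the upper ('long') boundary.

    Closed form for a drifted diffusion between two boundaries (sv must be
    0).  With zero effective drift this reduces to the relative start
    point z.
    """
    if params.sv != 0:
        raise ValueError("closed-form p_upper requires sv = 0")
    mu, a, z = params.drift, params.a, params.z
    if abs(mu) < 1e-12:
        return z
    num = -np.expm1(-2.0 * mu * a * z)
    den = -np.expm1(-2.0 * mu * a)
    return float(num / den)


def mean_decision_time(params: DDMParams) -> float:
    """Expected first-passage (decision) time, sv = 0, excluding t0."""
    if params.sv != 0:
        raise ValueError("closed-form mean requires sv = 0")
    mu, a, z = params.drift, params.a, params.z
    x0 = z * a
    if abs(mu) < 1e-12:
        return x0 * (a - x0)
    return (a * p_upper(params) - x0) / mu


def simulate(params: DDMParams, n_trials: int, seed=0, dt: float = 1e-4,
             t_max: float = 20.0, return_flags: bool = False):
    """Simulate choices and RTs by Euler stepping with bridge crossing checks.

    Each trial's drift is ``v + dc`` perturbed by N(0, sv).  Deterministic
    given ``seed`` (an int or a Generator, from which a 31-bit stream seed
    is drawn).  Trials still unabsorbed at ``t_max`` are truncated to the
    nearest boundary and counted; their number is available via
    ``return_flags``.

    Returns
    -------
    (choices, rts) with choices 1 for 'long' (upper) and 0 for 'short';
    with ``return_flags``, also the number of truncated trials.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kseed = int(rng.integers(0, 2**31 - 1))
    choices, rts, n_trunc = simulate_kernel(
        n_trials, params.a, params.v, params.t0, params.z, params.dc,
        params.sv, dt, t_max, kseed)
    if return_flags:
        return choices, rts, n_trunc
    return choices, rts


def filter_contaminants(trials: pd.DataFrame, fast_cut_s: float = 0.2,
                        n_sd: float = 4.0) -> tuple[pd.DataFrame, dict]:
    """Drop contaminant RTs: faster than the cut, then slower than mean + n_sd SD.

    The slow threshold is computed on the sample remaining after the fast
    cut, over the whole experiment sample passed in.  Returns the retained
    trials and a removal log with counts of both classes.
    """
    dec = trials[trials["rt_s"].notna()]
    fast = dec["rt_s"] < fast_cut_s
    kept = dec[~fast]
    mu, sd = kept["rt_s"].mean(), kept["rt_s"].std(ddof=1)
    slow = kept["rt_s"] > mu + n_sd * sd
    log = {
        "n_input": int(len(dec)),
        "n_fast_removed": int(fast.sum()),
        "n_slow_removed": int(slow.sum()),
        "slow_threshold_s": float(mu + n_sd * sd),
    }
    return kept[~slow], log


def gelman_rubin(chains: dict[str, np.ndarray] | np.ndarray) -> "pd.Series | float":
    """Gelman-Rubin R-hat: the classic between/within chain variance ratio.

    ``chains`` is an (n_chains, n_draws) array, or a mapping of parameter
    name to such arrays (a Series of R-hat values is then returned).
    Chains must have equal length and there must be at least two.
    """
    if isinstance(chains, dict):
        return pd.Series({k: gelman_rubin(np.asarray(v)) for k, v in chains.items()})
    draws = np.asarray(chains, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("need a 2-D array with >= 2 chains")
    m, n = draws.shape
    within = draws.var(axis=1, ddof=1).mean()
    between_over_n = draws.mean(axis=1).var(ddof=1)
    var_hat = (n - 1) / n * within + between_over_n
    if within == 0:
        return 1.0
    return float(np.sqrt(var_hat / within))
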