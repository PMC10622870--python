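"""Numba kernels: Wiener first-passage-time density and diffusion simulation.

The density uses the classic dual series expansion with automatic
small-time/large-time switching, choosing whichever representation needs
fewer terms for the requested truncation error.  Everything is expressed
for the *lower* boundary of a diffusion on (0, a) with within-trial
diffusion SD fixed at 1; the upper boundary follows by reflection
(v -> -v, w -> 1 - w).  Across-trial drift variability enters through an
analytic Gaussian-mixture factor, so no per-trial augmentation is needed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

SQRT_2PI = math.sqrt(2.0 * math.pi)


@njit(cache=True)
def _fpt_lower_std(tt: float, w: float, err: float) -> float:
    """Density of the normalized process (a=1, v=0) at the lower boundary.

    ``tt`` is the normalized time t/a^2; ``w`` the relative start point.
    Series truncation follows the bound on the requested absolute error.
    """
    if tt <= 0.0:
        return 0.0
    # number of terms needed by each representation
    if math.pi * tt * err < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tt * err) / (math.pi * math.pi * tt))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(tt)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(tt))
    if 2.0 * SQRT_2PI * tt * err < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tt * math.log(2.0 * err * math.sqrt(2.0 * math.pi * tt)))
        ks = max(ks, math.sqrt(tt) + 1.0)
    else:
        ks = 2.0

    if ks < kl:  # small-time expansion
        K = int(math.ceil(ks))
        acc = 0.0
        for k in range(-((K - 1) // 2), ((K - 1) // 2) + (K - 1) % 2 + 1):
            arg = w + 2.0 * k
            acc += arg * math.exp(-arg * arg / (2.0 * tt))
        return acc / math.sqrt(2.0 * math.pi * tt ** 3)
    K = int(math.ceil(kl))  # large-time expansion
    acc = 0.0
    for k in range(1, K + 1):
        acc += k * math.exp(-k * k * math.pi * math.pi * tt / 2.0) * math.sin(k * math.pi * w)
    return acc * math.pi


@njit(cache=True)
def wfpt_logpdf(t: float, upper: bool, a: float, v: float, t0: float,
                z: float, sv: float, err: float) -> float:
    """Log first-passage density at one boundary for decision time t - t0.

    ``v`` is the (signed) mean drift toward the upper boundary including
    any drift-criterion component; ``sv`` the across-trial drift SD.
    Returns -inf (as a very large negative number) for t <= t0.
    """
    td = t - t0
    if td <= 0.0:
        return -1.0e300
    if upper:
        v = -v
        w = 1.0 - z
    else:
        w = z
    tt = td / (a * a)
    g = _fpt_lower_std(tt, w, err) / (a * a)
    if g <= 0.0:
        return -1.0e300
    if sv > 0.0:
        s2 = sv * sv
        denom = 1.0 + s2 * td
        loge = ((a * w * s2 * a * w) - 2.0 * v * a * w - v * v * td) / (2.0 * denom) \
            - 0.5 * math.log(denom)
    else:
        loge = -v * a * w - v * v * td / 2.0
    return math.log(g) + loge


@njit(cache=True)
def loglik_cell(rt: np.ndarray, upper: np.ndarray, sign: np.ndarray,
                a: float, v: float, t0: float, z: float, dc: float,
                sv: float, err: float) -> float:
    """Summed log-likelihood of one subject-cell's trials.

    ``sign`` codes the true category (+1 long, -1 short); the per-trial
    mean drift is sign * v + dc.  ``upper`` marks 'long' responses.
    """
    total = 0.0
    for i in range(rt.shape[0]):
        vbar = sign[i] * v + dc
        total += wfpt_logpdf(rt[i], upper[i], a, vbar, t0, z, sv, err)
        if total < -1.0e250:
            return -1.0e300
    return total


@njit(cache=True)
def simulate_kernel(n: int, a: float, v: float, t0: float, z: float,
                    dc: float, sv: float, dt: float, t_max: float,
                    seed: int) -> tuple:
    """Euler simulation with Brownian-bridge boundary-crossing correction.

    Between grid points the probability that the path touched a boundary
    is evaluated with the exact bridge formula, removing the leading-order
    discretization bias of plain Euler crossing checks.  Runaway trials
    are truncated at ``t_max`` (choice by nearest boundary) and counted.
    """
    np.random.seed(seed)
    choices = np.empty(n, dtype=np.int8)
    rts = np.empty(n)
    n_truncated = 0
    sdt = math.sqrt(dt)
    for i in range(n):
        mu = v + dc + (sv * np.random.standard_normal() if sv > 0.0 else 0.0)
        x = z * a
        t = 0.0
        done = False
        while t < t_max:
            x_new = x + mu * dt + sdt * np.random.standard_normal()
            t += dt
            if x_new >= a:
                choices[i] = 1
                done = True
            elif x_new <= 0.0:
                choices[i] = 0
                done = True
            else:
                # bridge probability of an unobserved excursion to a boundary
                p_up = math.exp(-2.0 * (a - x) * (a - x_new) / dt)
                p_lo = math.exp(-2.0 * x * x_new / dt)
                u = np.random.random()
                if u < p_up:
                    choices[i] = 1
                    done = True
                elif u < p_up + p_lo:
                    choices[i] = 0
                    done = True
            if done:
                rts[i] = t0 + t
                break
            x = x_new
        if not done:
            n_truncated += 1
            choices[i] = 1 if x >= a / 2.0 else 0
            rts[i] = t0 + t_max
    return choices, rts, n_truncated
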