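"""Shared fixtures.

The two hierarchical DDM fits (drift-criterion-biased and
starting-point-biased synthetic cohorts) are expensive, so they are
session-scoped and shared between the recovery, convergence, predictive
and acceptance tests.  Cohort sizes and the reduced MCMC schedule are the
package's desk-scale defaults (10 subjects x 400 trials, 3 chains x 4,000
samples).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from biasdissect.ddm import (
    DDMModelSpec,
    DDMParams,
    MCMCConfig,
    convergence_report,
    filter_contaminants,
    fit_hierarchical,
    simulate,
)
from biasdissect.synth import generate_dataset, make_ddm_cohort, study_design


def _fit_bundle(dc_contrast: float, z_contrast: float) -> dict:
    cohort = make_ddm_cohort(10, "payoff", seed=11, sv=0.2,
                             dc_contrast=dc_contrast, z_contrast=z_contrast)
    designs = [study_design("payoff", "short", n_trials=200, task_mix=0.0),
               study_design("payoff", "long", n_trials=200, task_mix=0.0, block_index=1)]
    table = generate_dataset(designs, cohort, seed=12)
    dec, _ = filter_contaminants(table)
    fit = fit_hierarchical(dec, DDMModelSpec(), MCMCConfig(seed=5))
    return {
        "cohort": cohort,
        "trials": dec,
        "fit": fit,
        "conv": convergence_report(fit.chains),
        "true": {"dc_contrast": dc_contrast, "z_contrast": z_contrast, "sv": 0.2},
    }


@pytest.fixture(scope="session")
def dc_biased_fit() -> dict:
    """Hierarchical fit to a cohort whose bias is purely drift-criterion."""
    return _fit_bundle(dc_contrast=0.4, z_contrast=0.0)


@pytest.fixture(scope="session")
def z_biased_fit() -> dict:
    """Hierarchical fit to a cohort whose bias is purely starting-point."""
    return _fit_bundle(dc_contrast=0.0, z_contrast=0.1)


def make_ddm_trials(n_subjects: int, n_per_direction: int, z_contrast: float,
                    dc_contrast: float, seed: int, dt: float = 5e-4,
                    sv: float = 0.2) -> pd.DataFrame:
    """Decision-trial table straight from the diffusion simulator.

    Used for the model-free conditional-bias-function checks, which need
    more trials than the hierarchical fits do.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for s in range(n_subjects):
        for direction, sgn in (("long", 1.0), ("short", -1.0)):
            z = 0.5 + sgn * z_contrast / 2
            dc = sgn * dc_contrast / 2
            for cat_sign, cat in ((1.0, "long"), (-1.0, "short")):
                n = n_per_direction // 2
                params = DDMParams(a=2.0, v=cat_sign * 1.0, t0=0.3, z=z, dc=dc, sv=sv)
                ch, rt = simulate(params, n, seed=rng, dt=dt)
                frames.append(pd.DataFrame({
                    "subject_id": s, "bias_source": "payoff",
                    "bias_direction": direction, "true_category": cat,
                    "task": "decision",
                    "choice": np.where(ch == 1, "long", "short"), "rt_s": rt,
                }))
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def arrowhead_fit() -> dict:
    """Fit over four arrowhead lengths with a growing dc contrast and z
    pinned at 0.5; z and dc vary by arrowhead length x direction."""
    lengths = [30.0, 40.0, 50.0, 60.0]
    contrasts = [0.10, 0.25, 0.40, 0.55]
    rng = np.random.default_rng(21)
    frames = []
    for s in range(8):
        a = max(0.5, rng.normal(2.0, 0.1))
        v = rng.normal(1.0, 0.1)
        t0 = max(0.1, rng.normal(0.3, 0.02))
        for ln, dcc in zip(lengths, contrasts):
            ddc = rng.normal(dcc / 2, 0.03)
            for direction, sgn in (("long", 1.0), ("short", -1.0)):
                for cat_sign, cat in ((1.0, "long"), (-1.0, "short")):
                    params = DDMParams(a=a, v=cat_sign * v, t0=t0, z=0.5,
                                       dc=sgn * ddc, sv=0.2)
                    ch, rt = simulate(params, 75, seed=rng)
                    frames.append(pd.DataFrame({
                        "subject_id": s, "bias_source": "muller_lyer",
                        "bias_direction": direction, "arrowhead_px": ln,
                        "true_category": cat, "task": "decision",
                        "choice": np.where(ch == 1, "long", "short"), "rt_s": rt,
                    }))
    trials = pd.concat(frames, ignore_index=True)
    spec = DDMModelSpec(z_by=("arrowhead_px", "bias_direction"),
                        dc_by=("arrowhead_px", "bias_direction"),
                        a_by=(), v_by=(), t0_by=())
    fit = fit_hierarchical(trials, spec,
                           MCMCConfig(n_chains=3, n_samples=1500, n_burn_in=500,
                                      thinning=2, seed=9))
    return {"fit": fit, "lengths": lengths, "contrasts": contrasts}


@pytest.fixture(scope="session")
def cbf_z_trials() -> pd.DataFrame:
    return make_ddm_trials(20, 1000, z_contrast=0.1, dc_contrast=0.0, seed=7)


@pytest.fixture(scope="session")
def cbf_dc_trials() -> pd.DataFrame:
    return make_ddm_trials(20, 1000, z_contrast=0.0, dc_contrast=0.4, seed=7)
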