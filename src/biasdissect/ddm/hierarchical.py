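"""Hierarchical Bayesian fitting of the drift-diffusion model.

The model uses stimulus coding: the upper boundary is the 'long' response
and the stimulus drift ``v`` is signed by the true category, so the bias
parameters — relative starting point ``z`` and drift criterion ``dc`` —
are directly interpretable.  By default ``z`` and ``dc`` vary over
bias_source x bias_direction cells, while ``a``, ``v`` and ``t0`` vary
over bias source only (fixed across directions), and a single
across-trial drift SD ``sv`` is shared at the group level and integrated
into the likelihood analytically.

Subject-level parameters are drawn from condition-cell normals on
transformed scales (log for a, logit for z, identity for v, dc, t0) with
weakly informative hyperpriors.  Sampling is Metropolis-within-Gibbs:
random-walk updates for subject parameters, conjugate draws for group
means, random-walk updates on log scale for group SDs and sv, with
proposal scales adapted during burn-in only.  Any sampler meeting the
recovery and convergence contracts would do; this one keeps the package
dependency-free and desk-scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ._wfpt import loglik_cell, simulate_kernel
from .core import gelman_rubin

__all__ = [
    "DDMModelSpec",
    "MCMCConfig",
    "Chains",
    "ConvergenceReport",
    "HierarchicalFit",
    "fit_hierarchical",
    "convergence_report",
    "posterior_predictive",
    "arrowhead_gradient",
]

FAMILIES = ("a", "v", "t0", "z", "dc")

_TRANSFORM = {
    "a": (np.log, np.exp),
    "z": (logit, expit),
}

# hyperpriors on the transformed scale: (mean-prior m0, mean-prior sd s0,
# half-normal scale for the group SD)
_PRIORS = {
    "a": (math.log(1.5), 1.0, 0.5),
    "v": (0.0, 3.0, 1.0),
    "t0": (0.3, 0.5, 0.3),
    "z": (0.0, 1.0, 0.5),
    "dc": (0.0, 2.0, 0.5),
}
_SV_PRIOR_SCALE = 0.5


def _to_internal(fam: str, value: float) -> float:
    fwd = _TRANSFORM.get(fam)
    return float(fwd[0](value)) if fwd else float(value)


def _to_natural(fam, value):
    fwd = _TRANSFORM.get(fam)
    return fwd[1](value) if fwd else value


@dataclass(frozen=True)
class DDMModelSpec:
    """Sharing map: which design factors each parameter may vary over."""

    z_by: tuple[str, ...] = ("bias_source", "bias_direction")
    dc_by: tuple[str, ...] = ("bias_source", "bias_direction")
    a_by: tuple[str, ...] = ("bias_source",)
    v_by: tuple[str, ...] = ("bias_source",)
    t0_by: tuple[str, ...] = ("bias_source",)
    estimate_sv: bool = True

    def factors_of(self, fam: str) -> tuple[str, ...]:
        return getattr(self, f"{fam}_by")

    @property
    def all_factors(self) -> list[str]:
        seen: list[str] = []
        for fam in FAMILIES:
            for f in self.factors_of(fam):
                if f not in seen:
                    seen.append(f)
        return seen


@dataclass(frozen=True)
class MCMCConfig:
    """Chain schedule; the study's fidelity schedule is 3 x 30,000 with
    9,000 burn-in and thinning 2 (10,500 retained per chain); the default
    here is a desk-scale reduction of the same arithmetic."""

    n_chains: int = 3
    n_samples: int = 4000
    n_burn_in: int = 1000
    thinning: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_burn_in >= self.n_samples:
            raise ValueError("n_burn_in must be < n_samples")
        if (self.n_samples - self.n_burn_in) % self.thinning:
            raise ValueError("(n_samples - n_burn_in) must be divisible by thinning")

    @property
    def retained_per_chain(self) -> int:
        return (self.n_samples - self.n_burn_in) // self.thinning


@dataclass
class Chains:
    """Posterior draws, (n_chains, n_retained) per parameter name."""

    params: dict[str, np.ndarray]
    group_names: list[str]
    config: MCMCConfig

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.params.values()}
        if len(shapes) > 1:
            raise ValueError("all parameters must have equal chain shapes")

    def flat(self, name: str) -> np.ndarray:
        return self.params[name].reshape(-1)

    def group(self) -> dict[str, np.ndarray]:
        return {k: self.params[k] for k in self.group_names}


@dataclass(frozen=True)
class ConvergenceReport:
    rhat: pd.Series
    ess: pd.Series
    threshold: float
    flagged: list[str]

    @property
    def max_rhat(self) -> float:
        return float(self.rhat.max())

    @property
    def converged(self) -> bool:
        return not self.flagged


def convergence_report(chains: Chains, threshold: float = 1.01) -> ConvergenceReport:
    """R-hat and effective sample size for every group-level parameter."""
    import arviz as az

    group = chains.group()
    rhat = gelman_rubin(group)
    ess = pd.Series({k: float(az.ess(np.asarray(v))) for k, v in group.items()})
    flagged = [k for k, r in rhat.items() if r >= threshold]
    return ConvergenceReport(rhat=rhat, ess=ess, threshold=threshold, flagged=flagged)


class _SubjectData:
    """Per-subject trial arrays grouped by joint design cell."""

    def __init__(self, frame: pd.DataFrame, factors: list[str], spec: DDMModelSpec):
        self.cells: list[tuple] = []
        self.rt: list[np.ndarray] = []
        self.upper: list[np.ndarray] = []
        self.sign: list[np.ndarray] = []
        for cell, g in frame.groupby(factors, dropna=False, sort=True):
            cell = cell if isinstance(cell, tuple) else (cell,)
            self.cells.append(cell)
            self.rt.append(g["rt_s"].to_numpy(float))
            self.upper.append((g["choice"] == "long").to_numpy(bool))
            self.sign.append(np.where(g["true_category"] == "long", 1.0, -1.0))
        self.n_cells = len(self.cells)
        # map each joint cell to the family-cell it belongs to
        self.fam_cells: dict[str, list[tuple]] = {}
        self.fam_idx: dict[str, np.ndarray] = {}
        for fam in FAMILIES:
            fac = spec.factors_of(fam)
            pos = [factors.index(f) for f in fac]
            labels = [tuple(cell[p] for p in pos) for cell in self.cells]
            uniq = sorted(set(labels), key=repr)
            self.fam_cells[fam] = uniq
            self.fam_idx[fam] = np.array([uniq.index(l) for l in labels])
        self.min_rt = {fam: {c: min(self.rt[j].min()
                                    for j in range(self.n_cells)
                                    if self.fam_idx[fam][j] == k)
                             for k, c in enumerate(self.fam_cells[fam])}
                       for fam in ("t0",)}


def _label(cell: tuple) -> str:
    return "|".join(f"{x:g}" if isinstance(x, float) else str(x) for x in cell)


@dataclass
class HierarchicalFit:
    """Fit result: chains plus the bookkeeping needed for contrasts and PPC."""

    chains: Chains
    spec: DDMModelSpec
    config: MCMCConfig
    subject_ids: list
    factors: list[str]
    fam_cells: dict[str, list[tuple]]
    priors: dict = field(default_factory=dict)

    def group_mean_draws(self, fam: str, cell: tuple, natural: bool = True) -> np.ndarray:
        name = f"mu_{fam}[{_label(cell)}]"
        draws = self.chains.flat(name)
        return _to_natural(fam, draws) if natural else draws

    def contrast(self, fam: str, cell_a: tuple, cell_b: tuple,
                 natural: bool = True) -> np.ndarray:
        """Draws of the group-level difference (cell_a - cell_b)."""
        return (self.group_mean_draws(fam, cell_a, natural)
                - self.group_mean_draws(fam, cell_b, natural))

    def direction_contrast(self, fam: str, **fixed) -> np.ndarray:
        """Long-minus-short group contrast of a bias parameter.

        ``fixed`` pins the remaining factors of the family's sharing map
        (e.g. ``bias_source='payoff'`` or ``arrowhead_px=40``).
        """
        fac = self.spec.factors_of(fam)
        if "bias_direction" not in fac:
            raise ValueError(f"{fam} does not vary by bias_direction in this spec")
        def build(direction):
            vals = []
            for f in fac:
                vals.append(direction if f == "bias_direction" else fixed[f])
            return tuple(vals)
        return self.contrast(fam, build("long"), build("short"))


def _init_value(fam: str, rng: np.random.Generator, min_rt: float | None) -> float:
    if fam == "a":
        return math.log(2.0) + rng.normal(0, 0.15)
    if fam == "v":
        return 1.0 + rng.normal(0, 0.2)
    if fam == "t0":
        lo, hi = 0.05 * min_rt, 0.9 * min_rt
        return float(np.clip(0.5 * min_rt + rng.normal(0, 0.05), lo, hi))
    if fam == "z":
        return rng.normal(0, 0.2)
    return rng.normal(0, 0.1)  # dc


def fit_hierarchical(trials: pd.DataFrame, spec: DDMModelSpec = DDMModelSpec(),
                     mcmc: MCMCConfig = MCMCConfig(), err: float = 1e-9,
                     progress: bool = False) -> HierarchicalFit:
    """Sample the posterior of the hierarchical DDM from decision trials.

    ``trials`` must be contaminant-filtered decision trials with RTs for
    at least two subjects.  Raises ``ValueError`` on non-finite initial
    likelihoods (reporting the offending subject) rather than sampling
    from a broken state; convergence should be checked afterwards with
    :func:`convergence_report`.
    """
    dec = trials[(trials["task"] == "decision") & trials["rt_s"].notna()]
    if dec["subject_id"].nunique() < 2:
        raise ValueError("hierarchical fit needs >= 2 subjects")
    factors = [f for f in spec.all_factors if f in dec.columns]
    subject_ids = sorted(dec["subject_id"].unique())
    subjects = [_SubjectData(dec[dec["subject_id"] == sid], factors, spec)
                for sid in subject_ids]

    # global family cells = union over subjects
    fam_cells: dict[str, list[tuple]] = {}
    for fam in FAMILIES:
        cells: list[tuple] = []
        for sub in subjects:
            for c in sub.fam_cells[fam]:
                if c not in cells:
                    cells.append(c)
        fam_cells[fam] = sorted(cells, key=repr)

    n_sub = len(subjects)
    kept = mcmc.retained_per_chain
    group_names = [f"mu_{fam}[{_label(c)}]" for fam in FAMILIES for c in fam_cells[fam]]
    group_names += [f"sigma_{fam}[{_label(c)}]" for fam in FAMILIES for c in fam_cells[fam]]
    if spec.estimate_sv:
        group_names.append("sv")
    subj_names = [f"{fam}[{sid}|{_label(c)}]"
                  for fam in FAMILIES for s, sid in enumerate(subject_ids)
                  for c in subjects[s].fam_cells[fam]]
    store = {name: np.empty((mcmc.n_chains, kept)) for name in group_names + subj_names}

    root = np.random.SeedSequence(mcmc.seed)
    for chain, seq in enumerate(root.spawn(mcmc.n_chains)):
        rng = np.random.default_rng(seq)
        _run_chain(chain, rng, subjects, subject_ids, fam_cells, spec, mcmc,
                   err, store, progress)

    chains = Chains(params=store, group_names=group_names, config=mcmc)
    priors = {"hyper": _PRIORS, "sv_half_normal_scale": _SV_PRIOR_SCALE,
              "transforms": {"a": "log", "z": "logit"}}
    return HierarchicalFit(chains=chains, spec=spec, config=mcmc,
                           subject_ids=list(subject_ids), factors=factors,
                           fam_cells=fam_cells, priors=priors)


def _run_chain(chain: int, rng: np.random.Generator, subjects, subject_ids,
               fam_cells, spec: DDMModelSpec, mcmc: MCMCConfig, err: float,
               store: dict, progress: bool) -> None:
    n_sub = len(subjects)

    # subject-level parameter state (internal scale), per family: list over
    # subjects of arrays over that subject's family cells
    theta = {fam: [np.array([_init_value(fam, rng,
                                         sub.min_rt["t0"].get(c) if fam == "t0" else None)
                             for c in sub.fam_cells[fam]])
                   for sub in subjects]
             for fam in FAMILIES}
    mu = {fam: {} for fam in FAMILIES}
    sig = {fam: {} for fam in FAMILIES}
    for fam in FAMILIES:
        for c in fam_cells[fam]:
            vals = [theta[fam][s][sub.fam_cells[fam].index(c)]
                    for s, sub in enumerate(subjects) if c in sub.fam_cells[fam]]
            mu[fam][c] = float(np.mean(vals)) + rng.normal(0, 0.05)
            sig[fam][c] = 0.2 * math.exp(rng.normal(0, 0.2))
    sv = 0.15 * math.exp(rng.normal(0, 0.3)) if spec.estimate_sv else 0.0

    def natural(fam, s, k):
        return _to_natural(fam, theta[fam][s][k])

    def cell_loglik(s, j):
        sub = subjects[s]
        idx = {fam: sub.fam_idx[fam][j] for fam in FAMILIES}
        return loglik_cell(
            sub.rt[j], sub.upper[j], sub.sign[j],
            natural("a", s, idx["a"]), natural("v", s, idx["v"]),
            natural("t0", s, idx["t0"]), natural("z", s, idx["z"]),
            natural("dc", s, idx["dc"]), sv, err)

    loglik = [np.array([cell_loglik(s, j) for j in range(sub.n_cells)])
              for s, sub in enumerate(subjects)]
    for s, ll in enumerate(loglik):
        if not np.all(ll > -1e250):
            raise ValueError(f"non-finite initial likelihood for subject {subject_ids[s]}")

    # adaptive proposal scales
    prop = {(fam, s, k): (0.05 if fam == "t0" else 0.3)
            for fam in FAMILIES for s in range(n_sub)
            for k in range(len(subjects[s].fam_cells[fam]))}
    prop_sig = {(fam, repr(c)): 0.3 for fam in FAMILIES for c in fam_cells[fam]}
    prop_sig_nc = {(fam, repr(c), "nc"): 0.3 for fam in FAMILIES for c in fam_cells[fam]}
    prop_mu_tr = {(fam, repr(c), "tr"): (0.02 if fam == "t0" else 0.1)
                  for fam in FAMILIES for c in fam_cells[fam]}
    prop_sv = 0.2
    acc = {key: [0, 0]
           for key in list(prop) + list(prop_sig) + list(prop_sig_nc)
           + list(prop_mu_tr) + ["sv"]}

    def adapt(key, scale_map, mapkey):
        a, n = acc[key]
        if n >= 25:
            rate = a / n
            scale_map[mapkey] = float(np.clip(
                scale_map[mapkey] * math.exp(1.2 * (rate - 0.44)), 1e-3, 10.0))
            acc[key] = [0, 0]

    kept_i = 0
    b, t = mcmc.n_burn_in, mcmc.thinning
    for it in range(mcmc.n_samples):
        in_burn = it < b
        for s, sub in enumerate(subjects):
            for fam in FAMILIES:
                for k, c in enumerate(sub.fam_cells[fam]):
                    key = (fam, s, k)
                    old = theta[fam][s][k]
                    new = old + rng.normal(0, prop[key])
                    theta[fam][s][k] = new
                    js = np.nonzero(sub.fam_idx[fam] == k)[0]
                    new_ll = np.array([cell_loglik(s, j) for j in js])
                    m, sd = mu[fam][c], sig[fam][c]
                    dprior = (-(new - m) ** 2 + (old - m) ** 2) / (2 * sd * sd)
                    dll = new_ll.sum() - loglik[s][js].sum()
                    if math.log(rng.random() + 1e-320) < dll + dprior:
                        loglik[s][js] = new_ll
                        acc[key][0] += 1
                    else:
                        theta[fam][s][k] = old
                    acc[key][1] += 1
                    if in_burn:
                        adapt(key, prop, key)

        if spec.estimate_sv:
            old_sv, old_ll = sv, loglik
            sv_new = sv * math.exp(rng.normal(0, prop_sv))
            sv = sv_new
            new_ll = [np.array([cell_loglik(s, j) for j in range(sub.n_cells)])
                      for s, sub in enumerate(subjects)]
            dll = (sum(x.sum() for x in new_ll) - sum(x.sum() for x in old_ll))
            dprior = (-(sv_new ** 2) + old_sv ** 2) / (2 * _SV_PRIOR_SCALE ** 2)
            djac = math.log(sv_new) - math.log(old_sv)
            if math.log(rng.random() + 1e-320) < dll + dprior + djac:
                loglik = new_ll
                acc["sv"][0] += 1
            else:
                sv = old_sv
            acc["sv"][1] += 1
            if in_burn:
                a_, n_ = acc["sv"]
                if n_ >= 25:
                    prop_sv = float(np.clip(prop_sv * math.exp(1.2 * (a_ / n_ - 0.44)),
                                            1e-3, 10.0))
                    acc["sv"] = [0, 0]

        for fam in FAMILIES:
            m0, s0, hn = _PRIORS[fam]
            for c in fam_cells[fam]:
                vals = np.array([theta[fam][s][sub.fam_cells[fam].index(c)]
                                 for s, sub in enumerate(subjects)
                                 if c in sub.fam_cells[fam]])
                sd = sig[fam][c]
                prec = len(vals) / sd ** 2 + 1.0 / s0 ** 2
                mean = (vals.sum() / sd ** 2 + m0 / s0 ** 2) / prec
                mu[fam][c] = float(mean + rng.normal(0, 1.0 / math.sqrt(prec)))

                key = (fam, repr(c))
                old = sig[fam][c]
                new = old * math.exp(rng.normal(0, prop_sig[key]))
                def sig_logp(s_val):
                    return (-len(vals) * math.log(s_val)
                            - ((vals - mu[fam][c]) ** 2).sum() / (2 * s_val ** 2)
                            - s_val ** 2 / (2 * hn ** 2) + math.log(s_val))
                if math.log(rng.random() + 1e-320) < sig_logp(new) - sig_logp(old):
                    sig[fam][c] = new
                    acc[key][0] += 1
                acc[key][1] += 1
                if in_burn:
                    adapt(key, prop_sig, key)

                # interweaved non-centered move: rescale subject deviations
                # around the group mean together with sigma, holding the
                # standardized deviations fixed — this decouples sigma from
                # the subject parameters when partial pooling is strong
                # joint translation move: shift the group mean and every
                # subject value together (within-group deviations fixed)
                tkey = (fam, repr(c), "tr")
                delta = rng.normal(0, prop_mu_tr[tkey])
                old_mu = mu[fam][c]
                touched = []
                dll = 0.0
                for s, sub in enumerate(subjects):
                    if c not in sub.fam_cells[fam]:
                        continue
                    k = sub.fam_cells[fam].index(c)
                    theta[fam][s][k] += delta
                    js = np.nonzero(sub.fam_idx[fam] == k)[0]
                    new_ll = np.array([cell_loglik(s, j) for j in js])
                    touched.append((s, k, js, new_ll))
                    dll += new_ll.sum() - loglik[s][js].sum()
                dprior = (-(old_mu + delta - m0) ** 2 + (old_mu - m0) ** 2) / (2 * s0 ** 2)
                if math.log(rng.random() + 1e-320) < dll + dprior:
                    mu[fam][c] = old_mu + delta
                    for s, k, js, new_ll in touched:
                        loglik[s][js] = new_ll
                    acc[tkey][0] += 1
                else:
                    for s, k, js, _ in touched:
                        theta[fam][s][k] -= delta
                acc[tkey][1] += 1
                if in_burn:
                    adapt(tkey, prop_mu_tr, tkey)

                nkey = (fam, repr(c), "nc")
                for _ in range(2):  # the slow-mixing direction: take two steps
                    old = sig[fam][c]
                    new = old * math.exp(rng.normal(0, prop_sig_nc[nkey]))
                    rho = new / old
                    m = mu[fam][c]
                    touched = []  # (s, k, old_theta, js, new_ll)
                    dll = 0.0
                    for s, sub in enumerate(subjects):
                        if c not in sub.fam_cells[fam]:
                            continue
                        k = sub.fam_cells[fam].index(c)
                        old_th = theta[fam][s][k]
                        theta[fam][s][k] = m + (old_th - m) * rho
                        js = np.nonzero(sub.fam_idx[fam] == k)[0]
                        new_ll = np.array([cell_loglik(s, j) for j in js])
                        touched.append((s, k, old_th, js, new_ll))
                        dll += new_ll.sum() - loglik[s][js].sum()
                    dprior = (-(new ** 2) + old ** 2) / (2 * hn ** 2)
                    djac = math.log(new) - math.log(old)
                    if math.log(rng.random() + 1e-320) < dll + dprior + djac:
                        sig[fam][c] = new
                        for s, k, _, js, new_ll in touched:
                            loglik[s][js] = new_ll
                        acc[nkey][0] += 1
                    else:
                        for s, k, old_th, _, _ in touched:
                            theta[fam][s][k] = old_th
                    acc[nkey][1] += 1
                    if in_burn:
                        adapt(nkey, prop_sig_nc, nkey)

        if not in_burn and (it - b) % t == t - 1:
            for fam in FAMILIES:
                for c in fam_cells[fam]:
                    store[f"mu_{fam}[{_label(c)}]"][chain, kept_i] = mu[fam][c]
                    store[f"sigma_{fam}[{_label(c)}]"][chain, kept_i] = sig[fam][c]
            if spec.estimate_sv:
                store["sv"][chain, kept_i] = sv
            for fam in FAMILIES:
                for s, sid in enumerate(subject_ids):
                    for k, c in enumerate(subjects[s].fam_cells[fam]):
                        store[f"{fam}[{sid}|{_label(c)}]"][chain, kept_i] = \
                            _to_natural(fam, theta[fam][s][k])
            kept_i += 1
        if progress and (it + 1) % 500 == 0:
            print(f"chain {chain}: {it + 1}/{mcmc.n_samples}")


def posterior_predictive(fit: HierarchicalFit, trials: pd.DataFrame,
                         n_sims: int = 500, seed=0, dt: float = 1e-3) -> pd.DataFrame:
    """Observed vs model-predicted choice proportions and RT quantiles.

    For each subject, ``n_sims`` parameter vectors are drawn from the
    posterior and the subject's trial set is re-simulated under each;
    the table reports, per subject x design cell, the observed statistic
    and the predictive mean and central 95% interval.  Deterministic
    given ``seed``.
    """
    rng = np.random.default_rng(seed)
    dec = trials[(trials["task"] == "decision") & trials["rt_s"].notna()]
    qs = (0.1, 0.3, 0.5, 0.7, 0.9)
    rows = []
    n_total = fit.config.n_chains * fit.config.retained_per_chain
    for sid in fit.subject_ids:
        sub = dec[dec["subject_id"] == sid]
        draw_idx = rng.integers(0, n_total, size=n_sims)
        for cell, g in sub.groupby(fit.factors, dropna=False, sort=True):
            cell = cell if isinstance(cell, tuple) else (cell,)
            n_long = int((g["true_category"] == "long").sum())
            n_short = len(g) - n_long
            obs_rt = g["rt_s"].to_numpy()
            obs_stats = {"p_long": float((g["choice"] == "long").mean())}
            obs_stats |= {f"rt_q{int(q * 100)}": float(np.quantile(obs_rt, q)) for q in qs}

            def cell_param(fam):
                fac = fit.spec.factors_of(fam)
                sub_cell = tuple(cell[fit.factors.index(f)] for f in fac)
                return fit.chains.flat(f"{fam}[{sid}|{_label(sub_cell)}]")

            par = {fam: cell_param(fam) for fam in FAMILIES}
            sv_draws = (fit.chains.flat("sv") if fit.spec.estimate_sv
                        else np.zeros(n_total))
            sim_stats = {k: np.empty(n_sims) for k in obs_stats}
            for i, di in enumerate(draw_idx):
                a, v, t0 = par["a"][di], par["v"][di], par["t0"][di]
                z, dc, sv_i = par["z"][di], par["dc"][di], sv_draws[di]
                ch_parts, rt_parts = [], []
                for sign, n_s in ((1.0, n_long), (-1.0, n_short)):
                    if n_s == 0:
                        continue
                    ch, rt, _ = simulate_kernel(n_s, a, sign * v, t0, z, dc, sv_i,
                                                dt, 20.0, int(rng.integers(2**31 - 1)))
                    ch_parts.append(ch)
                    rt_parts.append(rt)
                ch = np.concatenate(ch_parts)
                rt = np.concatenate(rt_parts)
                sim_stats["p_long"][i] = ch.mean()
                for q in qs:
                    sim_stats[f"rt_q{int(q * 100)}"][i] = np.quantile(rt, q)
            for stat, obs in obs_stats.items():
                sims = sim_stats[stat]
                rows.append({"subject_id": sid, "cell": _label(cell), "stat": stat,
                             "observed": obs, "predicted_mean": float(sims.mean()),
                             "predicted_lo": float(np.quantile(sims, 0.025)),
                             "predicted_hi": float(np.quantile(sims, 0.975))})
    return pd.DataFrame(rows)


def arrowhead_gradient(fit: HierarchicalFit) -> pd.DataFrame:
    """Long-minus-short group contrasts of dc and z at each arrowhead length.

    Requires a fit whose z and dc sharing maps include ``arrowhead_px``
    and ``bias_direction``.  Returns one row per parameter x arrowhead
    length with the posterior mean, central 95% interval, and P(>0).
    """
    rows = []
    for fam in ("dc", "z"):
        fac = fit.spec.factors_of(fam)
        if "arrowhead_px" not in fac or "bias_direction" not in fac:
            raise ValueError(f"{fam} must vary by arrowhead_px and bias_direction")
        arrow_pos = fac.index("arrowhead_px")
        lengths = sorted({c[arrow_pos] for c in fit.fam_cells[fam]})
        if len(lengths) < 2:
            raise ValueError("need at least two arrowhead length levels")
        other = [f for f in fac if f not in ("arrowhead_px", "bias_direction")]
        for ln in lengths:
            fixed = {"arrowhead_px": ln}
            for f in other:
                vals = {c[fac.index(f)] for c in fit.fam_cells[fam]}
                if len(vals) != 1:
                    raise ValueError(f"ambiguous level for factor {f}")
                fixed[f] = next(iter(vals))
            draws = fit.direction_contrast(fam, **fixed)
            rows.append({"param": fam, "arrowhead_px": ln,
                         "mean": float(draws.mean()),
                         "lo": float(np.quantile(draws, 0.025)),
                         "hi": float(np.quantile(draws, 0.975)),
                         "p_positive": float((draws > 0).mean())})
    return pd.DataFrame(rows)
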