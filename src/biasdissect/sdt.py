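"""Signal detection statistics, reproduction errors, and conditional bias functions.

Conventions follow the study paradigm: correct 'long' responses are hits
and correct 'short' responses correct rejections, so

    d' = Z(HR) - Z(FAR)        c = (Z(HR) + Z(FAR)) / 2

with ``Z`` the standard-normal quantile.  Note the criterion is printed
*without* the conventional minus sign: higher c means a stronger bias
toward answering 'long' (the negative of the textbook convention).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "SDTSummary",
    "EffectSummary",
    "compute_rates",
    "sdt_summary",
    "reproduction_error",
    "long_minus_short",
    "exclusion_filter",
    "conditional_bias_function",
    "rank_correlation",
]

CELL_KEYS = ["bias_source", "bias_direction", "arrowhead_px"]


@dataclass(frozen=True)
class SDTSummary:
    d_prime: float
    criterion: float


def _cell_groups(trials: pd.DataFrame, extra: list[str] | None = None):
    keys = ["subject_id"] + [k for k in CELL_KEYS if k in trials.columns]
    if extra:
        keys += extra
    return trials.groupby(keys, dropna=False, sort=True), keys


def _rates_from_counts(n_long: int, hits: int, n_short: int, fas: int) -> tuple[float, float]:
    """HR/FAR with a log-linear correction applied only when a rate is degenerate."""
    hr = hits / n_long
    far = fas / n_short
    if hr in (0.0, 1.0) or far in (0.0, 1.0):
        hr = (hits + 0.5) / (n_long + 1.0)
        far = (fas + 0.5) / (n_short + 1.0)
    return hr, far


def compute_rates(trials: pd.DataFrame, extra_keys: list[str] | None = None) -> pd.DataFrame:
    """Hit and false-alarm rates per subject x condition cell.

    HR = P(respond 'long' | long target), FAR = P(respond 'long' | short
    target).  Cells lacking either signal class raise ``ValueError``.
    """
    dec = trials[trials["task"] == "decision"]
    if dec.empty:
        raise ValueError("no decision trials")
    groups, keys = _cell_groups(dec, extra_keys)
    rows = []
    for name, g in groups:
        is_long = g["true_category"] == "long"
        n_long = int(is_long.sum())
        n_short = int((~is_long).sum())
        if n_long == 0 or n_short == 0:
            raise ValueError(f"cell {name} has no {'long' if n_long == 0 else 'short'}-signal trials")
        hits = int((g.loc[is_long, "choice"] == "long").sum())
        fas = int((g.loc[~is_long, "choice"] == "long").sum())
        hr, far = _rates_from_counts(n_long, hits, n_short, fas)
        rows.append(dict(zip(keys, name if isinstance(name, tuple) else (name,)))
                    | {"n_long_signal": n_long, "n_short_signal": n_short,
                       "hit_rate": hr, "false_alarm_rate": far})
    return pd.DataFrame(rows)


def sdt_summary(hit_rate, false_alarm_rate) -> SDTSummary:
    """d' and criterion from interior hit/false-alarm rates."""
    hr = float(hit_rate)
    far = float(false_alarm_rate)
    if not (0.0 < hr < 1.0 and 0.0 < far < 1.0):
        raise ValueError("rates must be interior; apply the degenerate-rate correction first")
    zhr, zfar = norm.ppf(hr), norm.ppf(far)
    return SDTSummary(d_prime=zhr - zfar, criterion=0.5 * (zhr + zfar))


def sdt_table(trials: pd.DataFrame, extra_keys: list[str] | None = None) -> pd.DataFrame:
    """Per subject x cell rate table with d' and criterion columns appended."""
    rates = compute_rates(trials, extra_keys)
    summ = [sdt_summary(h, f) for h, f in zip(rates["hit_rate"], rates["false_alarm_rate"])]
    rates["d_prime"] = [s.d_prime for s in summ]
    rates["criterion"] = [s.criterion for s in summ]
    return rates


def reproduction_error(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean (reproduction - target) in pixels per subject x condition cell."""
    rep = trials[trials["task"] == "reproduction"]
    if rep.empty:
        raise ValueError("no reproduction trials")
    groups, keys = _cell_groups(rep)
    rows = []
    for name, g in groups:
        err = (g["reproduction_px"] - g["target_px"]).mean()
        rows.append(dict(zip(keys, name if isinstance(name, tuple) else (name,)))
                    | {"n_trials": len(g), "reproduction_error_px": float(err)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EffectSummary:
    """Per-subject long-minus-short differences and their group summary."""

    differences: pd.Series  # indexed by subject_id
    mean: float
    sd: float
    cohens_d: float | None  # None when the paired SD is zero

    @property
    def n(self) -> int:
        return len(self.differences)


def long_minus_short(per_subject: pd.DataFrame, value: str) -> EffectSummary:
    """Paired long-minus-short effect over subjects for one measure column.

    ``per_subject`` must carry one row per subject x bias_direction (as
    produced by :func:`sdt_table` or :func:`reproduction_error`); subjects
    missing a direction are dropped with a warning.  Cohen's d is the
    paired mean/SD of the differences, flagged ``None`` if the SD is zero.
    """
    wide = per_subject.pivot_table(index="subject_id", columns="bias_direction",
                                   values=value, aggfunc="mean")
    for col in ("long", "short"):
        if col not in wide.columns:
            raise ValueError(f"no '{col}' direction rows present")
    incomplete = wide["long"].isna() | wide["short"].isna()
    if incomplete.any():
        logger.warning("dropping %d subject(s) missing a bias direction: %s",
                       incomplete.sum(), list(wide.index[incomplete]))
        wide = wide[~incomplete]
    diffs = wide["long"] - wide["short"]
    sd = float(diffs.std(ddof=1)) if len(diffs) > 1 else 0.0
    d = float(diffs.mean()) / sd if sd > 0 else None
    return EffectSummary(differences=diffs, mean=float(diffs.mean()), sd=sd, cohens_d=d)


def exclusion_filter(subject_summaries: pd.DataFrame,
                     sd_columns: tuple[str, ...] = ("staircase_threshold", "criterion",
                                                    "d_prime", "reproduction_error_px"),
                     n_sd: float = 4.0) -> tuple[pd.DataFrame, list[dict]]:
    """Apply the participant exclusion rules.

    First removes subjects at or below chance (d' <= 0), then subjects for
    whom any listed quantity falls more than ``n_sd`` standard deviations
    from the sample mean (computed on the chance-filtered sample).
    Returns the retained rows and a log with one record per exclusion.
    """
    df = subject_summaries.copy()
    log: list[dict] = []

    chance = df["d_prime"] <= 0
    for sid in df.loc[chance, "subject_id"]:
        log.append({"subject_id": sid, "reason": "d_prime <= 0 (chance performance)"})
    df = df[~chance]

    outlier = pd.Series(False, index=df.index)
    for col in sd_columns:
        if col not in df.columns:
            continue
        vals = df[col].astype(float)
        mu, sd = vals.mean(), vals.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            continue
        flag = (vals - mu).abs() > n_sd * sd
        for sid in df.loc[flag, "subject_id"]:
            log.append({"subject_id": sid,
                        "reason": f"{col} beyond {n_sd:g} SD of sample mean"})
        outlier |= flag
    return df[~outlier], log


def _quintile_bins(rt: np.ndarray, n_bins: int = 5) -> np.ndarray:
    """Bin indices by type-7 empirical quantiles; boundary ties go to the lower bin."""
    probs = np.arange(1, n_bins) / n_bins
    edges = np.quantile(rt, probs)  # numpy default is the type-7 estimator
    return np.searchsorted(edges, rt, side="left")


def conditional_bias_function(trials: pd.DataFrame, n_bins: int = 5,
                              min_trials: int = 25) -> pd.DataFrame:
    """SDT criterion within per-subject RT quantile bins, averaged over subjects.

    Quintile boundaries are computed per subject x condition cell *before*
    averaging; each bin's criterion comes from that bin's own hit and
    false-alarm rates.  Returns one row per condition cell x bin with the
    across-subject mean criterion and its dispersion.
    """
    dec = trials[(trials["task"] == "decision") & trials["rt_s"].notna()]
    if dec.empty:
        raise ValueError("no decision trials with RTs")
    groups, keys = _cell_groups(dec)
    rows = []
    for name, g in groups:
        if len(g) < min_trials:
            raise ValueError(f"cell {name} has {len(g)} trials; need >= {min_trials}")
        bins = _quintile_bins(g["rt_s"].to_numpy(), n_bins)
        for b in range(n_bins):
            gb = g[bins == b]
            is_long = gb["true_category"] == "long"
            n_long, n_short = int(is_long.sum()), int((~is_long).sum())
            if n_long == 0 or n_short == 0:
                raise ValueError(f"cell {name} bin {b} lacks a signal class; too few trials")
            hits = int((gb.loc[is_long, "choice"] == "long").sum())
            fas = int((gb.loc[~is_long, "choice"] == "long").sum())
            hr, far = _rates_from_counts(n_long, hits, n_short, fas)
            rows.append(dict(zip(keys, name if isinstance(name, tuple) else (name,)))
                        | {"bin": b + 1, "criterion": sdt_summary(hr, far).criterion})
    per_subject = pd.DataFrame(rows)
    cell_cols = [k for k in CELL_KEYS if k in per_subject.columns]
    out = (per_subject.groupby(cell_cols + ["bin"], dropna=False)["criterion"]
           .agg(mean_criterion="mean", sd_criterion="std", n_subjects="count")
           .reset_index())
    return out


def rank_correlation(x, y, method: str = "spearman") -> float:
    """Rank (Spearman) correlation between paired observations.

    ``method='pearson'`` is available for sensitivity checks.  Constant
    inputs raise ``ValueError`` (the coefficient is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for constant input")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if method == "spearman":
            rho = stats.spearmanr(x, y).statistic
        elif method == "pearson":
            rho = stats.pearsonr(x, y).statistic
        else:
            raise ValueError(f"unknown method {method!r}")
    return float(rho)
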