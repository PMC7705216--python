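"""Reliability and accuracy statistics, and the MEI-vs-URD simulation study.

Agreement between paired CLS measurements (test vs retest, or adaptive vs
fixed-level reference) is summarized by Bland-Altman bias and 95% limits of
agreement, Cronbach's alpha with the conventional interpretation bands, and
root-mean-square error.  The Monte-Carlo study tracks, for a roster of
simulated listeners, how posterior entropy and the error of the running
maximum-likelihood CLS estimate evolve trial by trial under MEI versus
uniform-random (URD) level selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import bayes_mei, tracking
from .bayes_mei import LikelihoodTable, SelectionConstraints
from .catalog import Catalog
from .listener_sim import SimulatedListener, sample_listeners
from .tracking import SessionLog

__all__ = [
    "PairedMeasurements",
    "SimStudyConfig",
    "bland_altman",
    "cronbach_alpha",
    "alpha_label",
    "rmse",
    "run_simulation_study",
    "posterior_trajectory",
]


@dataclass(frozen=True)
class PairedMeasurements:
    """Two aligned vectors of levels (dB SPL); incomplete pairs are dropped."""

    a: np.ndarray
    b: np.ndarray
    label_a: str = "a"
    label_b: str = "b"

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("paired measurements must be equal-length 1-d vectors")
        keep = ~(np.isnan(a) | np.isnan(b))
        object.__setattr__(self, "a", a[keep])
        object.__setattr__(self, "b", b[keep])
        if len(self.a) < 3:
            raise ValueError("need at least 3 complete pairs")


def bland_altman(pm: PairedMeasurements) -> dict[str, float]:
    """Bias and 95% limits of agreement for paired measurements.

    Differences d = a - b; bias is their mean, the limits of agreement are
    bias +/- 1.96 SD(d), and the bias CI is bias +/- 1.96 SD(d)/sqrt(n).
    Normality of d is screened with a Kolmogorov-Smirnov test against a normal
    with the estimated mean and SD (a Lilliefors-style usage: the p-value is a
    screen, not an exact test); a non-normal result is the conventional cue to
    quote mean +/- 2 SD instead.
    """
    d = pm.a - pm.b
    n = len(d)
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    half = 1.96 * sd
    if sd > 0:
        ks = stats.kstest(d, "norm", args=(bias, sd))
        normality_p = float(ks.pvalue)
    else:
        normality_p = 1.0
    return {
        "bias": bias,
        "loa_low": bias - half,
        "loa_high": bias + half,
        "bias_ci_low": bias - half / np.sqrt(n),
        "bias_ci_high": bias + half / np.sqrt(n),
        "sd": sd,
        "n": n,
        "normality_p": normality_p,
    }


_ALPHA_BANDS = [
    (0.9, "excellent"),
    (0.8, "good"),
    (0.7, "acceptable"),
    (0.6, "questionable"),
    (0.5, "poor"),
]


def alpha_label(alpha: float) -> str:
    """Conventional interpretation band for a Cronbach's alpha value."""
    for cut, label in _ALPHA_BANDS:
        if alpha >= cut:
            return label
    return "unacceptable"


def cronbach_alpha(items: Sequence[np.ndarray]) -> tuple[float, str]:
    """Cronbach's alpha over k aligned item vectors, with its band label.

    alpha = k/(k-1) * (1 - sum_i var(item_i) / var(sum of items)), using
    sample (ddof=1) variances over the cases complete on every item.
    """
    mat = np.asarray([np.asarray(x, dtype=float) for x in items])
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("need at least 2 aligned items")
    mat = mat[:, ~np.isnan(mat).any(axis=0)]
    k, n = mat.shape
    if n < 3:
        raise ValueError("need at least 3 complete cases")
    total_var = mat.sum(axis=0).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total variance; alpha undefined")
    alpha = k / (k - 1) * (1.0 - mat.var(axis=1, ddof=1).sum() / total_var)
    return float(alpha), alpha_label(float(alpha))


def rmse(pm: PairedMeasurements) -> float:
    """Root-mean-square difference between the paired vectors, in dB."""
    return float(np.sqrt(np.mean((pm.a - pm.b) ** 2)))


@dataclass(frozen=True)
class SimStudyConfig:
    """Settings for the Monte-Carlo tracker comparison."""

    n_listeners: int = 200
    trials_per_track: int = tracking.N_RUNS * tracking.TRIALS_PER_RUN
    trackers: tuple[str, ...] = ("mei", "urd")
    seed: int = 0
    listener_mode: str = "from_catalog"
    response_mode: str = "stochastic"
    perturb_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.n_listeners < 1:
            raise ValueError("need at least one listener")
        bad = set(self.trackers) - {"mei", "urd"}
        if bad:
            raise ValueError(f"unknown trackers {sorted(bad)}")


def posterior_trajectory(
    log: SessionLog, catalog: Catalog, true_mcpf=None
) -> pd.DataFrame:
    """Per-trial posterior entropy and running ML-fit error for a session.

    Replays the trial sequence through the Bayes update; after each trial the
    running maximum-likelihood entry (argmax of the cumulative floored
    log-likelihood) defines the current CLS estimate.  When the listener's
    ``true_mcpf`` is given, ``rmse_db`` is the root-mean-square difference
    between the estimated and true per-CU levels over CU 5-45.
    """
    table = LikelihoodTable(catalog)
    state = bayes_mei.init_posterior(catalog)
    loglik = np.zeros(len(catalog))
    bl = catalog.boundary_level_matrix()[:, :9]  # boundaries for CU 5..45
    true_bl = None
    if true_mcpf is not None:
        true_bl = np.asarray(true_mcpf.boundary_levels)[:9]
    rows = []
    for t in log.trials:
        cat_idx = t.response_cu // 5
        state = bayes_mei.update_posterior(state, catalog, (t.level, t.response_cu), table)
        loglik += np.log(table.floored(t.level)[:, cat_idx])
        best = int(np.argmax(loglik))
        err = np.nan
        if true_bl is not None:
            err = float(np.sqrt(np.mean((bl[best] - true_bl) ** 2)))
        rows.append(
            {
                "trial": t.index + 1,
                "entropy_bits": bayes_mei.entropy(state),
                "ml_entry": catalog[best].entry_id,
                "rmse_db": err,
            }
        )
    return pd.DataFrame(rows)


def _track_once(
    tracker: str,
    listener: SimulatedListener,
    catalog: Catalog,
    seed: int,
) -> SessionLog:
    dr = None
    for _ in range(5):  # a stochastic listener can give a degenerate pre-phase
        try:
            dr = tracking.estimate_dynamic_range(listener)
            break
        except ValueError:
            continue
    if dr is None:
        dr = tracking.DynamicRange(0.0, 110.0)
    if tracker == "mei":
        return tracking.run_mei_adaptive(
            listener, catalog, dr, SelectionConstraints(), seed=seed
        )
    return tracking.run_urd(listener, dr, seed)


def run_simulation_study(
    cfg: SimStudyConfig, catalog: Catalog
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Monte-Carlo comparison of trackers on simulated listeners.

    For every listener and tracker a full session is run (dynamic-range
    pre-phase included); entropy and running ML-estimate error are recorded
    after each trial and averaged across listeners.  Returns ``(curves,
    summary)``: per-trial mean curves and a final-trial summary table.  The
    error metric is the rmse between estimated and true per-CU levels over
    CU 5-45 (missing categories cannot occur for the ML estimator, which
    always yields a complete function).  Fully deterministic given the seed.
    """
    listeners = sample_listeners(
        catalog,
        cfg.n_listeners,
        seed=cfg.seed,
        mode=cfg.listener_mode,
        response_mode=cfg.response_mode,
        perturb_sd=cfg.perturb_sd,
    )
    rng = np.random.default_rng(cfg.seed + 1)
    n_trials = cfg.trials_per_track
    records = []
    for li, listener in enumerate(listeners):
        for tracker in cfg.trackers:
            listener.reset()
            log = _track_once(tracker, listener, catalog, int(rng.integers(2**31)))
            traj = posterior_trajectory(log, catalog, listener.true_mcpf)
            traj = traj.iloc[:n_trials]
            for _, r in traj.iterrows():
                records.append(
                    {
                        "listener": li,
                        "tracker": tracker,
                        "trial": int(r["trial"]),
                        "entropy_bits": r["entropy_bits"],
                        "rmse_db": r["rmse_db"],
                    }
                )
    raw = pd.DataFrame(records)
    curves = (
        raw.groupby(["tracker", "trial"])[["entropy_bits", "rmse_db"]]
        .mean()
        .reset_index()
    )
    summary = (
        curves[curves["trial"] == curves["trial"].max()]
        .rename(columns={"entropy_bits": "final_entropy_bits", "rmse_db": "final_rmse_db"})
        .reset_index(drop=True)
    )
    return curves, summary
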