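"""Data-quality and outcome statistics: ERP averages, split-half SNR,
score-vs-cycle regression, normality and t tests, topography tables."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .closedloop import FeedbackTrace
from .io import EpochSet

__all__ = [
    "ErpResult",
    "grand_average",
    "p300_amplitude",
    "snr_pz",
    "score_cycle_regression",
    "distribution_tests",
    "topography_table",
]


@dataclass
class ErpResult:
    """Per-condition grand-average waveforms on the epoch timebase."""

    waveforms: dict[str, np.ndarray]  # condition -> channels x time (µV)
    n_trials: dict[str, int]
    times_ms: np.ndarray
    channel_labels: list[str]


def grand_average(epochs: EpochSet, conditions: list[str] | None = None) -> ErpResult:
    """Average kept trials per condition; rejected trials are excluded."""
    kept = epochs.kept_only()
    conds = conditions or sorted(set(map(str, kept.labels)))
    waves, counts = {}, {}
    for c in conds:
        m = kept.labels == c
        if not m.any():
            raise ValueError(f"no kept trials for condition {c!r}")
        waves[c] = kept.data[m].mean(axis=0)
        counts[c] = int(m.sum())
    return ErpResult(
        waveforms=waves,
        n_trials=counts,
        times_ms=epochs.times_ms,
        channel_labels=list(epochs.channel_labels),
    )


def p300_amplitude(
    erp: ErpResult,
    channels: list[str] | None = None,
    window_ms: tuple[float, float] = (300.0, 550.0),
) -> dict[str, float]:
    """Mean amplitude (µV) over a window and channel set, per condition."""
    tmask = (erp.times_ms >= window_ms[0]) & (erp.times_ms < window_ms[1])
    if not tmask.any():
        raise ValueError("window contains no samples of the epoch timebase")
    if channels is None:
        rows = list(range(len(erp.channel_labels)))
    else:
        upper = {l.upper(): i for i, l in enumerate(erp.channel_labels)}
        rows = [upper[c.upper()] for c in channels]
    return {
        cond: float(w[np.ix_(rows, np.flatnonzero(tmask))].mean())
        for cond, w in erp.waveforms.items()
    }


def snr_pz(
    epochs: EpochSet,
    channel: str = "PZ",
    window_ms: tuple[float, float] = (0.0, 1000.0),
) -> float:
    """Split-half SNR of one channel.

    Signal power is the mean square of the all-trial average over the window;
    noise power is the mean square of (odd-average - even-average)/2, whose
    expected value is the noise variance remaining in the full average.
    Returns ``inf`` (with a warning) when the noise power is zero.
    """
    kept = epochs.kept_only()
    if kept.n_trials < 4:
        raise ValueError("need at least 4 kept trials for split-half SNR")
    upper = {l.upper(): i for i, l in enumerate(kept.channel_labels)}
    ci = upper[channel.upper()]
    tmask = (kept.times_ms >= window_ms[0]) & (kept.times_ms < window_ms[1])
    x = kept.data[:, ci, :][:, tmask]
    avg = x.mean(axis=0)
    half_diff = 0.5 * (x[0::2].mean(axis=0) - x[1::2].mean(axis=0))
    p_signal = float(np.mean(avg**2))
    p_noise = float(np.mean(half_diff**2))
    if p_noise == 0.0:
        warnings.warn("zero noise power; SNR is infinite")
        return float("inf")
    return p_signal / p_noise


def score_cycle_regression(traces: list[FeedbackTrace] | FeedbackTrace) -> dict:
    """Pearson r and OLS fit of per-cycle mean displayed score vs cycle index.

    Cycle means are pooled across the given traces.  Returns r, two-tailed p,
    slope, intercept and the 95% CI of the slope; ``degenerate`` flags a
    constant-score input where r is undefined.
    """
    if isinstance(traces, FeedbackTrace):
        traces = [traces]
    xs, ys = [], []
    for tr in traces:
        cm = tr.cycle_means()
        xs.extend(cm.index.to_numpy(dtype=float))
        ys.extend(cm.to_numpy(dtype=float))
    x = np.asarray(xs)
    y = np.asarray(ys)
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct cycle indices")
    if np.ptp(y) == 0.0:
        return {
            "pearson_r": float("nan"),
            "p": float("nan"),
            "slope": 0.0,
            "intercept": float(y[0]),
            "slope_ci95": (0.0, 0.0),
            "n": len(y),
            "degenerate": True,
        }
    fit = stats.linregress(x, y)
    df = len(x) - 2
    tcrit = stats.t.ppf(0.975, df)
    return {
        "pearson_r": float(fit.rvalue),
        "p": float(fit.pvalue),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "slope_ci95": (
            float(fit.slope - tcrit * fit.stderr),
            float(fit.slope + tcrit * fit.stderr),
        ),
        "n": len(y),
        "degenerate": False,
    }


def distribution_tests(values: np.ndarray, chance: float = 0.5) -> dict:
    """KS normality (estimated mean/SD) and one-sample t against chance."""
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 values")
    mu, sd = v.mean(), v.std(ddof=1)
    if sd == 0.0:
        ks_p = float("nan")
    else:
        ks_p = float(stats.kstest(v, "norm", args=(mu, sd)).pvalue)
    if np.allclose(v, chance):
        t, p = 0.0, 1.0
    else:
        res = stats.ttest_1samp(v, chance)
        t, p = float(res.statistic), float(res.pvalue)
    return {"ks_normality_p": ks_p, "one_sample_t_vs_chance": {"t": t, "p": p}}


def topography_table(
    erp: ErpResult, step_ms: float = 200.0, window_ms: tuple[float, float] = (0.0, 1000.0)
) -> pd.DataFrame:
    """Channel x time-point amplitude table for topographic map export.

    One column per condition/time-point pair, sampled every ``step_ms`` over
    the window (nearest epoch sample).
    """
    points = np.arange(window_ms[0], window_ms[1] + 1e-9, step_ms)
    cols = {}
    for cond, w in erp.waveforms.items():
        for t in points:
            i = int(np.argmin(np.abs(erp.times_ms - t)))
            cols[f"{cond}_{int(t)}ms"] = w[:, i]
    return pd.DataFrame(cols, index=erp.channel_labels)
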