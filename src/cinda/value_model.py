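"""Bayesian beta-distribution trial-value model and value/RPE regressions.

Reward expectation on each trial is tracked as a beta distribution with
pseudo-counts alpha (rewarded outcomes) and beta (unrewarded outcomes) that
both decay by a factor gamma before each increment:

    alpha_{t+1} = gamma * alpha_t + r_t
    beta_{t+1}  = gamma * beta_t  + (1 - r_t)

The trial value V_t = alpha_t / (alpha_t + beta_t) is the posterior-mean
reward expectation *before* outcome r_t is revealed (the prediction used
for reward-prediction-error analyses). gamma = 1 recovers the Laplace
running mean (alpha0 + sum r) / (alpha0 + beta0 + t).

gamma is fitted from behavior: motivation tracks reward expectation, so
trial-initiation latency shrinks with V; the fitted gamma maximizes the
negative Pearson correlation between V and log latency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ValueSeries",
    "RegressionResult",
    "beta_value_series",
    "fit_gamma",
    "value_regression",
    "tonic_value_analysis",
]


@dataclass
class ValueSeries:
    alpha: np.ndarray          # pseudo-count before each trial's outcome
    beta: np.ndarray
    V: np.ndarray              # pre-outcome value alpha/(alpha+beta)
    V_post: np.ndarray         # value after the trial's update
    tercile: np.ndarray        # "low" | "med" | "high", by within-session V rank
    gamma: float
    prior: tuple[float, float]

    def __len__(self) -> int:
        return self.V.size


def _terciles(V: np.ndarray) -> np.ndarray:
    """Partition trials into thirds by V rank; ties broken by trial order."""
    order = np.argsort(V, kind="stable")  # stable sort = tie-break by trial order
    labels = np.empty(V.size, dtype=object)
    for chunk, lab in zip(np.array_split(order, 3), ("low", "med", "high")):
        labels[chunk] = lab
    return labels


def beta_value_series(
    trials: pd.DataFrame | np.ndarray,
    gamma: float,
    prior: tuple[float, float] = (1.0, 1.0),
) -> ValueSeries:
    """Run the decaying beta model over a session's outcome sequence.

    ``trials`` may be a trial table (uses its ``outcome`` column) or a
    plain 0/1 outcome array.
    """
    if not 0 < gamma <= 1:
        raise ValueError("gamma must be in (0, 1]")
    if isinstance(trials, pd.DataFrame):
        outcomes = trials["outcome"].to_numpy(dtype=float)
    else:
        outcomes = np.asarray(trials, dtype=float)
    n = outcomes.size
    a0, b0 = float(prior[0]), float(prior[1])
    if a0 <= 0 or b0 <= 0:
        raise ValueError("prior pseudo-counts must be positive")
    alpha = np.empty(n)
    beta = np.empty(n)
    a, b = a0, b0
    for t, r in enumerate(outcomes):
        alpha[t], beta[t] = a, b
        a = gamma * a + r
        b = gamma * b + (1.0 - r)
    V = alpha / (alpha + beta)
    V_post = np.append(alpha[1:] / (alpha[1:] + beta[1:]), a / (a + b))
    return ValueSeries(
        alpha=alpha, beta=beta, V=V, V_post=V_post,
        tercile=_terciles(V), gamma=float(gamma), prior=(a0, b0),
    )


def fit_gamma(
    trials: pd.DataFrame,
    grid: np.ndarray | None = None,
    prior: tuple[float, float] = (1.0, 1.0),
    use_post_outcome: bool = False,
) -> tuple[float, pd.DataFrame]:
    """Fit the decay gamma from initiation latencies.

    For each grid gamma, computes V_t and the Pearson correlation between
    V_t and log(latency_t); returns the gamma with the most negative
    correlation (ties -> smallest gamma) and the full profile.
    """
    if grid is None:
        grid = np.round(np.arange(0.50, 1.00 + 1e-9, 0.01), 10)
    lat = trials["latency"].to_numpy(dtype=float)
    if np.any(lat <= 0):
        raise ValueError("latencies must be positive")
    log_lat = np.log(lat)
    if np.allclose(log_lat, log_lat[0]):
        raise ValueError("no latency variance")
    rows = []
    for g in grid:
        vs = beta_value_series(trials, float(g), prior=prior)
        v = vs.V_post if use_post_outcome else vs.V
        r = stats.pearsonr(v, log_lat).statistic if np.std(v) > 0 else np.nan
        rows.append((float(g), r))
    profile = pd.DataFrame(rows, columns=["gamma", "r"])
    finite = profile.dropna(subset=["r"])
    if finite.empty:
        raise ValueError("value series degenerate at every gamma")
    # idxmin returns the first (smallest-gamma) row on ties
    gamma_star = float(finite.loc[finite["r"].idxmin(), "gamma"])
    return gamma_star, profile


@dataclass
class RegressionResult:
    scope: str                 # "epoch" | "per_bin"
    coefficient: float | np.ndarray
    intercept: float | np.ndarray
    p_value: float | np.ndarray
    significant: bool | np.ndarray
    sign: str | np.ndarray     # "positive" | "negative" | "zero"
    n_trials: int
    alpha: float
    epoch: tuple[float, float] | None = None
    correction: str | None = None


def _ols_1d(y: np.ndarray, v: np.ndarray) -> tuple[float, float, float]:
    """Simple OLS y ~ v; two-tailed p (t-test == F-test for one regressor)."""
    if np.std(y) == 0:
        return 0.0, float(np.mean(y)), 1.0   # constant signal convention
    res = stats.linregress(v, y)
    p = res.pvalue if np.isfinite(res.pvalue) else 1.0
    return float(res.slope), float(res.intercept), float(p)


def value_regression(
    signal: np.ndarray,
    values: ValueSeries | np.ndarray,
    scope: str = "epoch",
    trial_filter: np.ndarray | None = None,
    alpha: float = 0.05,
    correction: str = "bonferroni",
) -> RegressionResult:
    """OLS of a per-trial signal on trial value V.

    ``signal``: per-trial scalar (epoch scope, e.g. mean rate 100-250 ms
    after Side In) or trials x bins matrix (per_bin scope).  A negative
    coefficient on rewarded trials is RPE-consistent: the response is
    larger when reward is less expected.
    """
    v = values.V if isinstance(values, ValueSeries) else np.asarray(values, float)
    signal = np.asarray(signal, dtype=float)
    if trial_filter is not None:
        trial_filter = np.asarray(trial_filter, dtype=bool)
        v = v[trial_filter]
        signal = signal[trial_filter]
    n = v.size
    if n < 10:
        raise ValueError("fewer than 10 trials after filtering")
    if np.std(v) == 0:
        raise ValueError("value not identified (zero variance in V)")

    def signof(c: float) -> str:
        return "positive" if c > 0 else ("negative" if c < 0 else "zero")

    if scope == "epoch":
        if signal.ndim != 1:
            raise ValueError("epoch scope expects a per-trial scalar signal")
        coef, icpt, p = _ols_1d(signal, v)
        return RegressionResult(
            scope="epoch", coefficient=coef, intercept=icpt, p_value=p,
            significant=bool(p < alpha), sign=signof(coef), n_trials=n,
            alpha=alpha, correction=None,
        )
    if scope == "per_bin":
        if signal.ndim != 2:
            raise ValueError("per_bin scope expects a trials x bins matrix")
        n_bins = signal.shape[1]
        coefs = np.empty(n_bins)
        icpts = np.empty(n_bins)
        ps = np.empty(n_bins)
        for i in range(n_bins):
            coefs[i], icpts[i], ps[i] = _ols_1d(signal[:, i], v)
        if correction == "bonferroni":
            thr = alpha / n_bins
        elif correction in (None, "none"):
            thr = alpha
        else:
            raise ValueError(f"unknown correction '{correction}'")
        sig = ps < thr
        signs = np.array([signof(c) for c in coefs], dtype=object)
        return RegressionResult(
            scope="per_bin", coefficient=coefs, intercept=icpts, p_value=ps,
            significant=sig, sign=signs, n_trials=n, alpha=alpha,
            correction=correction,
        )
    raise ValueError(f"unknown scope '{scope}'")


def tonic_value_analysis(
    spike_times: np.ndarray,
    trials: pd.DataFrame,
    values: ValueSeries,
    iti_window: float = 3.0,
    minute_bin: float = 60.0,
    duration: float | None = None,
) -> dict:
    """Tonic-rate checks: does baseline CIN firing track trial value?

    Returns per-trial mean rates in the inter-trial interval
    [light_on - iti_window, light_on), grouped by value tercile (with
    Kruskal-Wallis and one-way-ANOVA p-values, reported not gated), plus
    the session firing-rate series in 1-min bins.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    light_on = trials["light_on"].to_numpy(dtype=float)
    keep = light_on >= iti_window
    n_dropped = int((~keep).sum())
    lo = light_on[keep]
    counts = (
        np.searchsorted(spike_times, lo)
        - np.searchsorted(spike_times, lo - iti_window)
    )
    iti_rates = counts / iti_window
    terc = values.tercile[keep]
    groups = {
        lab: iti_rates[terc == lab] for lab in ("low", "med", "high")
        if np.any(terc == lab)
    }
    kw_p = anova_p = np.nan
    if len(groups) >= 2 and all(g.size >= 2 for g in groups.values()):
        arrs = list(groups.values())
        try:
            kw_p = float(stats.kruskal(*arrs).pvalue)
        except ValueError:  # all values identical
            kw_p = 1.0
        anova_p = float(stats.f_oneway(*arrs).pvalue)
        if not np.isfinite(anova_p):
            anova_p = 1.0

    if duration is None:
        duration = max(
            float(trials["side_in"].max()),
            float(spike_times[-1]) if spike_times.size else 0.0,
        )
    edges = np.arange(0.0, duration + minute_bin, minute_bin)
    edges = edges[edges <= duration + 1e-9]
    if edges[-1] < duration - 1e-9:
        edges = np.append(edges, duration)
    counts_min, _ = np.histogram(spike_times, bins=edges)
    widths = np.diff(edges)
    minute_rates = counts_min / widths

    return {
        "iti_rates": iti_rates,
        "tercile": terc,
        "tercile_means": {k: float(np.mean(g)) for k, g in groups.items()},
        "kruskal_p": kw_p,
        "anova_p": anova_p,
        "n_dropped": n_dropped,
        "minute_bin_times": edges[:-1],
        "minute_rates": minute_rates,
    }
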