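"""Descriptive analyses over inferred transcription profiles.

Phases (constant-rate segments), up/down switch counting, switch-pair
amplitude correlations, the rate-duration regression on the ln-ln scale,
binary vs graded classification of cell profiles, posterior-predictive mRNA
count distributions, pooled 1-hour pairwise trace correlations and the
population-level mean transcription rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .postprocess import SubModelTable
from .types import LuminescenceTrace, Phase, PosteriorEnsemble, SwitchProfile

__all__ = [
    "profile_to_phases",
    "count_switches",
    "rate_duration_regression",
    "switch_pair_analysis",
    "classify_cell",
    "posterior_predictive_mrna",
    "pairwise_trace_correlation",
    "population_rate_trajectory",
    "phases_to_frame",
]


def profile_to_phases(profile: SwitchProfile, cell_id: str = "cell") -> list[Phase]:
    """One phase per constant-rate segment, tiling the observation window.

    The first phase is entered at the recording start ("start" direction,
    left-censored); the last runs into the recording end (right-censored).
    Directions of the remaining phases follow the sign of the rate change at
    the entering switch.
    """
    edges = profile.segment_edges()
    phases = []
    for i, rate in enumerate(profile.rates):
        if i == 0:
            direction = "start"
        else:
            direction = "up" if profile.rates[i] > profile.rates[i - 1] else "down"
        phases.append(Phase(
            cell_id=cell_id,
            start=float(edges[i]),
            end=float(edges[i + 1]),
            rate=float(rate),
            entering_direction=direction,
            left_censored=(i == 0),
            right_censored=(i == len(profile.rates) - 1),
        ))
    return phases


def phases_to_frame(phases: list[Phase]) -> pd.DataFrame:
    return pd.DataFrame([{
        "cell_id": p.cell_id, "start": p.start, "end": p.end,
        "duration": p.duration, "rate": p.rate,
        "direction": p.entering_direction,
        "left_censored": p.left_censored, "right_censored": p.right_censored,
    } for p in phases])


def _directions(profile: SwitchProfile) -> list[str]:
    return ["up" if b > a else "down"
            for a, b in zip(profile.rates[:-1], profile.rates[1:])]


def count_switches(
    profiles_by_condition: dict[str, list[SwitchProfile]],
    submodels_by_condition: dict[str, list[SubModelTable]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell up/down switch counts and per-condition mean +/- SEM.

    With ``submodels_by_condition`` given, counts are probability-weighted
    expectations over each cell's sub-models instead of consensus counts.
    Returns (per-cell frame, summary frame).
    """
    rows = []
    for cond, profiles in profiles_by_condition.items():
        if not profiles:
            raise ValueError(f"no profiles for condition {cond!r}")
        if submodels_by_condition is not None:
            for i, table in enumerate(submodels_by_condition[cond]):
                up = sum(sm.weight * _directions(sm.representative_profile).count("up")
                         for sm in table)
                down = sum(sm.weight * _directions(sm.representative_profile).count("down")
                           for sm in table)
                rows.append((cond, i, up, down))
        else:
            for i, prof in enumerate(profiles):
                d = _directions(prof)
                rows.append((cond, i, d.count("up"), d.count("down")))
    per_cell = pd.DataFrame(rows, columns=["condition", "cell", "up", "down"])
    summary = per_cell.groupby("condition")[["up", "down"]].agg(["mean", "sem"])
    summary.columns = [f"{a}_{b}" for a, b in summary.columns]
    return per_cell, summary.reset_index()


@dataclass(frozen=True)
class RateDurationFit:
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    slope_ci: tuple[float, float]
    n_used: int
    n_excluded: int


def rate_duration_regression(phases: list[Phase]) -> RateDurationFit:
    """OLS of ln(duration) on ln(rate) over uncensored positive phases.

    Censored phases (recording-truncated durations) and non-positive rates
    are excluded; the exclusion count is reported.  The Pearson r carries a
    two-sided p-value.
    """
    usable = [p for p in phases
              if not (p.left_censored or p.right_censored)
              and p.rate > 0 and p.duration > 0]
    n_excluded = len(phases) - len(usable)
    if len(usable) < 3:
        raise ValueError("need >= 3 uncensored phases with positive rate/duration")
    x = np.log([p.rate for p in usable])
    y = np.log([p.duration for p in usable])
    res = stats.linregress(x, y)
    r, p = stats.pearsonr(x, y)
    # 95% CI on the slope from the t distribution
    tcrit = stats.t.ppf(0.975, len(x) - 2)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    return RateDurationFit(slope=float(res.slope), intercept=float(res.intercept),
                           pearson_r=float(r), p_value=float(p),
                           slope_ci=ci, n_used=len(usable), n_excluded=n_excluded)


_SCENARIOS = {("up", "down"): "Up-Down", ("down", "down"): "Down-Down",
              ("down", "up"): "Down-Up", ("up", "up"): "Up-Up"}


def switch_pair_analysis(profiles: list[SwitchProfile]
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Consecutive switch-pair amplitudes and per-scenario correlations.

    Each consecutive pair of switches contributes signed amplitudes
    (previous, current) labelled Up-Down / Down-Down / Down-Up / Up-Up;
    per-scenario Pearson correlations are computed on absolute amplitudes.
    Scenarios with fewer than 3 pairs are reported as undefined (NaN).
    """
    rows = []
    for i, prof in enumerate(profiles):
        amps = np.diff(prof.rates)
        dirs = _directions(prof)
        for j in range(len(amps) - 1):
            rows.append({
                "cell": i,
                "prev_amplitude": float(amps[j]),
                "curr_amplitude": float(amps[j + 1]),
                "scenario": _SCENARIOS[(dirs[j], dirs[j + 1])],
            })
    pairs = pd.DataFrame(rows, columns=["cell", "prev_amplitude",
                                        "curr_amplitude", "scenario"])
    corr_rows = []
    for scen in _SCENARIOS.values():
        sub = pairs[pairs.scenario == scen]
        if len(sub) < 3:
            corr_rows.append({"scenario": scen, "r": np.nan, "p": np.nan,
                              "n_pairs": len(sub)})
        else:
            r, p = stats.pearsonr(sub.prev_amplitude.abs(), sub.curr_amplitude.abs())
            corr_rows.append({"scenario": scen, "r": float(r), "p": float(p),
                              "n_pairs": len(sub)})
    return pairs, pd.DataFrame(corr_rows)


def classify_cell(profile: SwitchProfile) -> str:
    """Binary vs graded classification of a cell's switch pattern.

    "graded-decrease" if the profile contains at least one Down-Down pair of
    consecutive switches; otherwise "graded-increase" if it contains an
    Up-Up pair; otherwise "binary" (strict alternation or at most one
    switch).  Deterministic in the direction sequence alone.
    """
    dirs = _directions(profile)
    pairs = list(zip(dirs[:-1], dirs[1:]))
    if ("down", "down") in pairs:
        return "graded-decrease"
    if ("up", "up") in pairs:
        return "graded-increase"
    return "binary"


def posterior_predictive_mrna(ensemble: PosteriorEnsemble, t_query: float,
                              n_draws: int = 200, seed=None) -> dict:
    """Posterior-predictive mRNA molecule counts at ``t_query``.

    For each draw a posterior sample (profile, parameters) is picked at
    random; the mRNA mean obeys dm/dt = beta(t) - delta_m m from the
    stationary mean of the first segment, and because a linear birth-death
    process started at Poisson stays Poisson, the predictive count is a
    Poisson draw at that mean.  Returns the empirical count distribution
    with its mean and 95% normal CI, comparable to an smFISH count table.
    """
    if len(ensemble) == 0:
        raise ValueError("empty posterior ensemble")
    window = ensemble.samples[0].profile.window
    if not (window[0] <= t_query <= window[1]):
        raise ValueError("t_query outside the observation window")
    rng = np.random.default_rng(seed)
    idx = rng.integers(len(ensemble.samples), size=n_draws)
    counts = np.empty(n_draws, dtype=int)
    for out_i, i in enumerate(idx):
        s = ensemble.samples[i]
        dm = s.params.delta_m
        edges = s.profile.segment_edges()
        m = s.profile.rates[0] / dm
        for j, beta in enumerate(s.profile.rates):
            a, b = float(edges[j]), float(edges[j + 1])
            if a >= t_query:
                break
            h = min(b, t_query) - a
            m_inf = beta / dm
            m = m_inf + (m - m_inf) * np.exp(-dm * h)
            if b >= t_query:
                break
        counts[out_i] = rng.poisson(m)
    mean = float(np.mean(counts))
    sem = float(np.std(counts, ddof=1) / np.sqrt(n_draws)) if n_draws > 1 else np.nan
    return {"counts": counts, "mean": mean,
            "ci95": (mean - 1.959964 * sem, mean + 1.959964 * sem)}


def pairwise_trace_correlation(traces: list[LuminescenceTrace],
                               window_h: float = 1.0,
                               horizon_h: float = 20.0
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations over sequential pooled time windows.

    For each ``window_h``-hour window up to ``horizon_h``, the correlation
    of luminescence within the window is computed between every unordered
    pair of cells.  Pairs where either cell has zero variance in a window
    are skipped (and counted).  Returns (long frame of coefficients,
    per-window summary with the median and skip count).
    """
    if len(traces) < 2:
        raise ValueError("need at least 2 traces")
    t0 = traces[0].times
    for tr in traces[1:]:
        if len(tr) != len(t0) or np.max(np.abs(tr.times - t0)) > 1e-9:
            raise ValueError("traces must share a common sampling grid")
    rows = []
    skipped = []
    n_win = int(np.floor(horizon_h / window_h))
    for w in range(n_win):
        lo, hi = w * window_h, (w + 1) * window_h
        mask = (t0 >= lo) & (t0 < hi)
        if mask.sum() < 3:
            continue
        seg = np.array([tr.values[mask] for tr in traces])
        sd = seg.std(axis=1)
        n_skip = 0
        for i in range(len(traces)):
            for j in range(i + 1, len(traces)):
                if sd[i] == 0 or sd[j] == 0:
                    n_skip += 1
                    continue
                r = float(np.corrcoef(seg[i], seg[j])[0, 1])
                rows.append({"window_start": lo, "cell_i": i, "cell_j": j, "r": r})
        skipped.append({"window_start": lo, "n_skipped": n_skip})
    coeffs = pd.DataFrame(rows, columns=["window_start", "cell_i", "cell_j", "r"])
    med = coeffs.groupby("window_start")["r"].median().rename("median_r").reset_index()
    summary = med.merge(pd.DataFrame(skipped), on="window_start", how="left")
    return coeffs, summary


def compare_condition_correlations(coeffs_a: pd.DataFrame,
                                   coeffs_b: pd.DataFrame) -> dict:
    """Unpaired t-test between two conditions' pooled correlation coefficients."""
    t, p = stats.ttest_ind(coeffs_a["r"], coeffs_b["r"], equal_var=False)
    return {"t": float(t), "p": float(p),
            "n_a": len(coeffs_a), "n_b": len(coeffs_b)}


def population_rate_trajectory(
    profiles: list[SwitchProfile] | None = None,
    submodel_tables: list[SubModelTable] | None = None,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Pointwise population mean of beta(t) on a common grid.

    Either consensus profiles or sub-model tables (probability-weighted mean
    over each cell's sub-models) may be supplied.
    """
    if profiles is None and submodel_tables is None:
        raise ValueError("supply profiles or submodel_tables")
    if profiles is not None and not profiles:
        raise ValueError("need at least one profile")
    if grid is None:
        window = (profiles[0].window if profiles
                  else submodel_tables[0][0].representative_profile.window)
        grid = np.arange(window[0], window[1] + 1e-9, 0.25)
    if profiles is not None:
        rates = np.array([p.rate_at(grid) for p in profiles])
    else:
        rates = np.array([
            np.sum([sm.weight * sm.representative_profile.rate_at(grid)
                    for sm in table], axis=0)
            for table in submodel_tables])
    return pd.DataFrame({"time_h": grid, "mean_rate": rates.mean(axis=0)})
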