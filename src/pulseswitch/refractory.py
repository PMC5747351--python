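"""Three-state (on / off / primed) model of the transcriptional cycle.

The inactive period between a down-switch and the next up-switch is modelled
as the sum of two exponential sojourns: an off (refractory) state with mean
T1 during which reactivation cannot begin, and a primed state with mean T2.
Their sum is hypoexponential; on-periods are exponential with mean T0.
Durations extracted from inferred switch profiles are merged over runs of
same-direction switches, then fitted by censored maximum likelihood:
complete durations contribute the density, right-censored (open-ended) ones
the survival probability.  T1 < T2 is imposed for identifiability and the
smaller mean is reported as the refractory period.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .types import DurationSample, Phase, ThreeStateEstimate

__all__ = [
    "merge_same_direction",
    "hypoexp_pdf",
    "hypoexp_cdf",
    "hypoexp_logsf",
    "fit_off_primed",
    "fit_on",
    "estimate_three_state",
    "refractory_summary",
    "minimum_duration_stats",
    "durations_to_frame",
]

_EQUAL_RATE_RTOL = 1e-6


def merge_same_direction(phases: list[Phase]) -> list[DurationSample]:
    """Merge runs of same-direction switches into single inter-switch durations.

    The continuous switch model frequently emits a down-switch followed by
    further down-switches (graded deactivation); for the discrete
    on/off/primed model those consecutive phases form one inactive duration
    running from the first switch of the run to the next opposite-direction
    switch.  A duration ending at the recording edge is right-censored.  The
    initial phase (entered at the recording start, not by a switch) carries
    no direction and is dropped.
    """
    phases = sorted(phases, key=lambda p: p.start)
    out: list[DurationSample] = []
    run_dir: str | None = None
    run_start = 0.0
    run_cell = ""
    run_censored = False
    for p in phases:
        if p.entering_direction == "start":
            continue
        if p.entering_direction == run_dir:
            run_censored = p.right_censored
            continue
        if run_dir is not None:
            out.append(DurationSample(value=p.start - run_start,
                                      censored=False,
                                      kind=f"after_{run_dir}",
                                      cell_id=run_cell))
        run_dir = p.entering_direction
        run_start = p.start
        run_cell = p.cell_id
        run_censored = p.right_censored
    if run_dir is not None:
        end = phases[-1].end
        out.append(DurationSample(value=end - run_start,
                                  censored=run_censored,
                                  kind=f"after_{run_dir}",
                                  cell_id=run_cell))
    return out


def durations_to_frame(durations: list[DurationSample]) -> pd.DataFrame:
    return pd.DataFrame([{
        "cell_id": d.cell_id, "kind": d.kind, "value": d.value,
        "censored": d.censored,
    } for d in durations], columns=["cell_id", "kind", "value", "censored"])


def _check_rates(lambda1: float, lambda2: float) -> None:
    if lambda1 <= 0 or lambda2 <= 0:
        raise ValueError("rates must be > 0")


def hypoexp_pdf(t, lambda1: float, lambda2: float):
    """Density of the sum of two independent exponentials (rates lambda1,2).

    f(t) = l1 l2 / (l2 - l1) * (exp(-l1 t) - exp(-l2 t)); symmetric in the
    two rates, with the Erlang-2 limit l^2 t exp(-l t) used when the rates
    are relatively closer than 1e-6.
    """
    _check_rates(lambda1, lambda2)
    scalar = np.ndim(t) == 0
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(t)
    pos = t >= 0
    tp = t[pos]
    if abs(lambda1 - lambda2) < _EQUAL_RATE_RTOL * max(lambda1, lambda2):
        lam = 0.5 * (lambda1 + lambda2)
        out[pos] = lam * lam * tp * np.exp(-lam * tp)
    else:
        c = lambda1 * lambda2 / (lambda2 - lambda1)
        out[pos] = c * (np.exp(-lambda1 * tp) - np.exp(-lambda2 * tp))
    return float(out[0]) if scalar else out


def hypoexp_cdf(t, lambda1: float, lambda2: float):
    """Distribution function matching :func:`hypoexp_pdf`."""
    _check_rates(lambda1, lambda2)
    scalar = np.ndim(t) == 0
    t = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(t)
    pos = t >= 0
    tp = t[pos]
    if abs(lambda1 - lambda2) < _EQUAL_RATE_RTOL * max(lambda1, lambda2):
        lam = 0.5 * (lambda1 + lambda2)
        out[pos] = 1.0 - (1.0 + lam * tp) * np.exp(-lam * tp)
    else:
        out[pos] = (lambda2 * (1.0 - np.exp(-lambda1 * tp))
                    - lambda1 * (1.0 - np.exp(-lambda2 * tp))) / (lambda2 - lambda1)
    return float(out[0]) if scalar else out


def hypoexp_logsf(t, lambda1: float, lambda2: float):
    """Log survival function, numerically stable for large t.

    1 - F(t) = (l2 exp(-l1 t) - l1 exp(-l2 t)) / (l2 - l1).
    """
    _check_rates(lambda1, lambda2)
    scalar = np.ndim(t) == 0
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if abs(lambda1 - lambda2) < _EQUAL_RATE_RTOL * max(lambda1, lambda2):
        lam = 0.5 * (lambda1 + lambda2)
        out = np.log1p(lam * t) - lam * t
    else:
        # order rates so the slow exponential dominates: with la < lb,
        # S(t) = (lb e^{-la t} - la e^{-lb t}) / (lb - la)
        la, lb = min(lambda1, lambda2), max(lambda1, lambda2)
        out = -la * t + np.log(lb - la * np.exp(-(lb - la) * t)) - np.log(lb - la)
    return float(out[0]) if scalar else out


def _neg_loglik_down(x: np.ndarray, complete: np.ndarray,
                     censored: np.ndarray) -> float:
    # x = (log T1, log (T2 - T1)) enforces 0 < T1 < T2
    T1 = math.exp(x[0])
    T2 = T1 + math.exp(x[1])
    l1, l2 = 1.0 / T1, 1.0 / T2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = hypoexp_pdf(complete, l1, l2)
        if np.any(f <= 0) or not np.all(np.isfinite(f)):
            return 1e12
        ll = float(np.sum(np.log(f)))
        if len(censored):
            ll += float(np.sum(hypoexp_logsf(censored, l1, l2)))
    return -ll if math.isfinite(ll) else 1e12


def fit_off_primed(durations: list[DurationSample] | pd.DataFrame,
                   min_complete: int = 5) -> tuple[float, float, float]:
    """Censored MLE of (T1, T2) from after-down durations.

    Maximises sum(log f_d) over complete durations plus sum(log(1 - F_d))
    over right-censored ones, under the identifiability constraint T1 < T2
    (parameterised as T2 = T1 + gap with both factors log-transformed).
    Multi-start Nelder-Mead; returns (T1, T2, loglik).  A boundary solution
    with T1 -> T2 is flagged with a warning.
    """
    df = _as_frame(durations)
    df = df[df.kind == "after_down"]
    complete = df.loc[~df.censored, "value"].to_numpy(dtype=float)
    censored = df.loc[df.censored, "value"].to_numpy(dtype=float)
    if len(complete) == 0:
        raise ValueError("all after-down durations are censored; MLE undefined")
    if len(complete) < min_complete:
        raise ValueError(f"need >= {min_complete} complete after-down durations")
    mean = float(np.mean(complete))
    starts = []
    for frac in (0.15, 0.3, 0.45):
        T1 = max(frac * mean, 1e-3)
        gap = max(mean - 2 * T1, 0.25 * mean)
        starts.append((math.log(T1), math.log(gap)))
    best = None
    for x0 in starts:
        res = minimize(_neg_loglik_down, np.asarray(x0), args=(complete, censored),
                       method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not math.isfinite(best.fun) or best.fun >= 1e11:
        raise RuntimeError("hypoexponential MLE failed to converge")
    T1 = math.exp(best.x[0])
    T2 = T1 + math.exp(best.x[1])
    if (T2 - T1) / T1 < 1e-3:
        warnings.warn("boundary solution T1 -> T2: the two inactive states are "
                      "indistinguishable on this dataset", RuntimeWarning)
    return T1, T2, -float(best.fun)


def fit_on(durations: list[DurationSample] | pd.DataFrame) -> float:
    """Censored-exponential MLE of the mean on-period T0 (closed form).

    rate = (# complete durations) / (sum of all durations, complete and
    censored); T0 is its inverse.
    """
    df = _as_frame(durations)
    df = df[df.kind == "after_up"]
    n_complete = int((~df.censored).sum())
    if n_complete == 0:
        raise ValueError("no complete after-up durations; rate MLE undefined")
    total = float(df.value.sum())
    return total / n_complete


def _as_frame(durations) -> pd.DataFrame:
    if isinstance(durations, pd.DataFrame):
        return durations
    return durations_to_frame(durations)


def estimate_three_state(durations: list[DurationSample] | pd.DataFrame,
                         beta_L: float = float("nan"),
                         beta_H: float = float("nan")) -> ThreeStateEstimate:
    """Joint summary: on-period T0 plus off/primed (T1, T2) censored MLEs."""
    df = _as_frame(durations)
    T0 = fit_on(df)
    T1, T2, ll = fit_off_primed(df)
    down = df[df.kind == "after_down"]
    return ThreeStateEstimate(
        T0=T0, T1=T1, T2=T2, loglik=ll,
        n_complete=int((~down.censored).sum()),
        n_censored=int(down.censored.sum()),
        beta_L=beta_L, beta_H=beta_H,
    )


def refractory_summary(durations: list[DurationSample] | pd.DataFrame,
                       n_boot: int = 200, seed=None) -> dict:
    """Bootstrap distribution of the refractory period T1.

    Cells (not individual durations) are resampled with replacement to
    respect within-cell dependence; (T1, T2) is refitted on each replicate.
    Reports the median, interquartile range and full range of the T1
    estimates; fails if fewer than half the replicates converge.
    """
    df = _as_frame(durations)
    T1_full, _, _ = fit_off_primed(df)  # must succeed on the full sample
    cells = df.cell_id.unique()
    groups = {c: g for c, g in df.groupby("cell_id")}
    rng = np.random.default_rng(seed)
    t1s = []
    for _ in range(n_boot):
        chosen = rng.choice(cells, size=len(cells), replace=True)
        boot = pd.concat([groups[c] for c in chosen], ignore_index=True)
        try:
            t1, _, _ = fit_off_primed(boot)
            t1s.append(t1)
        except (ValueError, RuntimeError):
            continue
    if len(t1s) < n_boot / 2:
        raise RuntimeError(f"only {len(t1s)}/{n_boot} bootstrap replicates "
                           "converged")
    t1s = np.asarray(t1s)
    q25, med, q75 = np.percentile(t1s, [25, 50, 75])
    return {"T1_point": float(T1_full), "median": float(med),
            "iqr": (float(q25), float(q75)),
            "whiskers": (float(np.min(t1s)), float(np.max(t1s))),
            "n_replicates": int(len(t1s))}


def minimum_duration_stats(durations: list[DurationSample] | pd.DataFrame) -> dict:
    """Minimum complete duration and empirical CDF per direction kind.

    Returns ``{kind: {"min": ..., "ecdf_x": ..., "ecdf_y": ..., "n": ...}}``;
    kinds with no complete durations are reported with min = None.
    """
    df = _as_frame(durations)
    out = {}
    for kind in ("after_down", "after_up"):
        vals = np.sort(df.loc[(df.kind == kind) & (~df.censored), "value"]
                       .to_numpy(dtype=float))
        if len(vals) == 0:
            out[kind] = {"min": None, "ecdf_x": vals, "ecdf_y": vals, "n": 0}
        else:
            out[kind] = {"min": float(vals[0]), "ecdf_x": vals,
                         "ecdf_y": np.arange(1, len(vals) + 1) / len(vals),
                         "n": int(len(vals))}
    return out
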