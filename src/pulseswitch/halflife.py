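"""Degradation-rate estimation from inhibitor-induced luminescence decay.

Blocking translation (cycloheximide) leaves the reporter protein decaying as
dP/dt = c_p - delta_p * P, so luminescence falls as a single exponential to
a small floor.  Blocking transcription (actinomycin D) leaves
dM/dt = c_m - delta_m * M with protein still translated from the decaying
mRNA pool, so luminescence follows the two-exponential solution of the
linear cascade.  The protein rate is fitted first and then fixed when
identifying the mRNA rate, mirroring the experimental order.  Fitted rates
feed the informative degradation priors of the switch-model inference.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares

from .types import DecayFit, LuminescenceTrace

__all__ = ["fit_protein_decay", "fit_mrna_decay", "make_degradation_prior"]

PRIOR_LOG_SD_FLOOR = 0.1


class DecayFitError(RuntimeError):
    """Raised when a decay fit cannot be performed or did not converge."""


def _post_inhibition(trace: LuminescenceTrace, t_inhibit: float):
    mask = trace.times >= t_inhibit - 1e-9
    t = trace.times[mask] - t_inhibit
    y = trace.values[mask]
    if len(t) < 5:
        raise DecayFitError("need at least 5 points after t_inhibit")
    return t, y


def _multistart_ls(residual, starts, bounds):
    best = None
    for x0 in starts:
        try:
            res = least_squares(residual, x0, bounds=bounds, xtol=1e-12,
                                ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        raise DecayFitError("decay fit did not converge from any start")
    return best


def fit_protein_decay(trace: LuminescenceTrace, t_inhibit: float) -> DecayFit:
    """Fit Y(t) = A exp(-delta_p (t - t_inhibit)) + B to a translation-
    inhibition trace; B = kappa c_p / delta_p >= 0 is the residual floor.

    Returns the protein degradation rate (the fitted half-life is
    ln 2 / rate).  Raises :class:`DecayFitError` on increasing traces or
    non-convergence.
    """
    t, y = _post_inhibition(trace, t_inhibit)
    # require an overall decreasing trend
    n3 = max(len(y) // 3, 1)
    if np.mean(y[:n3]) <= np.mean(y[-n3:]):
        raise DecayFitError("post-inhibition trace is not decreasing; "
                            "cannot fit an exponential decay")
    y0 = float(np.mean(y[:n3]))
    y_inf = float(max(np.mean(y[-n3:]), 0.0))
    amp0 = max(y0 - y_inf, 1e-6)
    span = float(t[-1] - t[0])
    starts = [np.array([amp0, r, y_inf]) for r in (0.1, 0.5 / span * np.log(2) * 4, 2.0)]

    def residual(x):
        A, rate, B = x
        return A * np.exp(-rate * t) + B - y

    res = _multistart_ls(residual, starts,
                         bounds=([0.0, 1e-6, 0.0], [np.inf, np.inf, np.inf]))
    A, rate, B = res.x
    return DecayFit(rate=float(rate), residual_const=float(B),
                    fit_rss=float(2 * res.cost), n_points=len(t))


def fit_mrna_decay(trace: LuminescenceTrace, t_inhibit: float,
                   delta_p: float, rate_tol: float = 0.02) -> DecayFit:
    """Identify the mRNA degradation rate from a transcription-inhibition
    trace, with the protein rate fixed from :func:`fit_protein_decay`.

    The post-inhibition luminescence is the cascade solution
    Y(t) = a exp(-delta_p t) + b exp(-delta_m t) + c with known delta_p; the
    coefficient of the delta_m exponential is the translated decaying mRNA
    pool.  A fitted delta_m within ``rate_tol`` (relative) of delta_p is
    rejected as degenerate: the two exponentials are then unidentifiable and
    the limiting t*exp(-delta t) form should be considered instead.
    """
    if delta_p <= 0:
        raise ValueError("delta_p must be > 0")
    t, y = _post_inhibition(trace, t_inhibit)
    n3 = max(len(y) // 3, 1)
    if np.mean(y[:n3]) <= np.mean(y[-n3:]):
        raise DecayFitError("post-inhibition trace is not decreasing")
    y0 = float(np.mean(y[:n3]))
    y_inf = float(max(np.mean(y[-n3:]), 0.0))
    amp0 = max(y0 - y_inf, 1e-6)

    def residual(x):
        a, b, dm, c = x
        return a * np.exp(-delta_p * t) + b * np.exp(-dm * t) + c - y

    # protein part decays and the mRNA-driven part transiently feeds it:
    # the delta_m exponential enters with the opposite-signed coefficient
    # when delta_m > delta_p, so leave both coefficient signs free.
    starts = [np.array([amp0 * f, amp0 * (1 - f), dm0, y_inf])
              for f in (0.2, 0.8) for dm0 in (0.3, 1.0, 3.0)]
    res = _multistart_ls(
        residual, starts,
        bounds=([-np.inf, -np.inf, 1e-6, 0.0], [np.inf, np.inf, np.inf, np.inf]))
    a, b, dm, c = res.x
    if abs(dm - delta_p) < rate_tol * delta_p:
        raise DecayFitError(
            f"fitted delta_m={dm:.4g} indistinguishable from delta_p={delta_p:.4g}; "
            "the cascade is degenerate (consider the t*exp(-delta*t) limit form)")
    return DecayFit(rate=float(dm), residual_const=float(c),
                    fit_rss=float(2 * res.cost), n_points=len(t))


def make_degradation_prior(fits: list[DecayFit]) -> dict:
    """Log-normal prior specification from replicate decay fits.

    The prior median is the geometric mean of the fitted rates; the log-scale
    s.d. is the replicate spread of log rates, floored at 0.1 so a handful of
    tightly agreeing replicates still yields a proper, usable prior.
    Returns ``{"median": ..., "log_sd": ...}``.
    """
    if not fits:
        raise ValueError("need at least one decay fit")
    if len(fits) < 2:
        raise ValueError("need >= 2 replicate fits to set a prior spread")
    log_rates = np.log([f.rate for f in fits])
    return {
        "median": float(np.exp(np.mean(log_rates))),
        "log_sd": float(max(np.std(log_rates, ddof=1), PRIOR_LOG_SD_FLOOR)),
    }
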