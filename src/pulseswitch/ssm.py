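"""Stochastic switch model: LNA likelihood and reversible-jump MCMC.

The latent reporter system (mRNA M, protein P) is approximated by the linear
noise approximation: the macroscopic mean m(t) = (m_M, m_P) obeys

    dm_M/dt = beta(t) - delta_m * m_M
    dm_P/dt = alpha * m_M - delta_p * m_P

and fluctuations xi = (M, P) - m follow a linear Gaussian SDE with drift
matrix A = [[-delta_m, 0], [alpha, -delta_p]] and diffusion
D(t) = diag(beta(t) + delta_m m_M, alpha m_M + delta_p m_P) evaluated along
the mean.  With the observation Y = kappa P + N(0, sigma^2) this yields a
Gaussian state-space model whose likelihood is computed by a Kalman
recursion.  Because beta(t) is piecewise constant, the joint
(mean, accumulated process covariance) system is linear with constant
coefficients within each segment, so propagation uses exact matrix
exponentials of a 6x6 augmented generator: no ODE discretisation error.

The posterior over the switch number K, switch times, segment rates and
kinetic parameters is sampled with a Green-type reversible-jump MCMC using
birth / death / position-shift / rate-update / parameter-update moves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .types import (
    KineticParams,
    LuminescenceTrace,
    PosteriorEnsemble,
    PosteriorSample,
    PriorSpec,
    SwitchProfile,
)

__all__ = [
    "lna_loglik",
    "stationary_moments",
    "rjmcmc_run",
    "run_cohort",
    "make_default_priors",
    "MoveSettings",
]

_LOG2PI = math.log(2.0 * math.pi)


class _Reject(Exception):
    """Internal: proposal invalid or likelihood failed; count as rejection."""


# ---------------------------------------------------------------------------
# LNA moments and propagation
# ---------------------------------------------------------------------------

def stationary_moments(beta: float, params: KineticParams):
    """Stationary LNA mean and covariance under constant transcription.

    The mRNA marginal is Poisson (V_MM = mean); the protein variance picks up
    translational amplification through the mRNA-protein covariance.
    """
    dm, dp, al = params.delta_m, params.delta_p, params.alpha
    m_M = beta / dm
    m_P = al * beta / (dm * dp)
    v_mm = m_M
    v_mp = al * v_mm / (dm + dp)
    v_pp = al * (v_mp + m_M) / dp
    mean = np.array([m_M, m_P])
    cov = np.array([[v_mm, v_mp], [v_mp, v_pp]])
    return mean, cov


def _augmented_generator(beta: float, params: KineticParams) -> np.ndarray:
    """Constant-coefficient generator of x = (1, m_M, m_P, q_MM, q_MP, q_PP).

    q is the process covariance accumulated from q = 0 at the piece start:
    dq/dt = A q + q A' + D(m(t)), with D affine in the mean, hence the whole
    system is linear and exp(L h) propagates it exactly.  The constant
    (homogeneous) coordinate leads, making L lower triangular.
    """
    dm, dp, al = params.delta_m, params.delta_p, params.alpha
    L = np.zeros((6, 6))
    L[1, 0] = beta
    L[1, 1] = -dm
    L[2, 1] = al
    L[2, 2] = -dp
    L[3, 0] = beta
    L[3, 1] = dm
    L[3, 3] = -2.0 * dm
    L[4, 3] = al
    L[4, 4] = -(dm + dp)
    L[5, 1] = al
    L[5, 2] = dp
    L[5, 4] = 2.0 * al
    L[5, 5] = -2.0 * dp
    return L


def _phi(params: KineticParams, h: float) -> tuple[float, float, float]:
    """Fundamental matrix exp(A h) of the fluctuation drift (lower triangular).

    Returns (phi_mm, phi_pm, phi_pp); the (M <- P) entry is zero.
    """
    dm, dp, al = params.delta_m, params.delta_p, params.alpha
    e_m = math.exp(-dm * h)
    e_p = math.exp(-dp * h)
    if abs(dm - dp) < 1e-10 * max(dm, dp):
        pm = al * h * e_m
    else:
        pm = al * (e_m - e_p) / (dp - dm)
    return e_m, pm, e_p


def _expm_lower_triangular(M: np.ndarray) -> np.ndarray:
    """exp(M) for lower-triangular M by the Parlett recurrence.

    Falls back to scipy's general expm when two diagonal entries nearly
    coincide (confluent eigenvalues make the recurrence ill-conditioned).
    """
    n = M.shape[0]
    d = np.diag(M)
    scale = np.max(np.abs(d)) + 1.0
    for i in range(n):
        for j in range(i):
            if abs(d[i] - d[j]) < 1e-2 * scale:
                return expm(M)
    F = np.zeros_like(M)
    for i in range(n):
        F[i, i] = math.exp(d[i])
    for gap in range(1, n):
        for j in range(n - gap):
            i = j + gap
            acc = 0.0
            for k in range(j, i):
                acc += M[i, k] * F[k, j]
            for k in range(j + 1, i + 1):
                acc -= F[i, k] * M[k, j]
            F[i, j] = acc / (d[j] - d[i])
    return F


@dataclass
class _IntervalOp:
    """Exact propagation over one inter-observation interval."""

    T: np.ndarray  # 6x6 augmented propagator (possibly composed across a switch)
    phi: tuple[float, float, float]


def _build_interval_ops(trace_times: np.ndarray, profile: SwitchProfile,
                        params: KineticParams) -> list[_IntervalOp]:
    t0 = profile.window[0]
    cache: dict[tuple[float, float], np.ndarray] = {}
    phi_cache: dict[float, tuple[float, float, float]] = {}

    def seg_T(beta: float, h: float) -> np.ndarray:
        key = (beta, h)
        T = cache.get(key)
        if T is None:
            T = _expm_lower_triangular(_augmented_generator(beta, params) * h)
            cache[key] = T
        return T

    sw = profile.switch_times
    rates = profile.rates
    K = len(sw)
    ops: list[_IntervalOp] = []
    prev = t0
    seg = 0  # index of the segment containing prev
    while seg < K and sw[seg] <= prev + 1e-12:
        seg += 1
    for t_next in trace_times:
        t_next = float(t_next)
        if t_next < prev - 1e-9:
            raise ValueError("observation times not increasing within window")
        h_tot = round(t_next - prev, 12)
        if seg >= K or sw[seg] >= t_next - 1e-12:
            # whole interval in one segment: reuse the cached propagator
            T = seg_T(rates[seg], h_tot)
            while seg < K and sw[seg] <= t_next + 1e-12:
                seg += 1
        else:
            T = None
            a = prev
            while True:
                b = sw[seg] if (seg < K and sw[seg] < t_next - 1e-12) else t_next
                piece = seg_T(rates[seg], round(b - a, 12))
                T = piece if T is None else piece @ T
                if b >= t_next - 1e-12:
                    while seg < K and sw[seg] <= t_next + 1e-12:
                        seg += 1
                    break
                a = b
                seg += 1
        phi = phi_cache.get(h_tot)
        if phi is None:
            phi = _phi(params, h_tot)
            phi_cache[h_tot] = phi
        ops.append(_IntervalOp(T=T, phi=phi))
        prev = t_next
    return ops


def lna_loglik(trace: LuminescenceTrace, profile: SwitchProfile,
               params: KineticParams) -> float:
    """Gaussian state-space log-likelihood of a trace under a switch profile.

    Latent moments are initialised at the stationary law of the first
    segment's rate at the window start and propagated exactly (matrix
    exponentials within constant-rate pieces); observations are assimilated
    by scalar Kalman updates on Y = kappa * P + N(0, sigma^2).
    """
    t0, t1 = profile.window
    times = trace.times
    if times[0] < t0 - 1e-9 or times[-1] > t1 + 1e-9:
        raise ValueError("trace times extend beyond the profile window")
    kappa, sigma2 = params.kappa, params.sigma2

    mean0, cov0 = stationary_moments(profile.rates[0], params)
    ops = _build_interval_ops(times, profile, params)

    # filtered state (absolute coordinates) and macroscopic mean
    m_M, m_P = mean0
    mu_M, mu_P = mean0
    p11, p12, p22 = cov0[0, 0], cov0[0, 1], cov0[1, 1]
    ll = 0.0
    x = np.empty(6)
    for y, op in zip(trace.values, ops):
        # exact mean + accumulated process noise over the interval
        x[0] = 1.0
        x[1], x[2] = m_M, m_P
        x[3] = x[4] = x[5] = 0.0
        xn = op.T @ x
        mn_M, mn_P = xn[1], xn[2]
        q11, q12, q22 = xn[3], xn[4], xn[5]
        f11, f21, f22 = op.phi
        # predicted filtered mean: macroscopic mean + propagated deviation
        d_M, d_P = mu_M - m_M, mu_P - m_P
        mu_M = mn_M + f11 * d_M
        mu_P = mn_P + f21 * d_M + f22 * d_P
        # predicted covariance Phi P Phi' + Q (Phi lower triangular)
        a11 = f11 * p11
        a21 = f21 * p11 + f22 * p12
        a12 = f11 * p12
        a22 = f21 * p12 + f22 * p22
        p11 = a11 * f11 + q11
        p12 = a11 * f21 + a12 * f22 + q12
        p22 = a21 * f21 + a22 * f22 + q22
        m_M, m_P = mn_M, mn_P
        # scalar update on Y = kappa * P + eps
        S = kappa * kappa * p22 + sigma2
        if not (S > 0.0) or not math.isfinite(S):
            raise FloatingPointError(
                f"singular or invalid innovation variance S={S!r} "
                f"(params={params!r}, profile K={profile.n_switches})")
        resid = y - kappa * mu_P
        ll += -0.5 * (_LOG2PI + math.log(S) + resid * resid / S)
        g1 = kappa * p12 / S
        g2 = kappa * p22 / S
        mu_M += g1 * resid
        mu_P += g2 * resid
        p11 -= g1 * g1 * S
        p12 -= g1 * g2 * S
        p22 -= g2 * g2 * S
    if not math.isfinite(ll):
        raise FloatingPointError(
            f"non-finite log-likelihood (params={params!r}, "
            f"profile={profile.switch_times!r}/{profile.rates!r})")
    return ll


# ---------------------------------------------------------------------------
# Reversible-jump MCMC
# ---------------------------------------------------------------------------

@dataclass
class MoveSettings:
    """Proposal mixture and random-walk scales for the sampler.

    Probabilities are fixed; birth/death/shift draws that are impossible in
    the current state (K at a bound) are counted as rejections, which keeps
    the pairing p_birth(K) / p_death(K+1) constant and the chain reversible.
    """

    p_birth: float = 0.20
    p_death: float = 0.20
    p_shift: float = 0.20
    p_rate: float = 0.20
    # remainder: parameter update
    shift_sd: float = 0.75        # hours
    shift_uniform_prob: float = 0.3  # fraction of shifts repositioned uniformly
    # the parameter-update move receives the probability mass left over by
    # the four explicit weights; that remainder must not be negative
    rate_step_sd: float = 0.35    # log-rate random walk
    birth_split_sd: float = 0.60  # log-rate split perturbation
    delta_step_sd: float = 0.08   # log delta_m / delta_p
    alpha_step_sd: float = 0.15   # log alpha
    sigma2_step_sd: float = 0.30  # log sigma^2


class _ChainState:
    __slots__ = ("s", "logb", "log_dm", "log_dp", "log_al", "log_s2", "ll")

    def __init__(self, s, logb, log_dm, log_dp, log_al, log_s2, ll):
        self.s = s            # np.ndarray of switch times
        self.logb = logb      # np.ndarray of K+1 log rates
        self.log_dm = log_dm
        self.log_dp = log_dp
        self.log_al = log_al
        self.log_s2 = log_s2
        self.ll = ll

    @property
    def K(self) -> int:
        return len(self.s)

    def params(self) -> KineticParams:
        return KineticParams(delta_m=math.exp(self.log_dm),
                             delta_p=math.exp(self.log_dp),
                             alpha=math.exp(self.log_al),
                             kappa=1.0,
                             sigma=math.sqrt(math.exp(self.log_s2)))

    def profile(self, window) -> SwitchProfile:
        return SwitchProfile(tuple(self.s), tuple(np.exp(self.logb)), window)


def _normal_logpdf(x: float, mu: float, sd: float) -> float:
    z = (x - mu) / sd
    return -0.5 * (_LOG2PI + z * z) - math.log(sd)


def _log_prior(state: _ChainState, priors: PriorSpec, k_logpmf: np.ndarray,
               window_len: float) -> float:
    K = state.K
    lp = float(k_logpmf[K])
    lp += math.lgamma(K + 1) - K * math.log(window_len)  # uniform order stats
    for x in state.logb:
        lp += _normal_logpdf(x, priors.rate_log_median, priors.rate_log_sd)
    lp += _normal_logpdf(state.log_dm, priors.delta_m_log_median, priors.delta_m_log_sd)
    lp += _normal_logpdf(state.log_dp, priors.delta_p_log_median, priors.delta_p_log_sd)
    lp += _normal_logpdf(state.log_al, priors.alpha_log_median, priors.alpha_log_sd)
    a, b = priors.sigma2_a, priors.sigma2_b
    lp += a * math.log(b) - math.lgamma(a) - a * state.log_s2 - b * math.exp(-state.log_s2)
    return lp


def make_default_priors(traces: list[LuminescenceTrace],
                        degradation_priors: dict | None = None,
                        k_mean: float = 4.0) -> PriorSpec:
    """Data-scaled default priors for a dataset of traces.

    The rate prior's median is set from the pooled mean luminescence via the
    stationary relation beta = Y_bar * delta_m * delta_p / alpha (at the
    prior medians of the kinetic parameters, kappa = 1); the inverse-gamma
    scale of sigma^2 is anchored to a high-frequency noise estimate
    (median absolute first difference).  ``degradation_priors`` is the JSON
    mapping produced by :func:`pulseswitch.halflife.make_degradation_prior`,
    with entries ``{"delta_m": {median, log_sd}, "delta_p": ...}``.
    """
    priors = PriorSpec(k_mean=k_mean)
    if degradation_priors:
        if "delta_m" in degradation_priors:
            priors.delta_m_log_median = math.log(degradation_priors["delta_m"]["median"])
            priors.delta_m_log_sd = degradation_priors["delta_m"]["log_sd"]
        if "delta_p" in degradation_priors:
            priors.delta_p_log_median = math.log(degradation_priors["delta_p"]["median"])
            priors.delta_p_log_sd = degradation_priors["delta_p"]["log_sd"]
    pooled = np.concatenate([t.values for t in traces])
    y_bar = max(float(np.mean(pooled)), 1.0)
    dm = math.exp(priors.delta_m_log_median)
    dp = math.exp(priors.delta_p_log_median)
    al = math.exp(priors.alpha_log_median)
    priors.rate_log_median = math.log(y_bar * dm * dp / al)
    diffs = np.concatenate([np.diff(t.values) for t in traces])
    # first differences carry measurement noise twice plus slow process drift
    mad = float(np.median(np.abs(diffs))) / 0.6745
    s2_mode = max(mad * mad / 2.0, 1e-6)
    priors.sigma2_b = s2_mode * (priors.sigma2_a + 1.0)
    return priors


def _binary_segmentation(times: np.ndarray, values: np.ndarray,
                         max_k: int = 4, min_gap: float = 2.0) -> list[float]:
    """Greedy changepoint screen on the raw trace (initialisation only).

    Recursively splits at the time maximising the reduction in residual sum
    of squares of a piecewise-constant fit, accepting a split while the RSS
    improvement exceeds a BIC-style penalty.  Only used to start the chain
    near a sensible mode; the posterior itself is untouched.
    """
    n = len(values)
    penalty = 2.0 * math.log(n) * np.var(values) if n else 0.0
    segments = [(0, n)]
    cps: list[float] = []
    for _ in range(max_k):
        best = None
        for si, (a, b) in enumerate(segments):
            seg = values[a:b]
            if b - a < 8:
                continue
            css = np.cumsum(seg)
            tot = css[-1]
            rss0 = float(np.sum(seg * seg) - tot * tot / len(seg))
            for cut in range(4, len(seg) - 4):
                if times[a + cut] - times[a] < min_gap \
                        or times[b - 1] - times[a + cut] < min_gap:
                    continue
                left = css[cut - 1]
                rss = (np.sum(seg[:cut] ** 2) - left * left / cut
                       + np.sum(seg[cut:] ** 2) - (tot - left) ** 2 / (len(seg) - cut))
                gain = rss0 - rss
                if best is None or gain > best[0]:
                    best = (gain, si, cut)
        if best is None or best[0] < penalty:
            break
        _, si, cut = best
        a, b = segments[si]
        cps.append(float(times[a + cut]))
        segments[si:si + 1] = [(a, a + cut), (a + cut, b)]
    return sorted(cps)


def _initial_state(trace, priors, window, prior_only) -> _ChainState:
    dm = priors.delta_m_log_median
    dp = priors.delta_p_log_median
    al = priors.alpha_log_median
    diffs = np.diff(trace.values)
    mad = float(np.median(np.abs(diffs))) / 0.6745 if len(diffs) else 1.0
    log_s2 = math.log(max(mad * mad / 2.0, 1e-6))

    def to_logb(y_level: float) -> float:
        return math.log(max(y_level, 1.0)) + dm + dp - al

    if prior_only or len(trace) < 20:
        logb0 = to_logb(float(np.mean(trace.values)))
        return _ChainState(np.empty(0), np.array([logb0]), dm, dp, al, log_s2,
                           0.0 if prior_only else float("nan"))
    t_lo, t_hi = window
    cps = [s for s in _binary_segmentation(trace.times, trace.values)
           if t_lo + 0.5 < s < t_hi - 0.5]
    # protein responds with a delay ~1/delta_p; shift starts slightly early
    s = np.asarray(cps)
    edges = np.concatenate(([trace.times[0]], s, [trace.times[-1]]))
    logb = []
    for a, b in zip(edges[:-1], edges[1:]):
        mask = (trace.times >= a) & (trace.times < b)
        logb.append(to_logb(float(np.mean(trace.values[mask]))
                            if mask.any() else 1.0))
    logb = np.asarray(logb)
    # enforce strictly-differing adjacent rates
    for j in range(1, len(logb)):
        if logb[j] == logb[j - 1]:
            logb[j] += 1e-6
    return _ChainState(s, logb, dm, dp, al, log_s2, float("nan"))


def rjmcmc_run(
    trace: LuminescenceTrace,
    priors: PriorSpec,
    n_iter: int = 30_000,
    seed=None,
    moves: MoveSettings | None = None,
    prior_only: bool = False,
    burn_in: int | None = None,
    window: tuple[float, float] | None = None,
    min_trace_len: int = 10,
) -> PosteriorEnsemble:
    """Sample the joint switch-profile posterior for one trace.

    Trans-dimensional moves follow the standard reversible-jump recipe: a
    birth draws a new switch time uniformly on the window and splits the
    enclosing log-rate symmetrically by a Gaussian perturbation u (Jacobian
    2); death is the exact reverse.  With ``prior_only=True`` the likelihood
    is held at zero, so the chain targets the prior (used to validate the
    sampler against the stated K prior).  The first third of iterations is
    discarded as burn-in unless ``burn_in`` is given.
    """
    if len(trace) < min_trace_len and not prior_only:
        raise ValueError(f"trace must have at least {min_trace_len} observations")
    if priors.k_max < 0 or priors.k_mean <= 0:
        raise ValueError("invalid K prior")
    moves = moves or MoveSettings()
    if window is None:
        window = trace.window
    t_lo, t_hi = window
    T = t_hi - t_lo
    rng = np.random.default_rng(seed)
    k_logpmf = priors.k_log_pmf()

    def loglik(state: _ChainState) -> float:
        if prior_only:
            return 0.0
        return lna_loglik(trace, state.profile(window), state.params())

    state = _initial_state(trace, priors, window, prior_only)
    try:
        state.ll = loglik(state)
    except FloatingPointError:
        state = _initial_state(trace, priors, window, True)
        state.ll = loglik(state)
    lp = _log_prior(state, priors, k_logpmf, T)

    if burn_in is None:
        burn_in = n_iter // 3
    n_prop = {m: 0 for m in ("birth", "death", "shift", "rate", "param")}
    n_acc = dict.fromkeys(n_prop, 0)
    samples: list[PosteriorSample] = []

    p_b, p_d, p_s, p_r = moves.p_birth, moves.p_death, moves.p_shift, moves.p_rate
    if p_b + p_d + p_s + p_r > 1.0 + 1e-12:
        raise ValueError("move probabilities exceed 1")
    edges = np.cumsum([p_b, p_d, p_s, p_r])

    def _step(kind: str, K: int) -> None:
        nonlocal state, lp
        if kind == "birth" and K < priors.k_max:
            s_new = t_lo + T * rng.random()
            i = int(np.searchsorted(state.s, s_new))
            u = rng.normal(0.0, moves.birth_split_sd)
            logb_i = state.logb[i]
            new_s = np.insert(state.s, i, s_new)
            new_logb = np.insert(state.logb, i, 0.0)
            new_logb[i] = logb_i + u
            new_logb[i + 1] = logb_i - u
            prop = _ChainState(new_s, new_logb, state.log_dm, state.log_dp,
                               state.log_al, state.log_s2, float("nan"))
            try:
                prop.ll = loglik(prop)
            except FloatingPointError:
                raise _Reject from None
            lp_prop = _log_prior(prop, priors, k_logpmf, T)
            log_q_fwd = math.log(p_b) - math.log(T) + _normal_logpdf(
                u, 0.0, moves.birth_split_sd)
            log_q_rev = math.log(p_d) - math.log(K + 1)
            log_alpha = (prop.ll - state.ll) + (lp_prop - lp) \
                + log_q_rev - log_q_fwd + math.log(2.0)
            if math.log(rng.random()) < log_alpha:
                state, lp = prop, lp_prop
                n_acc[kind] += 1

        elif kind == "death" and K > 0:
            j = int(rng.integers(K))
            u = 0.5 * (state.logb[j] - state.logb[j + 1])
            merged = 0.5 * (state.logb[j] + state.logb[j + 1])
            new_s = np.delete(state.s, j)
            new_logb = np.delete(state.logb, j + 1)
            new_logb[j] = merged
            # merging may equalise adjacent rates only on a null set; guard anyway
            if np.any(np.diff(new_logb) == 0.0) and len(new_logb) > 1:
                raise _Reject
            prop = _ChainState(new_s, new_logb, state.log_dm, state.log_dp,
                               state.log_al, state.log_s2, float("nan"))
            try:
                prop.ll = loglik(prop)
            except FloatingPointError:
                raise _Reject from None
            lp_prop = _log_prior(prop, priors, k_logpmf, T)
            log_q_fwd = math.log(p_d) - math.log(K)
            log_q_rev = math.log(p_b) - math.log(T) + _normal_logpdf(
                u, 0.0, moves.birth_split_sd)
            log_alpha = (prop.ll - state.ll) + (lp_prop - lp) \
                + log_q_rev - log_q_fwd - math.log(2.0)
            if math.log(rng.random()) < log_alpha:
                state, lp = prop, lp_prop
                n_acc[kind] += 1

        elif kind == "shift" and K > 0:
            j = int(rng.integers(K))
            lo = state.s[j - 1] if j > 0 else t_lo
            hi = state.s[j + 1] if j < K - 1 else t_hi
            if rng.random() < moves.shift_uniform_prob:
                # independence reposition within the neighbour interval;
                # symmetric because the interval is unchanged by the move
                s_new = lo + (hi - lo) * rng.random()
            else:
                s_new = state.s[j] + rng.normal(0.0, moves.shift_sd)
            if not (lo < s_new < hi):
                raise _Reject
            new_s = state.s.copy()
            new_s[j] = s_new
            prop = _ChainState(new_s, state.logb, state.log_dm, state.log_dp,
                               state.log_al, state.log_s2, float("nan"))
            try:
                prop.ll = loglik(prop)
            except FloatingPointError:
                raise _Reject from None
            if math.log(rng.random()) < prop.ll - state.ll:
                state.s = new_s
                state.ll = prop.ll
                n_acc[kind] += 1

        elif kind == "rate":
            i = int(rng.integers(K + 1))
            step = rng.normal(0.0, moves.rate_step_sd)
            new_logb = state.logb.copy()
            new_logb[i] += step
            prop = _ChainState(state.s, new_logb, state.log_dm, state.log_dp,
                               state.log_al, state.log_s2, float("nan"))
            try:
                prop.ll = loglik(prop)
            except FloatingPointError:
                raise _Reject from None
            d_prior = _normal_logpdf(new_logb[i], priors.rate_log_median,
                                     priors.rate_log_sd) \
                - _normal_logpdf(state.logb[i], priors.rate_log_median,
                                 priors.rate_log_sd)
            if math.log(rng.random()) < (prop.ll - state.ll) + d_prior:
                state.logb = new_logb
                state.ll = prop.ll
                lp += d_prior
                n_acc[kind] += 1

        elif kind == "param":
            which = int(rng.integers(4))
            prop = _ChainState(state.s, state.logb, state.log_dm, state.log_dp,
                               state.log_al, state.log_s2, float("nan"))
            if which == 0:
                prop.log_dm += rng.normal(0.0, moves.delta_step_sd)
                d_prior = _normal_logpdf(prop.log_dm, priors.delta_m_log_median,
                                         priors.delta_m_log_sd) \
                    - _normal_logpdf(state.log_dm, priors.delta_m_log_median,
                                     priors.delta_m_log_sd)
            elif which == 1:
                prop.log_dp += rng.normal(0.0, moves.delta_step_sd)
                d_prior = _normal_logpdf(prop.log_dp, priors.delta_p_log_median,
                                         priors.delta_p_log_sd) \
                    - _normal_logpdf(state.log_dp, priors.delta_p_log_median,
                                     priors.delta_p_log_sd)
            elif which == 2:
                prop.log_al += rng.normal(0.0, moves.alpha_step_sd)
                d_prior = _normal_logpdf(prop.log_al, priors.alpha_log_median,
                                         priors.alpha_log_sd) \
                    - _normal_logpdf(state.log_al, priors.alpha_log_median,
                                     priors.alpha_log_sd)
            else:
                prop.log_s2 += rng.normal(0.0, moves.sigma2_step_sd)
                a, b = priors.sigma2_a, priors.sigma2_b
                d_prior = (-a * prop.log_s2 - b * math.exp(-prop.log_s2)) \
                    - (-a * state.log_s2 - b * math.exp(-state.log_s2))
            try:
                prop.ll = loglik(prop)
            except FloatingPointError:
                raise _Reject from None
            if math.log(rng.random()) < (prop.ll - state.ll) + d_prior:
                state = prop
                lp += d_prior
                n_acc[kind] += 1

    for it in range(n_iter):
        u_move = rng.random()
        if u_move < edges[0]:
            kind = "birth"
        elif u_move < edges[1]:
            kind = "death"
        elif u_move < edges[2]:
            kind = "shift"
        elif u_move < edges[3]:
            kind = "rate"
        else:
            kind = "param"
        n_prop[kind] += 1
        try:
            _step(kind, state.K)
        except _Reject:
            pass
        if it >= burn_in:
            samples.append(PosteriorSample(
                profile=state.profile(window),
                params=state.params(),
                iteration=it,
                log_lik=state.ll,
            ))

    acc = {m: (n_acc[m] / n_prop[m] if n_prop[m] else 0.0) for m in n_prop}
    if n_iter > 0 and all(v == 0.0 for v in acc.values()):
        warnings.warn("all move types had zero acceptance; consider smaller "
                      "proposal scales or checking the priors", RuntimeWarning)
    seed_int = None
    if seed is not None and not isinstance(seed, np.random.SeedSequence):
        seed_int = int(seed)
    return PosteriorEnsemble(cell_id=trace.cell_id, samples=samples,
                             n_iter=n_iter, burn_in=burn_in,
                             acceptance_rates=acc, seed=seed_int)


def run_cohort(
    traces: list[LuminescenceTrace],
    priors: PriorSpec,
    n_iter: int = 30_000,
    seed=None,
    moves: MoveSettings | None = None,
    hierarchical: bool = True,
    pilot_fraction: float = 0.4,
) -> list[PosteriorEnsemble | None]:
    """Run per-cell chains with an empirical-Bayes hierarchical pass.

    Individual kinetic parameters are unlikely to differ much between cells
    of one dataset, so the translation-rate and noise-variance priors are
    shared: a pilot pass runs shorter per-cell chains under the initial
    priors, the population hyperparameters (alpha location/scale, sigma^2
    scale) are re-estimated from the per-cell posterior medians, and final
    chains run under the updated priors.  Per-cell seeds are spawned
    deterministically from ``seed``.  A failing cell yields ``None`` in the
    output and does not abort the cohort.
    """
    if not traces:
        raise ValueError("need at least one trace")
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    if hierarchical and len(traces) > 1:
        pilot_seeds, final_seeds = ss.spawn(2)
        pilot_seeds = pilot_seeds.spawn(len(traces))
        final_seeds = final_seeds.spawn(len(traces))
        n_pilot = max(int(n_iter * pilot_fraction), 200)
        alphas, s2s = [], []
        for trace, cs in zip(traces, pilot_seeds):
            try:
                ens = rjmcmc_run(trace, priors, n_pilot, seed=cs, moves=moves)
                alphas.append(float(np.median([s.params.alpha for s in ens.samples])))
                s2s.append(float(np.median([s.params.sigma2 for s in ens.samples])))
            except (ValueError, FloatingPointError):
                continue
        if alphas:
            import copy

            priors = copy.copy(priors)
            log_a = np.log(alphas)
            priors.alpha_log_median = float(np.mean(log_a))
            priors.alpha_log_sd = max(float(np.std(log_a)), 0.1)
            priors.sigma2_b = float(np.median(s2s)) * (priors.sigma2_a + 1.0)
    else:
        final_seeds = ss.spawn(len(traces))

    out: list[PosteriorEnsemble | None] = []
    failures = []
    for trace, cs in zip(traces, final_seeds):
        try:
            out.append(rjmcmc_run(trace, priors, n_iter, seed=cs, moves=moves))
        except (ValueError, FloatingPointError) as exc:
            failures.append((trace.cell_id, repr(exc)))
            out.append(None)
    if failures:
        warnings.warn(f"{len(failures)} cell(s) failed inference: {failures}",
                      RuntimeWarning)
    return out
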