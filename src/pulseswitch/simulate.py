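"""Exact stochastic simulation of the reporter system and cohort synthesis.

Everything downstream (decay-rate fitting, switch inference, the three-state
refractory fit) is exercised against data from this module, so it emulates
the structure of live-cell luminescence recordings: ~48 h traces sampled
every 15 min, heterogeneous per-cell switch profiles with a single
activating up-switch followed by graded down-switches, intrinsic molecular
noise from the exact Gillespie algorithm, and additive Gaussian measurement
noise on the luminescence readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .types import KineticParams, LatentPath, LuminescenceTrace, SwitchProfile

__all__ = [
    "ssa_simulate",
    "synthesize_trace",
    "simulate_decay_experiment",
    "sample_three_state_durations",
    "CohortConfig",
    "Cohort",
    "make_cohort",
]


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _ssa_segment(rng, t, t_end, M, P, beta, delta_m, alpha, delta_p,
                 times, ms, ps, translation_const=None):
    """Gillespie loop with constant propensity coefficients on [t, t_end).

    ``translation_const`` replaces the alpha*M translation propensity with a
    constant (used for translation-inhibited decay experiments).  Appends
    events in place; returns the final (t, M, P).
    """
    while True:
        a_birth = beta
        a_mdeg = delta_m * M
        a_trans = alpha * M if translation_const is None else translation_const
        a_pdeg = delta_p * P
        a_tot = a_birth + a_mdeg + a_trans + a_pdeg
        if a_tot <= 0.0:
            return t_end, M, P
        t = t + rng.exponential(1.0 / a_tot)
        if t >= t_end:
            return t_end, M, P
        u = rng.random() * a_tot
        if u < a_birth:
            M += 1
        elif u < a_birth + a_mdeg:
            M -= 1
        elif u < a_birth + a_mdeg + a_trans:
            P += 1
        else:
            P -= 1
        times.append(t)
        ms.append(M)
        ps.append(P)


def stationary_initial_state(beta: float, params: KineticParams, seed) -> tuple[int, int]:
    """Draw (M0, P0) from the stationary law under constant transcription.

    The stationary mRNA marginal of the linear birth-death process is exactly
    Poisson(beta/delta_m); the protein marginal has no simple closed form, so
    it is drawn by running the SSA to equilibrium from the macroscopic mean.
    """
    rng = np.random.default_rng(seed)
    delta_m, delta_p, alpha = params.delta_m, params.delta_p, params.alpha
    M0 = int(rng.poisson(beta / delta_m))
    P0 = max(int(round(alpha * beta / (delta_m * delta_p))), 0)
    burn = 8.0 / min(delta_m, delta_p)
    times, ms, ps = [0.0], [M0], [P0]
    _, M, P = _ssa_segment(rng, 0.0, burn, M0, P0, beta, delta_m, alpha, delta_p,
                           times, ms, ps)
    return M, P


def ssa_simulate(
    profile: SwitchProfile,
    params: KineticParams,
    t_end: float | None = None,
    initial_state: tuple[int, int] | None = None,
    seed=None,
) -> LatentPath:
    """Exact Gillespie realisation of the reporter network under ``profile``.

    The transcription rate is constant within profile segments, so the
    simulation is exact: propensities are simply restarted at each switch
    time.  If ``initial_state`` is None, (M0, P0) is drawn from the
    stationary law of the first segment's rate (cells are observed
    mid-expression, so a transient-free start is the realistic default).
    """
    t0, t1 = profile.window
    if t_end is None:
        t_end = t1
    if t_end <= t0:
        raise ValueError("t_end must exceed the window start")
    if t_end > t1 + 1e-12:
        raise ValueError("profile does not extend to t_end")
    ss = _as_seedseq(seed)
    init_seed, path_seed = ss.spawn(2)
    if initial_state is None:
        M, P = stationary_initial_state(profile.rates[0], params, init_seed)
    else:
        M, P = int(initial_state[0]), int(initial_state[1])
        if M < 0 or P < 0:
            raise ValueError("initial counts must be non-negative")
    rng = np.random.default_rng(path_seed)
    edges = profile.segment_edges()
    times, ms, ps = [t0], [M], [P]
    t = t0
    for i, beta in enumerate(profile.rates):
        seg_end = min(float(edges[i + 1]), t_end)
        if seg_end <= t:
            continue
        t, M, P = _ssa_segment(rng, t, seg_end, M, P, beta,
                               params.delta_m, params.alpha, params.delta_p,
                               times, ms, ps)
        if seg_end >= t_end:
            break
    times.append(t_end)
    ms.append(M)
    ps.append(P)
    return LatentPath(np.asarray(times), np.asarray(ms, dtype=np.int64),
                      np.asarray(ps, dtype=np.int64))


def synthesize_trace(
    path: LatentPath,
    params: KineticParams,
    sample_times: np.ndarray,
    seed=None,
    cell_id: str = "cell",
    condition: str = "BSA",
) -> LuminescenceTrace:
    """Observe a latent path: Y(t_j) = kappa * P(t_j) + N(0, sigma^2)."""
    sample_times = np.asarray(sample_times, dtype=float)
    _, protein = path.at(sample_times)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, params.sigma, size=len(sample_times)) if params.sigma > 0 \
        else np.zeros(len(sample_times))
    values = params.kappa * protein.astype(float) + noise
    return LuminescenceTrace(cell_id=cell_id, times=sample_times, values=values,
                             condition=condition)


def simulate_decay_experiment(
    kind: str,
    params: KineticParams,
    t_inhibit: float,
    seed=None,
    beta: float = 20.0,
    t_end: float | None = None,
    dt: float = 0.25,
    deterministic: bool = False,
    cell_id: str = "decay",
) -> LuminescenceTrace:
    """Luminescence trace of an inhibitor experiment.

    The system is pre-equilibrated at constant transcription rate ``beta``;
    at ``t_inhibit`` either translation (``"cycloheximide"``) or
    transcription (``"actinomycinD"``) is blocked, leaving only the residual
    constant production c_p (protein) or c_m (mRNA).  With
    ``deterministic=True`` the macroscopic mean solution is returned instead
    of an SSA path (useful as a noise-free reference).
    """
    if kind not in ("cycloheximide", "actinomycinD"):
        raise ValueError(f"unknown inhibitor kind: {kind!r}")
    if t_end is None:
        t_end = t_inhibit + 12.0
    dm, dp, al, kp = params.delta_m, params.delta_p, params.alpha, params.kappa
    M0 = beta / dm
    P0 = al * beta / (dm * dp)
    grid = np.arange(0.0, t_end + dt / 2, dt)
    ss = _as_seedseq(seed)
    s_init, s_path, s_obs = ss.spawn(3)

    if deterministic:
        tau = np.maximum(grid - t_inhibit, 0.0)
        if kind == "cycloheximide":
            p_inf = params.c_p / dp
            prot = np.where(grid < t_inhibit, P0, p_inf + (P0 - p_inf) * np.exp(-dp * tau))
        else:
            m_inf = params.c_m / dm
            p_inf = al * params.c_m / (dm * dp)
            if abs(dm - dp) < 1e-9 * max(dm, dp):
                raise ValueError("deterministic two-exponential form needs delta_m != delta_p")
            B = al * (M0 - m_inf) / (dp - dm)
            A = P0 - p_inf - B
            prot = np.where(grid < t_inhibit,
                            P0,
                            p_inf + A * np.exp(-dp * tau) + B * np.exp(-dm * tau))
        values = kp * prot
        if params.sigma > 0:
            values = values + np.random.default_rng(s_obs).normal(0.0, params.sigma, len(grid))
        return LuminescenceTrace(cell_id=cell_id, times=grid, values=values,
                                 condition=kind)

    M, P = stationary_initial_state(beta, params, s_init)
    rng = np.random.default_rng(s_path)
    times, ms, ps = [0.0], [M], [P]
    t, M, P = _ssa_segment(rng, 0.0, t_inhibit, M, P, beta, dm, al, dp, times, ms, ps)
    if kind == "cycloheximide":
        t, M, P = _ssa_segment(rng, t, t_end, M, P, beta, dm, al, dp,
                               times, ms, ps, translation_const=params.c_p)
    else:
        t, M, P = _ssa_segment(rng, t, t_end, M, P, params.c_m, dm, al, dp,
                               times, ms, ps)
    times.append(t_end)
    ms.append(M)
    ps.append(P)
    path = LatentPath(np.asarray(times), np.asarray(ms, dtype=np.int64),
                      np.asarray(ps, dtype=np.int64))
    return synthesize_trace(path, params, grid, seed=s_obs, cell_id=cell_id,
                            condition=kind)


def sample_three_state_durations(
    T0: float,
    T1: float,
    T2: float,
    n_cells: int,
    t_end: float = 48.0,
    seed=None,
    n_cycles: int = 20,
) -> pd.DataFrame:
    """Durations from the three-state (on -> off -> primed -> on) cycle.

    On-periods are Exp(mean T0); the inactive period between a down-switch
    and the next up-switch is the sum of an off (refractory) period
    Exp(mean T1) and a primed period Exp(mean T2), i.e. hypoexponential.
    Each cell alternates on / inactive until ``t_end``; the final duration is
    truncated there and flagged right-censored.  ``t_end=inf`` yields exactly
    ``n_cycles`` uncensored on/inactive pairs per cell.

    Returns a tidy frame with columns cell_id, kind ("after_up"/"after_down"),
    value (hours), censored.
    """
    if min(T0, T1, T2) <= 0:
        raise ValueError("state mean durations must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_cells):
        cid = f"cell{c:03d}"
        if not np.isfinite(t_end):
            for _ in range(n_cycles):
                rows.append((cid, "after_up", rng.exponential(T0), False))
                rows.append((cid, "after_down",
                             rng.exponential(T1) + rng.exponential(T2), False))
            continue
        t = 0.0
        on = True
        while True:
            dur = rng.exponential(T0) if on else rng.exponential(T1) + rng.exponential(T2)
            kind = "after_up" if on else "after_down"
            if t + dur >= t_end:
                rows.append((cid, kind, t_end - t, True))
                break
            rows.append((cid, kind, dur, False))
            t += dur
            on = not on
    return pd.DataFrame(rows, columns=["cell_id", "kind", "value", "censored"])


@dataclass
class CohortConfig:
    """Generation law for a synthetic cohort of single-cell traces.

    Defaults emulate the observed recordings: 48 h at 15-min sampling with a
    single all-or-nothing up-switch followed by several graded down-switches
    of decreasing amplitude.  Rates are mRNA/h; ``sigma`` is in luminescence
    units on a kappa=1 scale where one protein contributes one unit.
    """

    n_cells: int = 60
    t_end: float = 48.0
    dt: float = 0.25
    condition: str = "BSA"
    profile_law: str = "up_graded_down"  # | "pulsatile" | "constant"
    baseline_rate: float = 6.0
    up_fold_range: tuple[float, float] = (10.0, 20.0)
    down_fold_range: tuple[float, float] = (3.0, 6.0)
    n_down_range: tuple[int, int] = (2, 4)
    up_time_range: tuple[float, float] = (8.0, 20.0)
    down_gap_range: tuple[float, float] = (5.0, 9.0)
    # pulsatile law: repeated activation cycles; the inactive gap between
    # the end of a descent and the next up-switch is hypoexponential
    # (off + primed sojourns of the three-state model)
    active_hold_range: tuple[float, float] = (3.0, 6.0)
    down_step_gap_range: tuple[float, float] = (2.0, 4.0)
    refractory_T1: float = 2.0
    primed_T2: float = 6.0
    delta_m: float = 0.6
    delta_p: float = 0.35
    alpha: float = 5.0
    kappa: float = 1.0
    sigma: float = 10.0
    alpha_jitter_log_sd: float = 0.0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.profile_law not in ("up_graded_down", "pulsatile", "constant"):
            raise ValueError(f"unknown profile_law: {self.profile_law!r}")
        for name in ("t_end", "dt", "baseline_rate", "delta_m", "delta_p",
                     "alpha", "kappa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.sigma < 0 or self.alpha_jitter_log_sd < 0:
            raise ValueError("noise scales must be >= 0")
        lo, hi = self.n_down_range
        if lo < 1 or hi < lo:
            raise ValueError("n_down_range must be an increasing range >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown cohort config keys: {sorted(extra)}")
        d = dict(d)
        for key in ("up_fold_range", "down_fold_range", "n_down_range",
                    "up_time_range", "down_gap_range", "active_hold_range",
                    "down_step_gap_range"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class Cohort:
    """A simulated cohort plus its ground truth."""

    traces: list[LuminescenceTrace]
    profiles: list[SwitchProfile]
    params: list[KineticParams]
    config: CohortConfig
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.traces)


def _draw_pulsatile(cfg: CohortConfig, rng) -> SwitchProfile:
    """Repeated activation cycles: up-switch, brief hold at the high rate,
    graded down-steps back toward baseline, inactive gap, re-activation."""
    window = (0.0, cfg.t_end)
    base = cfg.baseline_rate * rng.uniform(0.8, 1.25)
    times: list[float] = []
    rates: list[float] = [base]
    t = rng.uniform(0.5, 4.0)  # recording starts mid-cycle somewhere
    while True:
        gap = rng.exponential(cfg.refractory_T1) + rng.exponential(cfg.primed_T2)
        t_up = t + max(gap, 1.0)
        if t_up >= cfg.t_end - 4.0:
            break
        fold = rng.uniform(*cfg.up_fold_range)
        up_rate = rates[-1] * fold
        times.append(t_up)
        rates.append(up_rate)
        n_down = int(rng.integers(cfg.n_down_range[0], cfg.n_down_range[1] + 1))
        # distribute the descent over the down steps, returning near baseline
        total_log = np.log(fold / rng.uniform(0.7, 1.4))
        w = rng.uniform(0.8, 1.2, size=n_down)
        w = w / w.sum()
        t_cursor = t_up + rng.uniform(*cfg.active_hold_range)
        r = up_rate
        for j in range(n_down):
            if t_cursor >= cfg.t_end - 1.0:
                break
            r = r / float(np.exp(w[j] * total_log))
            if r == rates[-1]:
                r *= 1.0 + 1e-9
            times.append(t_cursor)
            rates.append(r)
            t_cursor += rng.uniform(*cfg.down_step_gap_range)
        t = t_cursor
    return SwitchProfile(tuple(times), tuple(rates), window)


def _draw_profile(cfg: CohortConfig, rng) -> SwitchProfile:
    window = (0.0, cfg.t_end)
    if cfg.profile_law == "constant":
        return SwitchProfile((), (cfg.baseline_rate,), window)
    if cfg.profile_law == "pulsatile":
        return _draw_pulsatile(cfg, rng)
    base = cfg.baseline_rate * rng.uniform(0.8, 1.25)
    # clamp the activation window for short recordings
    up_lo = min(cfg.up_time_range[0], 0.25 * cfg.t_end)
    up_hi = min(cfg.up_time_range[1], 0.5 * cfg.t_end)
    up_t = rng.uniform(up_lo, up_hi)
    up_rate = base * rng.uniform(*cfg.up_fold_range)
    n_down = int(rng.integers(cfg.n_down_range[0], cfg.n_down_range[1] + 1))
    times = [up_t]
    rates = [base, up_rate]
    r = up_rate
    t = up_t
    for _ in range(n_down):
        t = t + rng.uniform(*cfg.down_gap_range)
        if t >= cfg.t_end - 1.0:
            break
        r = r / rng.uniform(*cfg.down_fold_range)
        times.append(t)
        rates.append(r)
    return SwitchProfile(tuple(times), tuple(rates), window)


def make_cohort(config: CohortConfig | dict | None = None, seed=None) -> Cohort:
    """Simulate a cohort of luminescence traces with known switch profiles.

    All randomness flows from ``seed``: per-cell streams are spawned from it,
    so identical seeds give byte-identical cohorts.
    """
    if config is None:
        config = CohortConfig()
    elif isinstance(config, dict):
        config = CohortConfig.from_dict(config)
    config.validate()
    ss = _as_seedseq(seed)
    cell_seeds = ss.spawn(config.n_cells)
    grid = np.arange(0.0, config.t_end + config.dt / 2, config.dt)
    traces, profiles, params_list = [], [], []
    for i, cs in enumerate(cell_seeds):
        s_prof, s_path, s_obs, s_par = cs.spawn(4)
        rng = np.random.default_rng(s_prof)
        profile = _draw_profile(config, rng)
        alpha = config.alpha
        if config.alpha_jitter_log_sd > 0:
            alpha *= np.exp(np.random.default_rng(s_par).normal(0.0, config.alpha_jitter_log_sd))
        params = KineticParams(delta_m=config.delta_m, delta_p=config.delta_p,
                               alpha=alpha, kappa=config.kappa, sigma=config.sigma)
        path = ssa_simulate(profile, params, seed=s_path)
        trace = synthesize_trace(path, params, grid, seed=s_obs,
                                 cell_id=f"cell{i:03d}", condition=config.condition)
        traces.append(trace)
        profiles.append(profile)
        params_list.append(params)
    return Cohort(traces=traces, profiles=profiles, params=params_list,
                  config=config, seed=seed)
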