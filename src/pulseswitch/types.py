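"""Core domain containers for the stochastic switch model pipeline.

The reporter system is the standard two-stage gene expression cascade

    0 --beta(t)--> mRNA --delta_m--> 0
    mRNA --alpha--> mRNA + Protein --delta_p--> 0

observed through a luminescence readout Y(t) = kappa * P(t) + eps,
eps ~ N(0, sigma^2).  Transcription is piecewise constant: ``beta(t)`` holds
rate ``rates[i]`` on the half-open interval ``[s_{i-1}, s_i)`` where ``s_0``
is the window start and ``s_{K+1}`` the window end.  Times are in hours,
rates in molecules per hour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

__all__ = [
    "SwitchProfile",
    "KineticParams",
    "LatentPath",
    "LuminescenceTrace",
    "PriorSpec",
    "PosteriorSample",
    "PosteriorEnsemble",
    "DecayFit",
    "Phase",
    "SwitchCandidate",
    "SubModel",
    "DurationSample",
    "ThreeStateEstimate",
]


@dataclass(frozen=True)
class SwitchProfile:
    """Piecewise-constant transcription function on a window ``[t0, t1)``.

    ``switch_times`` holds the K strictly increasing interior switch times;
    ``rates`` holds the K+1 segment rates, ``rates[i]`` applying on
    ``[s_{i-1}, s_i)``.  A binary (telegraph) profile is the special case of
    two alternating rate levels.
    """

    switch_times: tuple[float, ...]
    rates: tuple[float, ...]
    window: tuple[float, float] = (0.0, 48.0)

    def __post_init__(self) -> None:
        st = tuple(float(s) for s in self.switch_times)
        rt = tuple(float(r) for r in self.rates)
        object.__setattr__(self, "switch_times", st)
        object.__setattr__(self, "rates", rt)
        t0, t1 = self.window
        if not t1 > t0:
            raise ValueError("window must have positive length")
        if len(rt) != len(st) + 1:
            raise ValueError(
                f"need K+1 rates for K switches (got {len(rt)} rates, {len(st)} switches)"
            )
        if any(r < 0 for r in rt):
            raise ValueError("transcription rates must be non-negative")
        if any(not (t0 < s < t1) for s in st):
            raise ValueError("switch times must lie strictly inside the window")
        if any(b >= a for a, b in zip(st[1:], st[:-1])):
            raise ValueError("switch times must be strictly increasing")
        if any(a == b for a, b in zip(rt[:-1], rt[1:])):
            raise ValueError("adjacent rates must differ (null switches disallowed)")

    @property
    def n_switches(self) -> int:
        return len(self.switch_times)

    def rate_at(self, t: float | np.ndarray) -> np.ndarray:
        """beta(t); vectorised, right-continuous at switch times."""
        idx = np.searchsorted(self.switch_times, np.asarray(t, dtype=float), side="right")
        return np.asarray(self.rates, dtype=float)[idx]

    def segment_edges(self) -> np.ndarray:
        """Window start, switch times, window end as one increasing array."""
        return np.concatenate(([self.window[0]], self.switch_times, [self.window[1]]))


@dataclass(frozen=True)
class KineticParams:
    """Per-cell kinetic and measurement parameters.

    delta_m, delta_p : mRNA / protein degradation rates (1/h)
    alpha            : translation rate (protein per mRNA per hour)
    kappa            : luminescence units per protein molecule
    sigma            : measurement noise s.d. (luminescence units)
    c_p, c_m         : residual production constants for inhibitor decay
                       experiments (leaky translation / transcription)
    """

    delta_m: float
    delta_p: float
    alpha: float
    kappa: float = 1.0
    sigma: float = 0.0
    c_p: float = 0.0
    c_m: float = 0.0

    def __post_init__(self) -> None:
        for name in ("delta_m", "delta_p", "alpha", "kappa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.c_p < 0 or self.c_m < 0:
            raise ValueError("residual constants must be >= 0")

    @property
    def sigma2(self) -> float:
        return self.sigma**2


@dataclass(frozen=True)
class LatentPath:
    """Event-resolved latent molecular path from an exact SSA realisation.

    Counts are piecewise constant: state ``(mrna[i], protein[i])`` holds on
    ``[times[i], times[i+1])``.
    """

    times: np.ndarray
    mrna: np.ndarray
    protein: np.ndarray

    def at(self, t: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """State at arbitrary times within the path support."""
        t = np.asarray(t, dtype=float)
        if np.any(t < self.times[0]) or np.any(t > self.times[-1]):
            raise ValueError("query times outside path support")
        idx = np.searchsorted(self.times, t, side="right") - 1
        idx = np.clip(idx, 0, len(self.times) - 1)
        return self.mrna[idx], self.protein[idx]


@dataclass(frozen=True)
class LuminescenceTrace:
    """One cell's observed reporter intensity series.

    Values are background-subtracted and may be negative.  The censoring
    flags mark whether activity is truncated by the recording window
    (start of imaging, end of imaging or cell division).
    """

    cell_id: str
    times: np.ndarray
    values: np.ndarray
    condition: str = "BSA"
    left_censored: bool = True
    right_censored: bool = True

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", y)
        if t.ndim != 1 or y.shape != t.shape:
            raise ValueError("times and values must be 1-D and equal length")
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("values must be finite")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def window(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


@dataclass
class PriorSpec:
    """Priors for the switch-model posterior.

    Switch count K: truncated Poisson(``k_mean``) on 0..``k_max``; switch
    times: uniform order statistics on the observation window; rates and
    positive kinetic parameters: log-normal (location = log median);
    measurement variance sigma^2: inverse-gamma(a, b).
    """

    k_mean: float = 4.0
    k_max: int = 20
    rate_log_median: float = np.log(8.0)
    rate_log_sd: float = 1.5
    delta_m_log_median: float = np.log(0.6)
    delta_m_log_sd: float = 0.15
    delta_p_log_median: float = np.log(0.35)
    delta_p_log_sd: float = 0.15
    alpha_log_median: float = np.log(5.0)
    alpha_log_sd: float = 0.7
    sigma2_a: float = 2.0
    sigma2_b: float = 200.0

    def k_log_pmf(self) -> np.ndarray:
        """Log pmf of the truncated Poisson prior on K = 0..k_max."""
        from scipy import stats

        k = np.arange(self.k_max + 1)
        logp = stats.poisson.logpmf(k, self.k_mean)
        return logp - np.logaddexp.reduce(logp)


@dataclass(frozen=True)
class PosteriorSample:
    """One retained MCMC state: a switch profile plus kinetic parameters."""

    profile: SwitchProfile
    params: KineticParams
    iteration: int
    log_lik: float


@dataclass
class PosteriorEnsemble:
    """Post-burn-in reversible-jump MCMC samples for one cell."""

    cell_id: str
    samples: list[PosteriorSample]
    n_iter: int
    burn_in: int
    acceptance_rates: dict[str, float] = field(default_factory=dict)
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def k_values(self) -> np.ndarray:
        return np.array([s.profile.n_switches for s in self.samples], dtype=int)

    def pooled_switch_times(self) -> np.ndarray:
        """All sampled switch times across iterations (the marginal posterior)."""
        out = [t for s in self.samples for t in s.profile.switch_times]
        return np.asarray(out, dtype=float)


@dataclass(frozen=True)
class DecayFit:
    """Degradation-rate fit from an inhibitor-induced decay trace."""

    rate: float
    residual_const: float
    fit_rss: float
    n_points: int

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("degradation rate must be > 0")
        if self.residual_const < 0:
            raise ValueError("residual constant must be >= 0")

    @property
    def half_life(self) -> float:
        return float(np.log(2.0) / self.rate)


@dataclass(frozen=True)
class Phase:
    """One constant-rate transcription phase of a cell's profile."""

    cell_id: str
    start: float
    end: float
    rate: float
    entering_direction: str  # "up" | "down" | "start"
    left_censored: bool
    right_censored: bool

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError("phase must have positive duration")
        if self.entering_direction not in ("up", "down", "start"):
            raise ValueError("entering_direction must be up/down/start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class SwitchCandidate:
    """A discrete switch location from the mixture fit of pooled switch times."""

    location: float
    credible_interval: tuple[float, float]
    mixture_weight: float
    component_sd: float

    def __post_init__(self) -> None:
        lo, hi = self.credible_interval
        if not (lo <= self.location <= hi):
            raise ValueError("location must lie inside its credible interval")
        if not (0 < self.mixture_weight <= 1):
            raise ValueError("mixture weight must be in (0, 1]")


@dataclass(frozen=True)
class SubModel:
    """A mutually exclusive switch-subset model with its sampled frequency."""

    included_candidates: tuple[int, ...]
    weight: float
    representative_profile: SwitchProfile


@dataclass(frozen=True)
class DurationSample:
    """A merged inter-switch duration, labelled by the entering direction."""

    value: float
    censored: bool
    kind: str  # "after_down" | "after_up"
    cell_id: str = ""

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("duration must be > 0")
        if self.kind not in ("after_down", "after_up"):
            raise ValueError("kind must be after_down or after_up")


@dataclass(frozen=True)
class ThreeStateEstimate:
    """Fitted mean durations of the on / off (refractory) / primed states.

    T1 < T2 by estimation constraint; lambda1 = 1/T1, lambda2 = 1/T2.
    """

    T0: float
    T1: float
    T2: float
    loglik: float
    n_complete: int
    n_censored: int
    beta_L: float = float("nan")
    beta_H: float = float("nan")
    bootstrap_summary: dict | None = None

    def __post_init__(self) -> None:
        if min(self.T0, self.T1, self.T2) <= 0:
            raise ValueError("state mean durations must be > 0")
        if not self.T1 < self.T2:
            raise ValueError("identifiability constraint T1 < T2 violated")

    @property
    def lambda1(self) -> float:
        return 1.0 / self.T1

    @property
    def lambda2(self) -> float:
        return 1.0 / self.T2
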