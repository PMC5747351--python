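"""Turn raw switch-posterior samples into discrete candidates and a consensus.

The marginal posterior of switch times pooled over MCMC iterations is
multimodal: each mode is one putative switch.  A Gaussian mixture is fitted
to the pooled times (component count chosen by BIC) and each fitted
component becomes a switch candidate with a location and credible interval.
Every iteration's switch set is then mapped onto the candidates, so each
distinct candidate subset is a sub-model whose weight is its sampling
frequency; the highest-weight sub-model's representative profile is the
consensus transcription profile for the cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .types import PosteriorEnsemble, SubModel, SwitchCandidate, SwitchProfile

__all__ = [
    "fit_switch_mixture",
    "assign_and_enumerate",
    "consensus_profile",
    "SubModelTable",
]

MAX_CANDIDATES = 10  # sub-model enumeration capped at 2**10 subsets


def fit_switch_mixture(ensemble: PosteriorEnsemble,
                       max_components: int = MAX_CANDIDATES,
                       seed: int = 0,
                       min_separation: float = 1.0) -> list[SwitchCandidate]:
    """Gaussian-mixture fit of the pooled marginal switch-time posterior.

    Component counts 1..max_components are scored by BIC; candidates are
    returned ordered by location with 95% credible intervals from the
    component Gaussian quantiles.  Components closer than ``min_separation``
    hours are merged: switches nearer than the system's temporal resolution
    describe the same event, and BIC happily splits one heavy posterior mode
    into two overlapping Gaussians.  An ensemble that never visited K > 0
    yields an empty candidate list.
    """
    if len(ensemble) == 0:
        raise ValueError("empty posterior ensemble")
    pooled = ensemble.pooled_switch_times()
    if len(pooled) == 0:
        return []
    X = pooled.reshape(-1, 1)
    best = None
    best_bic = np.inf
    n_max = min(max_components, len(np.unique(pooled)), len(pooled))
    for n in range(1, max(n_max, 1) + 1):
        gm = None
        for attempt in range(3):
            cand = GaussianMixture(n_components=n, covariance_type="full",
                                   reg_covar=1e-4, n_init=2,
                                   random_state=seed + attempt)
            cand.fit(X)
            if cand.converged_:
                gm = cand
                break
        if gm is None:
            raise RuntimeError(f"mixture EM failed to converge for {n} components")
        bic = gm.bic(X)
        if bic < best_bic:
            best_bic = bic
            best = gm
    means = best.means_.ravel()
    sds = np.sqrt(best.covariances_.reshape(-1))
    weights = best.weights_
    order = np.argsort(means)
    out = []
    for i in order:
        mu, sd, w = float(means[i]), float(sds[i]), float(weights[i])
        out.append(SwitchCandidate(
            location=mu,
            credible_interval=(mu - 1.959964 * sd, mu + 1.959964 * sd),
            mixture_weight=w,
            component_sd=sd,
        ))
    return _merge_close_candidates(out, MAX_CANDIDATES, min_separation)


def _merge_close_candidates(cands: list[SwitchCandidate], max_n: int,
                            min_separation: float = 0.0) -> list[SwitchCandidate]:
    """Merge closest candidate pairs until separated and at most ``max_n``."""
    cands = sorted(cands, key=lambda c: c.location)
    while len(cands) > 1:
        gaps = [b.location - a.location for a, b in zip(cands, cands[1:])]
        i = int(np.argmin(gaps))
        if len(cands) <= max_n and gaps[i] >= min_separation:
            break
        a, b = cands[i], cands[i + 1]
        w = a.mixture_weight + b.mixture_weight
        mu = (a.mixture_weight * a.location + b.mixture_weight * b.location) / w
        var = (a.mixture_weight * (a.component_sd**2 + (a.location - mu) ** 2)
               + b.mixture_weight * (b.component_sd**2 + (b.location - mu) ** 2)) / w
        sd = float(np.sqrt(var))
        merged = SwitchCandidate(location=mu,
                                 credible_interval=(mu - 1.959964 * sd,
                                                    mu + 1.959964 * sd),
                                 mixture_weight=w, component_sd=sd)
        cands[i:i + 2] = [merged]
    return cands


@dataclass
class SubModelTable:
    """Sub-models of one cell plus assignment diagnostics.

    Iterates like a list of :class:`SubModel`.  ``n_ambiguous`` counts
    sampled switches whose best-candidate responsibility fell below 0.5 and
    were assigned to the nearest candidate.
    """

    submodels: list[SubModel] = field(default_factory=list)
    n_ambiguous: int = 0

    def __iter__(self):
        return iter(self.submodels)

    def __len__(self):
        return len(self.submodels)

    def __getitem__(self, i):
        return self.submodels[i]

    def weight_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"candidates": sm.included_candidates, "weight": sm.weight,
              "n_switches": sm.representative_profile.n_switches}
             for sm in self.submodels])


def _assign_iterations(ensemble, locs, sds, wts, responsibility_threshold):
    n_ambiguous = 0
    assignments: list[tuple[int, ...]] = []
    for s in ensemble.samples:
        ids = set()
        for t in s.profile.switch_times:
            z = (t - locs) / sds
            logr = np.log(wts) - 0.5 * z * z - np.log(sds)
            logr -= np.logaddexp.reduce(logr)
            k = int(np.argmax(logr))
            if np.exp(logr[k]) < responsibility_threshold:
                n_ambiguous += 1
                k = int(np.argmin(np.abs(t - locs)))
            ids.add(k)
        assignments.append(tuple(sorted(ids)))
    return assignments, n_ambiguous


def _merge_exclusive_alternatives(candidates, assignments,
                                  exclusivity: float = 0.2):
    """Merge adjacent candidates that (almost) never co-occur.

    Two genuinely distinct switches are sampled together in most
    iterations; two mixture components that are rarely present in the same
    iteration are alternative placements of one uncertain switch and are
    collapsed into a single candidate carrying their combined mass.
    Returns the merged candidate list, or None if nothing merged.
    """
    n = len(candidates)
    if n < 2:
        return None
    present = np.zeros((len(assignments), n), dtype=bool)
    for i, key in enumerate(assignments):
        present[i, list(key)] = True
    counts = present.sum(axis=0).astype(float)
    for j in range(n - 1):
        a, b = j, j + 1
        if counts[a] == 0 or counts[b] == 0:
            continue
        both = float(np.logical_and(present[:, a], present[:, b]).sum())
        if both / min(counts[a], counts[b]) < exclusivity:
            ca, cb = candidates[a], candidates[b]
            wa, wb = counts[a], counts[b]
            w = wa + wb
            mu = (wa * ca.location + wb * cb.location) / w
            var = (wa * (ca.component_sd**2 + (ca.location - mu) ** 2)
                   + wb * (cb.component_sd**2 + (cb.location - mu) ** 2)) / w
            sd = float(np.sqrt(var))
            merged = SwitchCandidate(
                location=mu,
                credible_interval=(mu - 1.959964 * sd, mu + 1.959964 * sd),
                mixture_weight=ca.mixture_weight + cb.mixture_weight,
                component_sd=sd)
            out = list(candidates)
            out[a:a + 2] = [merged]
            return out
    return None


def assign_and_enumerate(ensemble: PosteriorEnsemble,
                         candidates: list[SwitchCandidate],
                         responsibility_threshold: float = 0.5,
                         merge_exclusive: bool = True) -> SubModelTable:
    """Map each iteration's switches to candidates and enumerate sub-models.

    Each sampled switch is assigned to the candidate with maximal mixture
    responsibility; each distinct candidate subset observed across
    iterations becomes a sub-model weighted by its sampling frequency, so
    sub-model weights sum to one per cell.  Adjacent candidates that almost
    never co-occur within an iteration are first collapsed (they are
    alternative placements of one switch, not two switches).  Representative
    segment rates are the posterior means of beta evaluated at segment
    midpoints, conditional on the iterations belonging to the sub-model.
    """
    if len(ensemble) == 0:
        raise ValueError("empty posterior ensemble")
    window = ensemble.samples[0].profile.window
    if not candidates:
        # only the zero-switch sub-model exists
        rate = float(np.mean([s.profile.rates[0] for s in ensemble.samples]))
        prof = SwitchProfile((), (rate,), window)
        return SubModelTable([SubModel((), 1.0, prof)], 0)

    candidates = list(candidates)
    while True:
        locs = np.array([c.location for c in candidates])
        sds = np.array([max(c.component_sd, 1e-6) for c in candidates])
        wts = np.array([c.mixture_weight for c in candidates])
        wts = wts / wts.sum()
        assignments, n_ambiguous = _assign_iterations(
            ensemble, locs, sds, wts, responsibility_threshold)
        if not merge_exclusive:
            break
        merged = _merge_exclusive_alternatives(candidates, assignments)
        if merged is None:
            break
        candidates = merged

    counts: dict[tuple[int, ...], int] = {}
    members: dict[tuple[int, ...], list[int]] = {}
    for i, key in enumerate(assignments):
        counts[key] = counts.get(key, 0) + 1
        members.setdefault(key, []).append(i)

    n_total = len(assignments)
    submodels = []
    for key, cnt in sorted(counts.items(), key=lambda kv: (-kv[1], len(kv[0]))):
        sw_times = tuple(float(locs[k]) for k in key)
        edges = np.concatenate(([window[0]], sw_times, [window[1]]))
        mids = 0.5 * (edges[:-1] + edges[1:])
        rates = np.zeros(len(mids))
        for i in members[key]:
            rates += ensemble.samples[i].profile.rate_at(mids)
        rates /= cnt
        # averaged rates may coincide on degenerate posteriors; nudge
        for j in range(1, len(rates)):
            if rates[j] == rates[j - 1]:
                rates[j] *= 1.0 + 1e-9
                rates[j] += 1e-12
        prof = SwitchProfile(sw_times, tuple(rates), window)
        submodels.append(SubModel(key, cnt / n_total, prof))
    return SubModelTable(submodels, n_ambiguous)


def consensus_profile(submodels: SubModelTable | list[SubModel],
                      strategy: str = "median",
                      edge_guard_h: float = 1.0
                      ) -> tuple[SwitchProfile, pd.DataFrame]:
    """Extract a single most-probable transcription profile.

    ``strategy="median"`` (default) builds the median-probability model: a
    candidate switch is included iff its inclusion frequency over the
    weighted sub-models exceeds 0.5, and segment rates are the sub-model-
    weighted posterior mean of beta at the segment midpoints.  This is far
    more stable than the modal subset when weights fragment over many
    near-null-switch subsets.  Candidates closer than ``edge_guard_h`` to a
    window edge are never included: a switch with less than the temporal
    resolution's worth of data on one side is unidentifiable, and posterior
    mass accumulates at the edges where the likelihood is indifferent.
    ``strategy="map"`` returns the highest-weight sub-model's representative
    profile, ties broken toward fewer switches.  The full weight table is
    returned alongside for probability-weighted downstream statistics.
    """
    sms = list(submodels)
    if not sms:
        raise ValueError("need at least one sub-model")
    table = pd.DataFrame(
        [{"candidates": sm.included_candidates, "weight": sm.weight,
          "n_switches": sm.representative_profile.n_switches}
         for sm in sms])
    if strategy == "map":
        best = sorted(sms, key=lambda sm: (-sm.weight,
                                           sm.representative_profile.n_switches))[0]
        return best.representative_profile, table
    if strategy != "median":
        raise ValueError(f"unknown consensus strategy: {strategy!r}")
    incl: dict[int, float] = {}
    for sm in sms:
        for c in sm.included_candidates:
            incl[c] = incl.get(c, 0.0) + sm.weight
    window = sms[0].representative_profile.window
    loc_all: dict[int, float] = {}
    for sm in sms:
        for c, t in zip(sm.included_candidates,
                        sm.representative_profile.switch_times):
            loc_all.setdefault(c, t)
    chosen = sorted(
        c for c, f in incl.items()
        if f > 0.5 and window[0] + edge_guard_h <= loc_all[c]
        <= window[1] - edge_guard_h)
    sw_times = tuple(loc_all[c] for c in chosen)
    edges = np.concatenate(([window[0]], sw_times, [window[1]]))
    mids = 0.5 * (edges[:-1] + edges[1:])
    rates = np.zeros(len(mids))
    for sm in sms:
        rates += sm.weight * sm.representative_profile.rate_at(mids)
    for j in range(1, len(rates)):
        if rates[j] == rates[j - 1]:
            rates[j] *= 1.0 + 1e-9
            rates[j] += 1e-12
    return SwitchProfile(sw_times, tuple(rates), window), table
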