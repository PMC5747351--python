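"""Readers and writers for the pipeline's plain-text interchange formats.

Trace CSV (long format): cell_id, condition, time_h, luminescence,
right_censored — one row per observation.  Ground truth, prior
specifications and estimates travel as JSON; cohort configuration as YAML.
All writers emit a ``# pulseswitch-schema: <name> v1`` header comment so
files are self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import Cohort, CohortConfig
from .types import KineticParams, LuminescenceTrace, SwitchProfile

__all__ = [
    "write_traces_csv",
    "read_traces_csv",
    "write_ground_truth",
    "read_ground_truth",
    "write_posterior_csv",
    "read_posterior_csv",
    "write_json",
    "read_json",
    "write_cohort_config",
    "read_cohort_config",
]

SCHEMA_VERSION = 1


def write_traces_csv(traces: list[LuminescenceTrace], path) -> None:
    path = Path(path)
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "cell_id": tr.cell_id,
            "condition": tr.condition,
            "time_h": tr.times,
            "luminescence": tr.values,
            "right_censored": tr.right_censored,
        }))
    df = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(f"# pulseswitch-schema: traces v{SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)


def read_traces_csv(path) -> list[LuminescenceTrace]:
    df = pd.read_csv(path, comment="#")
    required = {"cell_id", "time_h", "luminescence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    traces = []
    for (cell,), g in df.groupby(["cell_id"], sort=False):
        g = g.sort_values("time_h")
        traces.append(LuminescenceTrace(
            cell_id=str(cell),
            times=g.time_h.to_numpy(dtype=float),
            values=g.luminescence.to_numpy(dtype=float),
            condition=str(g.condition.iloc[0]) if "condition" in g else "unknown",
            right_censored=bool(g.right_censored.iloc[0])
            if "right_censored" in g else True,
        ))
    return traces


def _profile_to_dict(p: SwitchProfile) -> dict:
    return {"switch_times": list(p.switch_times), "rates": list(p.rates),
            "window": list(p.window)}


def _params_to_dict(p: KineticParams) -> dict:
    return {"delta_m": p.delta_m, "delta_p": p.delta_p, "alpha": p.alpha,
            "kappa": p.kappa, "sigma": p.sigma, "c_p": p.c_p, "c_m": p.c_m}


def write_ground_truth(cohort: Cohort, path) -> None:
    payload = {
        "schema": f"pulseswitch-ground-truth v{SCHEMA_VERSION}",
        "seed": cohort.seed,
        "config": cohort.config.to_dict(),
        "cells": {
            tr.cell_id: {
                "profile": _profile_to_dict(prof),
                "params": _params_to_dict(par),
            }
            for tr, prof, par in zip(cohort.traces, cohort.profiles, cohort.params)
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path) -> dict:
    payload = json.loads(Path(path).read_text())
    out = {}
    for cell, d in payload["cells"].items():
        prof = SwitchProfile(tuple(d["profile"]["switch_times"]),
                             tuple(d["profile"]["rates"]),
                             tuple(d["profile"]["window"]))
        out[cell] = {"profile": prof, "params": KineticParams(**d["params"])}
    return out


def write_posterior_csv(ensembles, path, thin: int = 1) -> None:
    """Serialise posterior ensembles in long format.

    One row per profile segment per retained iteration: columns cell_id,
    iteration, K, switch_index (0 for the first segment; j >= 1 rows carry
    switch time s_j), time_h, rate, delta_m, delta_p, alpha, sigma2,
    log_lik.  ``thin`` keeps every thin-th retained sample to bound file
    size.  Failed cells (None) are skipped.
    """
    from .types import PosteriorEnsemble  # noqa: F401  (doc reference)

    rows = []
    for ens in ensembles:
        if ens is None:
            continue
        for s in ens.samples[::thin]:
            prof, par = s.profile, s.params
            times = (float("nan"),) + prof.switch_times
            for j, (t, r) in enumerate(zip(times, prof.rates)):
                rows.append((ens.cell_id, s.iteration, prof.n_switches, j,
                             round(t, 4) if j else "", round(r, 5),
                             round(par.delta_m, 6), round(par.delta_p, 6),
                             round(par.alpha, 5), round(par.sigma2, 4),
                             round(s.log_lik, 4)))
    df = pd.DataFrame(rows, columns=[
        "cell_id", "iteration", "K", "switch_index", "time_h", "rate",
        "delta_m", "delta_p", "alpha", "sigma2", "log_lik"])
    with open(path, "w") as fh:
        fh.write(f"# pulseswitch-schema: posterior v{SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)


def read_posterior_csv(path):
    """Inverse of :func:`write_posterior_csv` (window taken from metadata
    is not stored; profiles are rebuilt on the [min, max] span stored in a
    trailing comment if present, else inferred from switch times with the
    companion trace file).  Returns ``{cell_id: list of
    (SwitchProfile-like dict, params dict)}`` for lightweight reloading.
    """
    df = pd.read_csv(path, comment="#")
    out: dict[str, list[dict]] = {}
    for (cell, it), g in df.groupby(["cell_id", "iteration"], sort=False):
        g = g.sort_values("switch_index")
        rec = {
            "iteration": int(it),
            "switch_times": [float(t) for t in g.time_h.iloc[1:]],
            "rates": [float(r) for r in g.rate],
            "delta_m": float(g.delta_m.iloc[0]),
            "delta_p": float(g.delta_p.iloc[0]),
            "alpha": float(g.alpha.iloc[0]),
            "sigma2": float(g.sigma2.iloc[0]),
            "log_lik": float(g.log_lik.iloc[0]),
        }
        out.setdefault(str(cell), []).append(rec)
    return out


def ensembles_from_posterior_csv(path, window: tuple[float, float]):
    """Rebuild :class:`PosteriorEnsemble` objects from a posterior CSV.

    ``window`` is the observation window of the traces the posterior was
    fitted on (the CSV stores switch times and rates only).
    """
    from .types import PosteriorEnsemble, PosteriorSample, SwitchProfile

    records = read_posterior_csv(path)
    out = []
    for cell, recs in records.items():
        samples = []
        for r in recs:
            rates = list(r["rates"])
            for j in range(1, len(rates)):  # rounding can equalise rates
                if rates[j] == rates[j - 1]:
                    rates[j] *= 1.0 + 1e-9
                    rates[j] += 1e-12
            prof = SwitchProfile(tuple(r["switch_times"]), tuple(rates), window)
            par = KineticParams(delta_m=r["delta_m"], delta_p=r["delta_p"],
                                alpha=r["alpha"], kappa=1.0,
                                sigma=float(np.sqrt(r["sigma2"])))
            samples.append(PosteriorSample(profile=prof, params=par,
                                           iteration=r["iteration"],
                                           log_lik=r["log_lik"]))
        out.append(PosteriorEnsemble(cell_id=cell, samples=samples,
                                     n_iter=0, burn_in=0))
    return out


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, default=default))


def read_json(path):
    return json.loads(Path(path).read_text())


def write_cohort_config(config: CohortConfig, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pulseswitch-schema: cohort-config v{SCHEMA_VERSION}\n")
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def read_cohort_config(path) -> CohortConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return CohortConfig.from_dict(d)
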