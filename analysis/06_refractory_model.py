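"""Fit the three-state (on / off / primed) refractory model.

Merges the inferred phases over runs of same-direction switches into
inter-switch durations, fits the censored exponential (on) and censored
hypoexponential (off + primed) maximum likelihoods, bootstraps the
refractory period over cells, and reports minimum durations with their
empirical CDFs.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from pulseswitch import io, refractory
from pulseswitch.phase_stats import profile_to_phases
from pulseswitch.types import SwitchProfile


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--postprocess", type=Path, default=Path("results/postprocess.json"))
    ap.add_argument("--traces", type=Path, default=Path("results/cohort_traces.csv"))
    ap.add_argument("--boot", type=int, default=200)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    traces = io.read_traces_csv(args.traces)
    window = traces[0].window
    cells = json.loads(args.postprocess.read_text())

    durations = []
    beta_L, beta_H = [], []
    for cell, d in cells.items():
        rates = list(d["consensus"]["rates"])
        for j in range(1, len(rates)):
            if rates[j] == rates[j - 1]:
                rates[j] *= 1.0 + 1e-9
        prof = SwitchProfile(tuple(d["consensus"]["switch_times"]),
                             tuple(rates), window)
        phases = profile_to_phases(prof, cell_id=cell)
        durations += refractory.merge_same_direction(phases)
        for a, b in zip(prof.rates[:-1], prof.rates[1:]):
            (beta_H if b > a else beta_L).append(b)

    df = refractory.durations_to_frame(durations)
    df.to_csv(args.out_dir / "merged_durations.csv", index=False)

    est = refractory.estimate_three_state(
        df,
        beta_L=float(np.mean(beta_L)) if beta_L else float("nan"),
        beta_H=float(np.mean(beta_H)) if beta_H else float("nan"))
    boot = refractory.refractory_summary(df, n_boot=args.boot, seed=args.seed)
    mins = refractory.minimum_duration_stats(df)

    out = {
        "T0_on_h": est.T0, "T1_refractory_h": est.T1, "T2_primed_h": est.T2,
        "loglik": est.loglik, "n_complete": est.n_complete,
        "n_censored": est.n_censored,
        "beta_L": est.beta_L, "beta_H": est.beta_H,
        "bootstrap": boot,
        "min_complete_after_down_h": mins["after_down"]["min"],
        "min_complete_after_up_h": mins["after_up"]["min"],
    }
    io.write_json(out, args.out_dir / "three_state_fit.json")
    ecdf = pd.DataFrame({
        "duration_h": mins["after_down"]["ecdf_x"],
        "ecdf": mins["after_down"]["ecdf_y"]})
    ecdf.to_csv(args.out_dir / "down_duration_ecdf.csv", index=False)

    print(f"three-state fit over {len(cells)} cells "
          f"({est.n_complete} complete + {est.n_censored} censored "
          f"inactive durations):")
    print(f"  on period        T0 = {est.T0:.2f} h")
    print(f"  refractory (off) T1 = {est.T1:.2f} h "
          f"[bootstrap median {boot['median']:.2f}, "
          f"IQR {boot['iqr'][0]:.2f}-{boot['iqr'][1]:.2f}]")
    print(f"  primed           T2 = {est.T2:.2f} h")
    print(f"  minimum complete inactive duration: "
          f"{out['min_complete_after_down_h']:.2f} h; "
          f"minimum activation: {out['min_complete_after_up_h']:.2f} h")
    print(f"outputs: {args.out_dir}/three_state_fit.json")


if __name__ == "__main__":
    main()
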