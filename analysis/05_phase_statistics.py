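"""Descriptive statistics over the inferred transcription profiles.

Phase extraction, up/down switch counts (mean +/- SEM), the ln-ln
rate-duration regression, switch-pair amplitude correlations per scenario,
binary/graded classification, raw-trace pairwise 1-h correlations and the
population mean transcription rate.  Writes tidy CSVs plus a summary JSON.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from pulseswitch import io, phase_stats
from pulseswitch.types import SwitchProfile


def load_consensus(path: Path, window) -> dict[str, SwitchProfile]:
    cells = json.loads(path.read_text())
    out = {}
    for cell, d in cells.items():
        times = tuple(d["consensus"]["switch_times"])
        rates = list(d["consensus"]["rates"])
        for j in range(1, len(rates)):
            if rates[j] == rates[j - 1]:
                rates[j] *= 1.0 + 1e-9
        out[cell] = SwitchProfile(times, tuple(rates), window)
    return out


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--postprocess", type=Path, default=Path("results/postprocess.json"))
    ap.add_argument("--traces", type=Path, default=Path("results/cohort_traces.csv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    traces = io.read_traces_csv(args.traces)
    window = traces[0].window
    condition = traces[0].condition
    profiles = load_consensus(args.postprocess, window)

    all_phases = []
    for cell, prof in profiles.items():
        all_phases += phase_stats.profile_to_phases(prof, cell_id=cell)
    phase_stats.phases_to_frame(all_phases).to_csv(
        args.out_dir / "phases.csv", index=False)

    per_cell, summary = phase_stats.count_switches(
        {condition: list(profiles.values())})
    per_cell.to_csv(args.out_dir / "switch_counts.csv", index=False)

    summary_out = {"condition": condition,
                   "n_cells": len(profiles),
                   "mean_up": float(summary.loc[0, "up_mean"]),
                   "sem_up": float(summary.loc[0, "up_sem"]),
                   "mean_down": float(summary.loc[0, "down_mean"]),
                   "sem_down": float(summary.loc[0, "down_sem"])}
    summary_out["down_up_ratio"] = summary_out["mean_down"] / max(
        summary_out["mean_up"], 1e-12)

    try:
        reg = phase_stats.rate_duration_regression(all_phases)
        summary_out["rate_duration"] = {
            "slope": reg.slope, "pearson_r": reg.pearson_r,
            "p_value": reg.p_value, "n_used": reg.n_used}
    except ValueError as e:
        summary_out["rate_duration"] = f"not computed: {e}"

    pairs, corr = phase_stats.switch_pair_analysis(list(profiles.values()))
    pairs.to_csv(args.out_dir / "switch_pairs.csv", index=False)
    corr.to_csv(args.out_dir / "switch_pair_correlations.csv", index=False)

    classes = pd.Series({c: phase_stats.classify_cell(p)
                         for c, p in profiles.items()}, name="class")
    classes.rename_axis("cell_id").to_csv(args.out_dir / "cell_classes.csv")
    frac = classes.value_counts(normalize=True).to_dict()
    summary_out["class_fractions"] = frac
    summary_out["graded_fraction"] = float(
        sum(v for k, v in frac.items() if k.startswith("graded")))

    coeffs, med = phase_stats.pairwise_trace_correlation(traces)
    med.to_csv(args.out_dir / "pairwise_correlation_medians.csv", index=False)

    pop = phase_stats.population_rate_trajectory(list(profiles.values()))
    pop.to_csv(args.out_dir / "population_rate.csv", index=False)

    io.write_json(summary_out, args.out_dir / "phase_summary.json")
    print(f"{len(profiles)} cells ({condition}): "
          f"up {summary_out['mean_up']:.2f} +/- {summary_out['sem_up']:.2f}, "
          f"down {summary_out['mean_down']:.2f} +/- {summary_out['sem_down']:.2f} "
          f"(down:up {summary_out['down_up_ratio']:.2f})")
    if isinstance(summary_out["rate_duration"], dict):
        rd = summary_out["rate_duration"]
        print(f"ln(rate)-ln(duration): r = {rd['pearson_r']:.3f} "
              f"(p = {rd['p_value']:.2g}, n = {rd['n_used']})")
    print("class fractions:", {k: round(v, 2) for k, v in frac.items()})
    print(f"outputs under {args.out_dir}/")


if __name__ == "__main__":
    main()
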