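"""Estimate reporter degradation rates from the inhibitor decay traces.

Fits the protein rate from the cycloheximide traces, then the mRNA rate
from the actinomycin D traces with the protein rate fixed, pools replicate
fits into log-normal priors, and writes the prior specification JSON used
by the switch-model inference.
"""

import argparse
from pathlib import Path

import numpy as np

from pulseswitch import io
from pulseswitch.halflife import (
    DecayFitError,
    fit_mrna_decay,
    fit_protein_decay,
    make_degradation_prior,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--decay-traces", type=Path,
                    default=Path("results/decay_traces.csv"))
    ap.add_argument("--t-inhibit", type=float, default=2.0)
    ap.add_argument("--out", type=Path,
                    default=Path("results/degradation_priors.json"))
    args = ap.parse_args()

    traces = io.read_traces_csv(args.decay_traces)
    chx = [t for t in traces if t.condition == "cycloheximide"]
    actd = [t for t in traces if t.condition == "actinomycinD"]

    protein_fits = []
    for tr in chx:
        try:
            protein_fits.append(fit_protein_decay(tr, args.t_inhibit))
        except DecayFitError as e:
            print(f"  {tr.cell_id}: protein fit failed ({e})")
    dp_prior = make_degradation_prior(protein_fits)

    mrna_fits = []
    for tr in actd:
        try:
            mrna_fits.append(fit_mrna_decay(tr, args.t_inhibit,
                                            delta_p=dp_prior["median"]))
        except DecayFitError as e:
            print(f"  {tr.cell_id}: mRNA fit failed ({e})")
    dm_prior = make_degradation_prior(mrna_fits)

    io.write_json({"delta_p": dp_prior, "delta_m": dm_prior}, args.out)
    print(f"protein: {len(protein_fits)} fits, rate median "
          f"{dp_prior['median']:.3f}/h "
          f"(half-life {np.log(2) / dp_prior['median']:.2f} h, "
          f"log-sd {dp_prior['log_sd']:.2f})")
    print(f"mRNA:    {len(mrna_fits)} fits, rate median "
          f"{dm_prior['median']:.3f}/h "
          f"(half-life {np.log(2) / dm_prior['median']:.2f} h, "
          f"log-sd {dm_prior['log_sd']:.2f})")
    print(f"priors written to {args.out}")


if __name__ == "__main__":
    main()
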