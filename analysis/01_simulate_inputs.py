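#!/usr/bin/env python
"""Generate the synthetic inputs for every downstream analysis stage.

Writes, under results/sim/: a gel lane + ladder, a nanopore trace + ECD
standards, bead trajectories, an immunoblot band-density table, and the
two-group cohort table — each with its truth sidecar.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from hyalkit import gel, io as hio, nanopore as npo, simulate as sim
from hyalkit.cli import _default_ladder, _default_standards


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/sim"))
    args = ap.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    # gel lane at the healthy-cohort gel target (Mw 3660 kDa, PDI 2.26)
    dist, dtruth = sim.gen_mw_lognormal(3660.0, 2.26)
    ladder = _default_ladder()
    calib = gel.fit_gel_calibration(ladder)
    lane, ltruth = sim.gen_gel_lane(dist, calib, noise_sd=0.01, baseline=5.0, seed=args.seed)
    pd.DataFrame({"distance_px": lane.distance_px, "intensity": lane.intensity}).to_csv(
        out / "gel_lane.csv", index=False)
    pd.DataFrame(ladder, columns=["band_px", "mw_kda"]).to_csv(out / "gel_ladder.csv", index=False)
    (out / "gel_truth.json").write_text(json.dumps(
        {"mw_kda": dtruth["mw_kda"], "pdi": dtruth["pdi"],
         "truncated_mass_fraction": ltruth["truncated_mass_fraction"]}, indent=2))

    # nanopore trace (SNR 10, ~1000 events from a 1 MDa, PDI 1.5 sample)
    standards = _default_standards()
    ecal = npo.fit_ecd_calibration(standards)
    ndist, _ = sim.gen_mw_lognormal(1000.0, 1.5)
    trace, ntruth = sim.gen_nanopore_trace(
        ndist, ecal, event_rate_hz=40, duration_s=25.0, seed=args.seed + 1, snr=10.0)
    hio.write_trace_raw(trace, out / "nanopore_trace.bin")
    ntruth.to_csv(out / "nanopore_truth.csv", index=False)
    pd.DataFrame(standards, columns=["mw_kda", "mean_ecd_pas"]).to_csv(
        out / "nanopore_standards.csv", index=False)

    # bead trajectories at each viscosity of the sweep
    for i, eta in enumerate([1, 10, 50, 100, 250]):
        tracks, rtruth = sim.gen_brownian_tracks(eta_cp=eta, seed=args.seed + 30 + i)
        hio.write_trajectories_csv(tracks, out / f"tracks_{eta}cp.csv")
    (out / "tracks_truth.json").write_text(json.dumps({"etas_cp": [1, 10, 50, 100, 250]}))

    # immunoblot band densities and cohort table
    bdf, _ = sim.gen_blot_pairs(noise=0.05, seed=args.seed + 3)
    bdf.to_csv(out / "blot_pairs.csv", index=False)
    cdf, ctruth = sim.gen_cohort(seed=args.seed + 4)
    cdf.to_csv(out / "cohort.csv", index=False)
    (out / "cohort_truth.json").write_text(json.dumps(ctruth, indent=2, default=str))

    print(f"wrote synthetic inputs for all 5 stages to {out}/ (seed {args.seed})")


if __name__ == "__main__":
    main()
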