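"""Invasion scoring and the vehicle-normalised drug screen.

Computes invasive/proliferative indices per condition and the per-depth-bin
invasion profiles normalised to the DMSO vehicle, then tests each
treatment's normalised suppression against 1 with one-sample t-tests.
"""

from pathlib import Path

import pandas as pd

from orgmatrix import expression as expr, invasion as inv

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    records = inv.records_from_frame(pd.read_csv(RESULTS / "invasion_counts.csv"))

    for which in ("invasive", "marker"):
        table = inv.aggregate_indices(records, which)
        table.to_csv(RESULTS / f"{which}_index.csv")
        for cond, row in table.iterrows():
            print(f"{which} index, {cond:>10}: {row['mean_pct']:.1f} "
                  f"± {row['sem_pct']:.1f} % (n={int(row['n_replicates'])})")

    norm = inv.normalize_to_control(records, "DMSO")
    norm.to_csv(RESULTS / "normalized_depth_profiles.csv")
    comparable = [c for c in norm.columns
                  if c not in norm.attrs["non_comparable_bins"]]
    print("\nvehicle-normalised invasion by depth bin "
          f"(comparable bins: {comparable}):")
    print(norm[comparable].round(2))

    # per-replicate normalised values for the one-sample test against 1
    profiles = []
    for r in records:
        prof = inv.depth_profile(r)
        profiles.append({"condition": r.condition, "replicate": r.replicate,
                         **dict(zip(inv.DEPTH_BIN_COLUMNS, prof))})
    per_rep = (pd.DataFrame(profiles)
               .groupby(["condition", "replicate"]).mean())
    vehicle_mean = per_rep.loc["DMSO"].mean()
    stats_rows = []
    for cond in ("Y-27632", "Gefitinib"):
        for bin_col in comparable:
            values = per_rep.loc[cond, bin_col] / vehicle_mean[bin_col]
            test = expr.one_sample_t(values.to_numpy(), mu0=1.0)
            stats_rows.append({"condition": cond, "bin": bin_col,
                               "mean_normalized": float(values.mean()),
                               "t": test.t, "p": test.p, "stars": test.stars})
    stats = pd.DataFrame(stats_rows)
    stats.to_csv(RESULTS / "screen_statistics.csv", index=False)
    print("\none-sample t-tests of normalised invasion vs 1:")
    print(stats.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
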