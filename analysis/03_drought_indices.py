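"""Drought-tolerance indices and rank-sum screening.

Takes the grain-yield BLUEs of both regimes, computes the eight indices and
the trial stress intensity, ranks genotypes per index (1 = most tolerant),
aggregates with RS = R + SDR and selects the top 20%.
"""

import argparse
from pathlib import Path

import pandas as pd

from ideoselect import drought_indices as di


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--intensity", type=float, default=0.20)
    args = ap.parse_args()

    ys = pd.read_csv(args.results / "blues_WS.csv", index_col=0)["GY"]
    yp = pd.read_csv(args.results / "blues_WW.csv", index_col=0)["GY"]
    dti, ctx = di.compute_indices(ys, yp)
    ranks = di.rank_indices(dti)
    summary = di.rank_sum(ranks)
    selected = di.select_by_rank_sum(summary, args.intensity)

    dti.to_csv(args.results / "dti.csv", float_format="%.8g")
    ranks.to_csv(args.results / "ranks.csv", float_format="%.8g")
    summary.to_csv(args.results / "rank_sum.csv", float_format="%.8g")
    pd.DataFrame({"genotype": selected}).to_csv(
        args.results / "selected_rs.csv", index=False)

    print(f"stress intensity SI = {ctx.si:.3f} "
          f"(mean Ys {ctx.ybar_s:.1f}, mean Yp {ctx.ybar_p:.1f} kg/ha)")
    print(f"selected {len(selected)} genotypes at {args.intensity:.0%} intensity")
    print("\nten most drought-tolerant by rank sum:")
    top = summary.sort_values("RS").head(10).round(3)
    print(top)


if __name__ == "__main__":
    main()
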