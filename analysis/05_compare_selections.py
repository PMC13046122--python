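"""Associations among indices and agreement among the selection methods.

Pearson correlations among yields and indices, the genotype x index biplot
decomposition, and the Venn-region comparison of the rank-sum and
MGIDI (WS, WW) selection sets.
"""

import argparse
from pathlib import Path

import pandas as pd

from ideoselect import association as ass


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    dti = pd.read_csv(args.results / "dti.csv", index_col=0)
    r, p = ass.correlate(dti)
    r.to_csv(args.results / "correlations_indices.csv", float_format="%.6g")
    print(f"Ys-Yp correlation: r = {r.loc['Ys', 'Yp']:.3f} "
          f"(p = {p.loc['Ys', 'Yp']:.2e})")
    print(f"TOL-SSI correlation: r = {r.loc['TOL', 'SSI']:.3f}")

    bi = ass.index_biplot(dti)
    pd.DataFrame({"axis_variance_pct": bi.axis_variance_pct}).to_csv(
        args.results / "biplot_axes.csv", index=False, float_format="%.6g")
    pd.concat([bi.genotype_coords.assign(kind="genotype"),
               bi.index_coords.assign(kind="index")]).to_csv(
        args.results / "biplot_coords.csv", float_format="%.6g")
    print(f"biplot: axis I {bi.axis_variance_pct[0]:.2f}%, "
          f"axis II {bi.axis_variance_pct[1]:.2f}% "
          f"(together {bi.axis_variance_pct[:2].sum():.1f}% of variation)")

    sets = {
        "RS": pd.read_csv(args.results / "selected_rs.csv")["genotype"].tolist(),
        "MGIDI-WS": pd.read_csv(args.results / "selected_mgidi_WS.csv")["genotype"].tolist(),
        "MGIDI-WW": pd.read_csv(args.results / "selected_mgidi_WW.csv")["genotype"].tolist(),
    }
    comp = ass.compare_selections(sets)
    rows = [{"sets": "&".join(sorted(k)), "count": v}
            for k, v in sorted(comp.regions.items(),
                               key=lambda kv: (len(kv[0]), sorted(kv[0])))]
    pd.DataFrame(rows).to_csv(args.results / "venn_regions.csv", index=False)
    print("\nselection-set overlap:")
    for row in rows:
        print(f"  {row['sets']}: {row['count']}")
    print(f"consensus across all three methods: "
          f"{', '.join(comp.consensus) or '(none)'}")


if __name__ == "__main__":
    main()
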