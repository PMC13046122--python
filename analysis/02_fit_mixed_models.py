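"""Fit the per-trait mixed models within each water regime.

For every trait and regime: EM-REML variance components, broad-sense
heritability with its low/moderate/high class, residual CV, the sequential
ANOVA table, and genotype adjusted means (BLUEs).  Writes
blues_/anova_/heritability_<regime>.csv under results/.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from ideoselect import cli_io, met_model as mm


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    trials = cli_io.read_trials(args.results / "trials.csv")
    traits = sorted(trials["trait"].unique())
    for regime in ("WS", "WW"):
        rows, blues, anovas = [], {}, []
        for trait in traits:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vc = mm.fit_variance_components(trials, trait, regime)
                est = mm.heritability(vc)
                blues[trait] = mm.blues(trials, trait, regime, vc=vc)
            tab = mm.anova(trials, trait, regime)
            tab.insert(0, "trait", trait)
            anovas.append(tab)
            rows.append({"trait": trait, "sigma2_g": vc.sigma2_g,
                         "sigma2_ge": vc.sigma2_ge, "sigma2_e": vc.sigma2_e,
                         "H2_pct": est.h2_pct, "category": est.category,
                         "CV_pct": est.cv_pct})
        herit = pd.DataFrame(rows).set_index("trait")
        pd.DataFrame(blues).to_csv(args.results / f"blues_{regime}.csv",
                                   float_format="%.8g")
        pd.concat(anovas).to_csv(args.results / f"anova_{regime}.csv",
                                 index=False, float_format="%.8g")
        herit.to_csv(args.results / f"heritability_{regime}.csv",
                     float_format="%.8g")
        print(f"\n=== {regime}: heritability and CV ===")
        print(herit[["H2_pct", "CV_pct", "category"]].round(2))


if __name__ == "__main__":
    main()
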