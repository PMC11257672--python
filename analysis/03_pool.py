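"""Second stage: pool location coefficients by climate with REML meta-regression.

Reads results/stage1.json, fits the multilevel multivariate model (climate
fixed effects, country random coefficient block), and writes the pooled
fixed effects, between-country covariance, heterogeneity statistics and
BLUPs to results/meta.json.
"""

import json
from pathlib import Path

from raincross.casecrossover import StageOneFit
from raincross.meta import pool

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    with open(RESULTS / "stage1.json") as fh:
        fits = [StageOneFit.from_dict(d) for d in json.load(fh)]
    mf = pool(fits)
    with open(RESULTS / "meta.json", "w") as fh:
        json.dump(mf.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    print(f"pooled {len(fits)} locations, climates: {', '.join(mf.climate_levels)}")
    print(f"heterogeneity: Q = {mf.Q:.1f} (df {mf.Q_df}, p = {mf.Q_p:.2g}), "
          f"I2 = {mf.I2:.1f}%")
    print(f"climate Wald test: chi2 = {mf.wald['statistic']:.1f} "
          f"(df {mf.wald['df']}), p = {mf.wald['p']:.2g}")
    print(f"between-country covariance structure: {mf.psi_structure}")
    print(f"wrote {RESULTS/'meta.json'}")


if __name__ == "__main__":
    main()
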