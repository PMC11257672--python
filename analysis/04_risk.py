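"""Risk summaries: pooled exposure-response curves, MMP, percent changes.

Runs the full pipeline on results/study.csv and writes the risk bundle
(summary.json plus tidy curve tables) under results/bundle/, then prints
the headline table: minimum-risk precipitation and the percent change in
mortality risk at the 5th (extremely dry) and 95th (extremely wet)
percentiles of 28-day cumulative precipitation, by climate zone.
"""

from pathlib import Path

from raincross.pipeline import PipelineConfig, read_table, run_pipeline, write_bundle

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    bundle = run_pipeline(read_table(RESULTS / "study.csv"), PipelineConfig())
    write_bundle(bundle, RESULTS / "bundle")
    print(f"{'climate':<10} {'MMP mm':>7} {'MMP pct':>7} "
          f"{'dry %chg (95% CI)':>22} {'wet %chg (95% CI)':>22}")
    for climate, s in bundle["risk"].items():
        dry = s["pct_change_dry"]
        wet = s["pct_change_wet"]
        dry_s = (f"{dry['pct_change']:+.1f} ({dry['ci_low']:.1f}, {dry['ci_high']:.1f})"
                 if s["mmp_percentile"] > 0 else "--")
        wet_s = f"{wet['pct_change']:+.1f} ({wet['ci_low']:.1f}, {wet['ci_high']:.1f})"
        print(f"{climate:<10} {s['mmp_mm']:>7.0f} {s['mmp_percentile']:>7.1f} "
              f"{dry_s:>22} {wet_s:>22}")
    print(f"\n{len(bundle['risk_blup'])} country-climate BLUP curves "
          f"written alongside the pooled curves under {RESULTS/'bundle'}")


if __name__ == "__main__":
    main()
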