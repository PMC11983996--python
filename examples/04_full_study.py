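"""Run the full pipeline on a generated cohort and read the odds-ratio table.

Generates a 400-pair cohort, aggregates the FFQ, scores adherence against
sex-specific control medians, and fits crude and adjusted conditional
models for every subsite and sex stratum.
"""

from meddiet import RunConfig, default_config, run_study

config = RunConfig(
    out_dir="scratch/example_study",
    generator=default_config(n_pairs=400),
    seed=2024,
)
report = run_study(config)

print(f"subjects loaded {report.n_loaded}, scored {report.n_scored}, "
      f"ratio-undefined {report.n_ratio_excluded}")
print("\nScore distribution (overall):")
overall = report.distribution[report.distribution["stratum"] == "all"]
print(overall.round(1).to_string(index=False))

print("\nOdds ratios, CRC overall (low adherence is the reference):")
ors = report.or_table.query("subsite == 'all' and stratum == 'all'")
cols = ["category", "n_cases", "n_controls", "or_adjusted",
        "ci_adjusted_low", "ci_adjusted_high"]
print(ors[cols].round(3).to_string(index=False))
print("\nThis cohort was generated without a diet effect, so the adjusted"
      "\nORs fluctuate around 1; tables are also written to the output directory.")
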