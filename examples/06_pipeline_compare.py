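"""End-to-end pipeline run plus a control-vs-disease group contrast.

Runs the full per-sample statistics bundle for three presets, writes the
report directory (JSON summary, bedGraph tracks, boundary BED, P(s) tables),
then contrasts small groups of control (MN_W6) and disease (ALS_MN_W6)
replicates with an exact label-permutation test.
"""

import warnings

import hicstats as hs
from hicstats.pipeline import RunConfig, analyze_sample, compare_groups, run_pipeline

warnings.filterwarnings("ignore")

cfg = RunConfig(samples=[{"name": "PF", "preset": "PF"},
                         {"name": "IPSC", "preset": "IPSC"},
                         {"name": "MN", "preset": "MN_W6"}],
                genome="test", bin_size=250_000, window=500_000,
                flank=500_000, n_contacts=1_000_000, seed=0,
                outdir="pipeline_out")
summary = run_pipeline(cfg)
print("per-sample cis %:", {k: v["cis_percent"] for k, v in summary["samples"].items()})
print("report written to pipeline_out/ (summary.json, tracks, boundaries)")

bt = hs.build_bin_table(hs.test_genome(), 250_000, 1_000_000)
planted = hs.sample_switch_tracks(bt, seed=0)
groups = {}
for name in ("MN_W6", "ALS_MN_W6"):
    reps = []
    for rep in range(3):
        m = hs.simulate_state(bt, hs.preset(name), planted.tracks[2],
                              n_contacts=1_000_000, seed=50 + rep)
        reps.append(analyze_sample(m, planted.tracks[2].ev1,
                                   window=500_000, flank=500_000))
    groups[name] = reps

table = compare_groups(groups["MN_W6"], groups["ALS_MN_W6"])
cols = ["statistic", "mean_control", "mean_case", "difference", "p_permutation"]
print(table[table["statistic"].isin(["cis_percent", "tel_tel", "mito_nuclear_score"])]
      [cols].to_string(index=False))
print("\nNegative differences: the ALS group falls short of the mature "
      "control on territoriality and telomere clustering; the positive "
      "mito-nuclear difference is the elevated background of compromised "
      "mitochondria.")
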