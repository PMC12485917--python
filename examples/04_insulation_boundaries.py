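"""TAD-boundary insulation: calling, recovery, set algebra and pileups.

Simulates an immature (MN_W0) and a mature (MN_W6) motor-neuron map with the
same planted boundary positions but stronger insulation at week 6, calls
boundaries from diamond insulation minima, compares the two boundary sets,
and aggregates insulation around the planted positions.
"""

import warnings

import numpy as np

import hicstats as hs

warnings.filterwarnings("ignore")

bt = hs.build_bin_table(hs.test_genome(), 250_000, 1_000_000)
planted = hs.sample_switch_tracks(bt, seed=0)
track = planted.tracks[2]

results = {}
for name in ("MN_W0", "MN_W6"):
    m = hs.simulate_state(bt, hs.preset(name), track, n_contacts=2_000_000, seed=3)
    m = hs.ic_balance(hs.mask_low_coverage(m))
    ins = hs.insulation_track(m, window=500_000)
    calls = [b for b in hs.call_boundaries(ins) if b.is_strong]
    results[name] = (ins, calls)
    truth = {bt.bin_id(c, int(p)) for c, p, _ in
             hs.default_boundaries(bt, hs.preset(name).boundary_spacing,
                                   hs.preset(name).boundary_beta)}
    rec = sum(1 for t in truth if any(abs(b.bin - t) <= 1 for b in calls))
    print(f"{name}: {len(calls)} strong boundaries, "
          f"{100 * rec / len(truth):.0f}% of {len(truth)} planted recovered (+/-1 bin)")

parts = hs.compare_boundary_sets(results["MN_W0"][1], results["MN_W6"][1])
print(f"\nW0-specific {len(parts['a_specific'])}, common {len(parts['common'])}, "
      f"W6-specific {len(parts['b_specific'])}")

for name in ("MN_W0", "MN_W6"):
    ins, calls = results[name]
    agg = hs.aggregate_insulation(ins, calls, flank=750_000)
    print(f"{name}: mean insulation at boundary = {agg.profile[len(agg.offsets)//2]:+.2f} "
          f"(flanks {agg.profile[0]:+.2f})")
print("A deeper central dip at week 6 shows boundaries strengthening with "
      "neuronal maturation.")
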