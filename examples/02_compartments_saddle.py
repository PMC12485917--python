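"""A/B compartment eigenvector and saddle strength on simulated maps.

Simulates one map per cell state, estimates the compartment eigenvector
(EV1) per chromosome, and quantifies compartmentalization strength from
EV1-sorted saddle corners: mean homotypic (A-A or B-B) enrichment divided by
mean heterotypic (A-B) enrichment over the extreme 20% of bins.
"""

import warnings

import hicstats as hs

warnings.filterwarnings("ignore")

bt = hs.build_bin_table(hs.test_genome(), 250_000, 1_000_000)
planted = hs.sample_switch_tracks(bt, seed=0)
state_of = {"PF": 0, "IPSC": 1}

print(f"{'state':10s} {'AA cis':>7s} {'BB cis':>7s} {'AA trans':>9s}")
for name in ("PF", "IPSC", "MN_W0", "MN_W3", "MN_W6"):
    track = planted.tracks[state_of.get(name, 2)]
    m = hs.simulate_state(bt, hs.preset(name), track, n_contacts=2_000_000, seed=2)
    m = hs.ic_balance(hs.mask_low_coverage(m))
    ev = hs.compute_ev1(m, track.ev1)
    cis = hs.saddle_strength(m, ev, "cis")
    trans = hs.saddle_strength(m, ev, "trans")
    print(f"{name:10s} {cis.strength_AA:7.2f} {cis.strength_BB:7.2f} "
          f"{trans.strength_AA:9.2f}")

print("\nStrength ~1 means no homotypic preference. The dip at the iPSC "
      "state and the rise through motor-neuron maturation reproduce the "
      "reprogramming/differentiation arc.")
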