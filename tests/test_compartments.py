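import numpy as np
import pandas as pd
import pytest

from hicstats import (ContactMatrix, Genome, build_bin_table, classify_switches,
                      compute_ev1, expected_contact_map, intersection_fraction,
                      saddle_strength, summarize_by_group)
from hicstats.compartments import CompartmentTrack, SwitchTable
from hicstats.contacts import ic_balance, mask_low_coverage, observed_over_expected_cis
from hicstats.simulate import sample_contact_map

from conftest import as_matrix, checkerboard_params

Mb = 1_000_000


def _single_chrom_checkerboard(n_mb=50, domain_mb=2, c=2.0):
    """One-chromosome expected map with alternating A/B domains (<=200 bins)."""
    g = Genome(("chr1", "chr2"), (n_mb * Mb, 30 * Mb), (n_mb * Mb // 2, 15 * Mb))
    bt = build_bin_table(g, 250_000, 1_000_000)
    ev = np.where((bt.start // (domain_mb * Mb)) % 2 == 0, 1.0, -1.0)
    tr = CompartmentTrack(bt, ev)
    E = expected_contact_map(bt, tr, checkerboard_params(c_AA=c, c_BB=c))
    return bt, tr, as_matrix(bt, E)


class TestComputeEv1:
    def test_matches_dense_eigendecomposition_oracle(self):
        """On a small noise-free map the track must reproduce the leading
        eigenvector of the independently computed correlation matrix."""
        bt, tr, m = _single_chrom_checkerboard()
        track = compute_ev1(m, tr.ev1)
        sl = bt.chrom_slice("chr1")
        assert sl.stop - sl.start <= 200
        # independent oracle: explicit O/E, correlation, eigh
        B = m.balanced()[sl, sl]
        n = B.shape[0]
        oe = np.zeros_like(B)
        for d in range(-n + 1, n):
            vals = np.diagonal(B, d)
            idx = np.arange(n - abs(d))
            if d >= 0:
                oe[idx, idx + d] = vals / vals.mean()
            else:
                oe[idx - d, idx] = vals / vals.mean()
        C = np.corrcoef(oe)
        w, v = np.linalg.eigh(C)
        lead = v[:, np.argmax(w)]
        got = track.ev1[sl]
        r = np.corrcoef(got, lead)[0, 1]
        assert abs(r) > 0.99

    def test_recovers_planted_labels(self):
        bt, tr, m = _single_chrom_checkerboard()
        track = compute_ev1(m, tr.ev1)
        ok = np.isfinite(track.ev1)
        assert abs(np.corrcoef(track.ev1[ok], tr.ev1[ok])[0, 1]) > 0.9

    def test_sign_flip_antisymmetry(self, sampled_checkerboard, alternating_track):
        up = compute_ev1(sampled_checkerboard, alternating_track.ev1)
        dn = compute_ev1(sampled_checkerboard, -alternating_track.ev1)
        np.testing.assert_allclose(up.ev1, -dn.ev1, equal_nan=True, atol=1e-12)

    def test_uniform_matrix_warns_and_reports_no_signal(self, desk_bins):
        n = desk_bins.n_bins
        m = ContactMatrix(desk_bins, np.full((n, n), 50.0), weights=np.ones(n))
        ref = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        with pytest.warns(UserWarning, match="no eigenvector correlates"):
            track = compute_ev1(m, ref)
        assert max(abs(c) for c in track.reference_corr.values()) < 0.3

    def test_small_chromosome_left_undefined(self):
        g = Genome(("big", "tiny"), (30 * Mb, 3 * Mb), (15 * Mb, 1 * Mb))
        bt = build_bin_table(g, 250_000, 1_000_000)
        ev = np.where(np.arange(bt.n_bins) % 8 < 4, 1.0, -1.0)
        tr = CompartmentTrack(bt, ev)
        E = expected_contact_map(bt, tr, checkerboard_params())
        with pytest.warns(UserWarning, match="unmasked bins"):
            track = compute_ev1(as_matrix(bt, E), ev)
        assert np.isnan(track.ev1[bt.chrom_slice("tiny")]).all()
        assert np.isfinite(track.ev1[bt.chrom_slice("big")]).all()


class TestSaddle:
    def test_symmetric_affinity_ratio_recovered(self, checkerboard_matrix,
                                                alternating_track):
        sad = saddle_strength(checkerboard_matrix, alternating_track, "cis")
        assert sad.strength_AA == pytest.approx(2.0, rel=0.05)
        assert sad.strength_BB == pytest.approx(2.0, rel=0.05)

    def test_asymmetric_ratios_recovered(self, desk_bins, alternating_track):
        E = expected_contact_map(desk_bins, alternating_track,
                                 checkerboard_params(c_AA=3.0, c_BB=1.5))
        sad = saddle_strength(as_matrix(desk_bins, E), alternating_track, "cis")
        assert sad.strength_AA == pytest.approx(3.0, rel=0.05)
        assert sad.strength_BB == pytest.approx(1.5, rel=0.05)

    def test_null_affinities_give_unit_strength(self, desk_bins, alternating_track):
        E = expected_contact_map(desk_bins, alternating_track,
                                 checkerboard_params(c_AA=1.0, c_BB=1.0))
        sad = saddle_strength(as_matrix(desk_bins, E), alternating_track, "cis")
        assert sad.strength_AA == pytest.approx(1.0, abs=0.02)
        assert sad.strength_BB == pytest.approx(1.0, abs=0.02)

    def test_trans_elevated_AA_only(self, desk_bins, alternating_track):
        E = expected_contact_map(desk_bins, alternating_track,
                                 checkerboard_params(c_AA=1, c_BB=1,
                                                     t_AA=1.6, t_BB=1.0, t_AB=1.0))
        sad = saddle_strength(as_matrix(desk_bins, E), alternating_track, "trans")
        assert sad.strength_AA == pytest.approx(1.6, rel=0.05)
        assert sad.strength_BB == pytest.approx(1.0, abs=0.05)

    def test_monotone_in_planted_affinity_ratio(self, desk_bins, alternating_track):
        got = []
        for ratio in (1.0, 1.5, 2.0, 3.0):
            E = expected_contact_map(desk_bins, alternating_track,
                                     checkerboard_params(c_AA=ratio, c_BB=ratio))
            m = sample_contact_map(desk_bins, E, 1_000_000, seed=21)
            m = ic_balance(mask_low_coverage(m))
            ev = compute_ev1(m, alternating_track.ev1)
            got.append(saddle_strength(m, ev, "cis").strength_AA)
        assert all(b > a for a, b in zip(got, got[1:]))


def _track(bt, values):
    return CompartmentTrack(bt, np.asarray(values, float))


class TestClassifySwitches:
    def test_basic_categories_and_thresholds(self):
        g = Genome(("c",), (30 * Mb,))
        bt = build_bin_table(g, Mb, Mb)
        n = bt.n_bins
        a = np.full(n, 0.8)
        b = np.full(n, 0.8)
        c = np.full(n, 0.8)
        b[1] = -0.7            # ABA at bin 1? -> second state B
        c[2] = 0.03            # within threshold band -> ambiguous
        a[3] = np.nan          # undefined
        table = classify_switches([_track(bt, a), _track(bt, b), _track(bt, c)])
        assert table.category[0] == "AAA"
        assert table.category[1] == "ABA"
        assert table.category[2] == "ambiguous"
        assert table.category[3] == "undefined"
        assert table.n_classified == n - 1

    def test_fraction_denominator_is_classified_bins(self):
        g = Genome(("c",), (10 * Mb,))
        bt = build_bin_table(g, Mb, Mb)
        v = np.full(10, 0.8)
        v2 = v.copy()
        v2[0] = 0.0   # one ambiguous bin
        t = classify_switches([_track(bt, v), _track(bt, v2), _track(bt, v)])
        assert t.fractions["AAA"] == pytest.approx(0.9)
        assert t.fractions["ambiguous"] == pytest.approx(0.1)

    def test_mismatched_bin_tables_rejected(self, small_bins, desk_bins):
        a = _track(small_bins, np.ones(small_bins.n_bins))
        b = _track(desk_bins, np.ones(desk_bins.n_bins))
        with pytest.raises(ValueError, match="bin tables"):
            classify_switches([a, a, b])


class TestIntersectionFraction:
    def _table(self, bt, cats):
        cats = np.asarray(cats, dtype=object)
        return SwitchTable(bt, cats, {}, len(cats))

    def test_identical_tables_give_one(self, small_bins):
        cats = np.resize(["AAA", "ABB"], small_bins.n_bins)
        t = self._table(small_bins, cats)
        assert intersection_fraction([t, t]) == 1.0

    def test_one_of_ten_differs(self):
        g = Genome(("c",), (10 * Mb,))
        bt = build_bin_table(g, Mb, Mb)
        a = ["AAA"] * 10
        b = ["AAA"] * 9 + ["BBB"]
        assert intersection_fraction([self._table(bt, a), self._table(bt, b)]) == 0.9

    def test_random_equiprobable_tables_match_analytic_rate(self, desk_bins):
        """Independent uniform categories agree at ~8 * (1/8)^k."""
        from hicstats.compartments import SWITCH_CATEGORIES
        rng = np.random.default_rng(0)
        n = desk_bins.n_bins
        for k in (2, 3):
            tables = [self._table(desk_bins,
                                  rng.choice(SWITCH_CATEGORIES, n))
                      for _ in range(k)]
            got = intersection_fraction(tables)
            expect = 8 * (1 / 8) ** k
            sd = np.sqrt(expect * (1 - expect) / n)
            assert abs(got - expect) < 4 * sd

    def test_single_table_rejected(self, small_bins):
        t = self._table(small_bins, np.resize(["AAA"], small_bins.n_bins))
        with pytest.raises(ValueError, match="two"):
            intersection_fraction([t])


class TestSummarizeByGroup:
    def _switch(self, bt):
        cats = np.where(np.arange(bt.n_bins) % 2 == 0, "AAA", "BBB").astype(object)
        return SwitchTable(bt, cats, {}, bt.n_bins)

    def test_single_group_populated(self, small_bins):
        sw = self._switch(small_bins)
        expr = pd.DataFrame({"gene_id": ["g1", "g2"], "chrom": ["chrA", "chrA"],
                             "start": [0, 500_000], "end": [1000, 501_000],
                             "TPM_s1": [5.0, 7.0]})
        out, skipped = summarize_by_group(sw, expr)
        assert skipped == 0
        assert set(out["group"]) == {"AAA"}  # bins 0 and 2 are both even
        assert out.iloc[0]["n_genes"] == 2

    def test_planted_A_high_expression_ranks_groups(self, small_bins):
        rng = np.random.default_rng(0)
        sw = self._switch(small_bins)
        rows = []
        for i in range(small_bins.n_bins):
            if small_bins.is_mito_bin[i]:
                continue
            high = sw.category[i] == "AAA"
            rows.append({"gene_id": f"g{i}",
                         "chrom": small_bins.genome.chrom_names[small_bins.chrom_code[i]],
                         "start": int(small_bins.start[i]) + 10,
                         "end": int(small_bins.start[i]) + 500,
                         "TPM_x": float(rng.lognormal(3.0 if high else 0.0, 0.3))})
        out, _ = summarize_by_group(sw, pd.DataFrame(rows))
        med = out.set_index("group")["median_tpm"]
        assert med["AAA"] > med["BBB"]

    def test_gene_outside_genome_skipped_with_count(self, small_bins):
        sw = self._switch(small_bins)
        expr = pd.DataFrame({"gene_id": ["g1"], "chrom": ["chrZ"],
                             "start": [0], "end": [100], "TPM_s1": [1.0]})
        out, skipped = summarize_by_group(sw, expr)
        assert skipped == 1 and len(out) == 0

    def test_empty_table_gives_empty_summary(self, small_bins):
        sw = self._switch(small_bins)
        expr = pd.DataFrame(columns=["gene_id", "chrom", "start", "end", "TPM_s1"])
        out, skipped = summarize_by_group(sw, expr)
        assert len(out) == 0 and skipped == 0
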