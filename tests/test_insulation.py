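import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hicstats import (ContactMatrix, Genome, aggregate_insulation, build_bin_table,
                      call_boundaries, compare_boundary_sets, expected_contact_map,
                      insulation_track)
from hicstats.compartments import CompartmentTrack
from hicstats.insulation import BoundaryCall, InsulationTrack

from conftest import as_matrix, checkerboard_params

Mb = 1_000_000


def _flat_track(n_mb=40):
    g = Genome(("chr1", "chr2"), (n_mb * Mb, 20 * Mb), (n_mb * Mb // 2, 10 * Mb))
    bt = build_bin_table(g, 250_000, 1_000_000)
    return bt, CompartmentTrack(bt, np.zeros(bt.n_bins))


def _expected_with_boundaries(bt, tr, boundaries, beta=None):
    p = checkerboard_params(c_AA=1.0, c_BB=1.0)
    p.boundaries = boundaries
    return as_matrix(bt, expected_contact_map(bt, tr, p))


def brute_force_insulation(matrix, window):
    """Independent reimplementation of the diamond score by explicit loops."""
    bt = matrix.bin_table
    w = window // bt.bin_size
    B = matrix.balanced()
    out = np.full(bt.n_bins, np.nan)
    for code, mito in enumerate(bt.genome.is_mito):
        if mito:
            continue
        sl = bt.chrom_slice(code)
        sub = B[sl, sl]
        n = sub.shape[0]
        # positional factor from observed vs expected row sums
        m_exp = np.zeros_like(sub)
        for i in range(n):
            for j in range(n):
                d = abs(i - j)
                m_exp[i, j] = np.nanmean(np.diagonal(sub, d))
        r = np.nansum(sub, axis=1) / np.nansum(m_exp, axis=1)
        r = r / np.nanmean(r)
        D = sub / np.outer(r, r)
        dia = np.full(n, np.nan)
        for i in range(w, n - w):
            vals = [D[a, b] for a in range(i - w, i) for b in range(i + 1, i + w + 1)]
            if np.all(np.isfinite(vals)):
                m = np.mean(vals)
                dia[i] = m if m > 0 else np.nan
        cm = np.nanmean(dia)
        out[sl] = np.log2(dia / cm)
    return out


class TestInsulationTrack:
    def test_uniform_map_scores_zero(self):
        g = Genome(("c",), (20 * Mb,))
        bt = build_bin_table(g, Mb, Mb)
        m = ContactMatrix(bt, np.ones((20, 20)), weights=np.ones(20))
        ins = insulation_track(m, 3 * Mb)
        defined = np.isfinite(ins.score)
        assert defined.sum() == 20 - 6
        np.testing.assert_allclose(ins.score[defined], 0.0, atol=1e-9)

    def test_matches_brute_force_diamonds_exactly(self):
        bt, tr = _flat_track()
        m = _expected_with_boundaries(bt, tr, [("chr1", 10 * Mb, 0.5),
                                               ("chr2", 8 * Mb, 0.4)])
        ins = insulation_track(m, 750_000)
        ref = brute_force_insulation(m, 750_000)
        np.testing.assert_allclose(ins.score, ref, equal_nan=True, atol=1e-10)

    def test_planted_boundary_is_local_minimum(self):
        bt, tr = _flat_track()
        m = _expected_with_boundaries(bt, tr, [("chr1", 10 * Mb, 0.5)])
        ins = insulation_track(m, 750_000)
        b = bt.bin_id("chr1", 10 * Mb)
        sl = bt.chrom_slice("chr1")
        x = ins.score[sl]
        i = b - sl.start
        local = np.nanargmin(x[i - 4: i + 5]) + i - 4
        assert abs(local - i) <= 1

    def test_monotone_in_boundary_strength(self):
        bt, tr = _flat_track()
        vals = []
        for beta in (0.2, 0.4, 0.6, 0.8):
            m = _expected_with_boundaries(bt, tr, [("chr1", 10 * Mb, beta)])
            ins = insulation_track(m, 750_000)
            vals.append(ins.score[bt.bin_id("chr1", 10 * Mb)])
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_close_boundaries_merge_into_one_broad_minimum(self):
        bt, tr = _flat_track()
        bounds = [("chr1", 10 * Mb, 0.5), ("chr1", 10.5 * Mb, 0.5)]
        m = _expected_with_boundaries(bt, tr, bounds)
        ins = insulation_track(m, 750_000)
        calls = [c for c in call_boundaries(ins) if c.chrom == "chr1" and c.is_strong]
        lo = bt.bin_id("chr1", int(9 * Mb))
        hi = bt.bin_id("chr1", int(11.5 * Mb))
        inside = [c for c in calls if lo <= c.bin <= hi]
        assert len(inside) == 1

    def test_window_must_be_multiple_of_bin(self, small_bins):
        m = ContactMatrix(small_bins, np.ones((small_bins.n_bins,) * 2),
                          weights=np.ones(small_bins.n_bins))
        with pytest.raises(ValueError, match="multiple"):
            insulation_track(m, 300_000)

    def test_window_wider_than_chromosome_warns(self):
        g = Genome(("c", "d"), (4 * Mb, 40 * Mb), (2 * Mb, 20 * Mb))
        bt = build_bin_table(g, Mb, Mb)
        n = bt.n_bins
        m = ContactMatrix(bt, np.ones((n, n)), weights=np.ones(n))
        with pytest.warns(UserWarning, match="too wide"):
            ins = insulation_track(m, 3 * Mb)
        assert np.isnan(ins.score[bt.chrom_slice("c")]).all()


def test_boundary_free_map_yields_no_strong_calls(desk_bins):
    """A deeply sampled featureless map (no boundaries, no compartments)
    must produce at most a couple of strong boundary calls genome-wide."""
    from hicstats import ic_balance, mask_low_coverage, sample_contact_map
    from hicstats.simulate import expected_contact_map
    tr = CompartmentTrack(desk_bins, np.zeros(desk_bins.n_bins))
    E = expected_contact_map(
        desk_bins, tr, checkerboard_params(c_AA=1.0, c_BB=1.0, alpha2=1.5,
                                           f_cis=0.8))
    m = ic_balance(mask_low_coverage(sample_contact_map(desk_bins, E,
                                                        50_000_000, seed=6)))
    strong = [b for b in call_boundaries(insulation_track(m, 500_000))
              if b.is_strong]
    assert len(strong) <= 2


class TestCallBoundaries:
    def _track_from_values(self, values):
        g = Genome(("c",), (len(values) * Mb,))
        bt = build_bin_table(g, Mb, Mb)
        return InsulationTrack(bt, 2 * Mb, np.asarray(values, float))

    def test_monotone_track_has_no_boundaries(self):
        t = self._track_from_values(np.linspace(-1, 1, 30))
        assert call_boundaries(t, detrend_bins=0) == []

    def test_strength_is_gap_to_lower_flanking_maximum(self):
        vals = np.zeros(15)
        vals[5] = 0.3   # left max
        vals[7] = -0.5  # minimum
        vals[9] = 0.6   # right max
        calls = call_boundaries(self._track_from_values(vals), detrend_bins=0)
        min_call = [c for c in calls if c.bin == 7]
        assert len(min_call) == 1
        assert min_call[0].strength == pytest.approx(0.3 - (-0.5))

    def test_threshold_is_strict(self):
        vals = np.zeros(11)
        vals[5] = -0.1
        calls = call_boundaries(self._track_from_values(vals), detrend_bins=0)
        c = [x for x in calls if x.bin == 5][0]
        assert c.strength == pytest.approx(0.1)
        assert not c.is_strong
        vals[5] = -0.1001
        c2 = [x for x in call_boundaries(self._track_from_values(vals),
                                         detrend_bins=0) if x.bin == 5][0]
        assert c2.is_strong

    def test_plateau_minimum_takes_leftmost_bin(self):
        vals = np.zeros(12)
        vals[5] = vals[6] = -0.4
        calls = call_boundaries(self._track_from_values(vals), detrend_bins=0)
        assert [c.bin for c in calls if c.is_strong] == [5]


def _call(chrom, b):
    return BoundaryCall(chrom, b, b * 250_000, 0.5, True)


class TestCompareBoundarySets:
    def test_identical_sets_all_common(self):
        a = [_call("c", i) for i in (3, 9, 20)]
        out = compare_boundary_sets(a, [(_call("c", i)) for i in (3, 9, 20)])
        assert len(out["common"]) == 3
        assert out["a_specific"] == [] and out["b_specific"] == []

    def test_far_separated_sets_share_nothing(self):
        out = compare_boundary_sets([_call("c", 2)], [_call("c", 50)], 1)
        assert out["common"] == []
        assert len(out["a_specific"]) == 1 and len(out["b_specific"]) == 1

    def test_adjacent_bins_match_within_tolerance(self):
        out = compare_boundary_sets([_call("c", 10)], [_call("c", 11)], 1)
        assert len(out["common"]) == 1

    def test_different_chromosomes_never_match(self):
        out = compare_boundary_sets([_call("c", 10)], [_call("d", 10)], 1)
        assert out["common"] == []

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(a=st.lists(st.integers(0, 60), max_size=15),
           b=st.lists(st.integers(0, 60), max_size=15),
           tol=st.integers(0, 3))
    def test_partition_sizes_sum_and_symmetry(self, a, b, tol):
        ca = [_call("c", i) for i in a]
        cb = [_call("c", i) for i in b]
        out = compare_boundary_sets(ca, cb, tol)
        assert len(out["a_specific"]) + len(out["common"]) == len(ca)
        assert len(out["b_specific"]) + len(out["common"]) == len(cb)
        swapped = compare_boundary_sets(cb, ca, tol)
        assert len(swapped["common"]) == len(out["common"])
        assert len(swapped["a_specific"]) == len(out["b_specific"])


class TestAggregateInsulation:
    def test_profile_minimum_at_offset_zero(self):
        bt, tr = _flat_track()
        bounds = [("chr1", x * Mb, 0.6) for x in (6, 12, 18, 24, 30)]
        m = _expected_with_boundaries(bt, tr, bounds)
        ins = insulation_track(m, 750_000)
        calls = [c for c in call_boundaries(ins) if c.is_strong]
        agg = aggregate_insulation(ins, calls, flank=1_000_000)
        assert np.argmin(agg.profile) == len(agg.offsets) // 2
        assert agg.stackup.shape[0] + agg.n_dropped == len(calls)

    def test_flat_profile_on_uniform_map(self):
        g = Genome(("c",), (30 * Mb,))
        bt = build_bin_table(g, Mb, Mb)
        m = ContactMatrix(bt, np.ones((30, 30)), weights=np.ones(30))
        ins = insulation_track(m, 2 * Mb)
        fake = [BoundaryCall("c", b, b * Mb, 0.0, False) for b in (10, 15, 20)]
        agg = aggregate_insulation(ins, fake, flank=2 * Mb)
        np.testing.assert_allclose(agg.profile, 0.0, atol=1e-9)

    def test_empty_boundary_list_rejected(self):
        bt, tr = _flat_track()
        m = _expected_with_boundaries(bt, tr, [])
        ins = insulation_track(m, 750_000)
        with pytest.raises(ValueError, match="empty"):
            aggregate_insulation(ins, [], flank=500_000)

    def test_flank_must_be_bin_multiple(self):
        bt, tr = _flat_track()
        m = _expected_with_boundaries(bt, tr, [])
        ins = insulation_track(m, 750_000)
        with pytest.raises(ValueError, match="multiple"):
            aggregate_insulation(ins, [BoundaryCall("chr1", 20, 5 * Mb, 0.5, True)],
                                 flank=300_000)
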