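"""Chromosome-territory and chromosome-end statistics.

Covers the whole-chromosome view of nuclear organization: averaged trans
interaction maps scaled to a universal chromosome coordinate (where clustered
telomeres show up as corner peaks and clustered centromeres as a peak at the
length-proportional centromere position), aggregate telomere/centromere
enrichments, the matrix of pairwise chromosome-arm-end contact frequencies,
virtual 4C profiles, and the mitochondrial-nuclear background score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .contacts import ContactMatrix
from .genome import BinTable

__all__ = [
    "ScaledTransMap",
    "TelomerePairMatrix",
    "scaled_trans_map",
    "telcen_aggregate",
    "telomere_pair_matrix",
    "virtual_4c",
    "mito_nuclear_score",
]


def _trans_corrected(B: np.ndarray, bt: BinTable, codes: list[int]) -> np.ndarray:
    """Balanced map with per-bin trans-marginal factors divided out.

    Matrix balancing equalizes each bin's *total* marginal, which leaves a
    positional factor in the trans sector (bins near chromosome ends trade
    cis for trans mass and come out systematically elevated). Dividing each
    trans pair by the product of its bins' mean trans levels (relative to
    the overall trans mean) removes that bin-wise factor while leaving
    pair-specific structure — end-region clustering, homotypic affinity
    corners — essentially intact, since any single bin's flagged partners
    are a small share of its trans row. All enrichments in this module are
    computed on this corrected map.
    """
    sel = np.zeros(bt.n_bins, dtype=bool)
    for c in codes:
        sel[bt.chrom_slice(c)] = True
    cis = bt.chrom_code[:, None] == bt.chrom_code[None, :]
    trans_sel = sel[:, None] & sel[None, :] & ~cis
    # estimate each bin's factor against unflagged partners only, so genuine
    # end-region clustering does not feed back into its own correction
    plain = ~(bt.in_telomere_end | bt.in_centromere_flank)
    ref_cols = trans_sel & plain[None, :]
    if ref_cols.sum() < 0.05 * max(trans_sel.sum(), 1):
        ref_cols = trans_sel
    T = np.where(ref_cols, B, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        overall = np.nanmean(np.where(ref_cols & plain[:, None], B, np.nan))
        with np.errstate(invalid="ignore"):
            g = np.nanmean(T, axis=1) / overall
    g = np.where(np.isfinite(g) & (g > 0), g, 1.0)
    out = B / (g[:, None] * g[None, :])
    return out


def _subset_codes(bt: BinTable, subset) -> list[int]:
    names = bt.genome.chrom_names
    non_mito = [c for c, m in enumerate(bt.genome.is_mito) if not m]
    if subset in (None, "all"):
        return non_mito
    if subset == "large":
        return [c for c in non_mito if names[c] in {f"chr{i}" for i in range(1, 13)}]
    if subset == "small":
        return [c for c in non_mito if names[c] in {f"chr{i}" for i in range(13, 23)}]
    return [names.index(n) for n in subset]


@dataclass
class ScaledTransMap:
    """Average observed/expected trans map in universal chromosome coordinates.

    Both axes run p -> q, so telomere clustering appears at the (0,0) and
    (n-1,n-1) corners of ``map`` and centromere clustering as an interior
    peak on ``diagonal_profile``.
    """

    map: np.ndarray                 # (n_scaled, n_scaled)
    diagonal_profile: np.ndarray    # len n_scaled
    subset: str
    n_pairs: int


def _overlap_weights(length: int, bin_size: int, n_bins: int, n_scaled: int,
                     offset_starts: np.ndarray, offset_ends: np.ndarray) -> np.ndarray:
    """(n_scaled, n_bins) matrix of bp overlaps between scaled slots and bins."""
    M = np.zeros((n_scaled, n_bins))
    slot = length / n_scaled
    for k in range(n_scaled):
        lo, hi = k * slot, (k + 1) * slot
        ov = np.minimum(offset_ends, hi) - np.maximum(offset_starts, lo)
        M[k] = np.clip(ov, 0, None)
    return M


def scaled_trans_map(matrix: ContactMatrix, n_scaled: int = 50,
                     subset="all") -> ScaledTransMap:
    """Average all trans chromosome-pair blocks on a universal scaled axis.

    Each ordered pair's block is rescaled to ``n_scaled x n_scaled`` by
    length-weighted bin averaging of the balanced map, divided by the pair's
    mean trans contact (observed/expected), then averaged across pairs (both
    orders, so the result is symmetric).
    """
    bt = matrix.bin_table
    codes = _subset_codes(bt, subset)
    if len(codes) < 2:
        raise ValueError("subset must contain at least 2 chromosomes")
    B = _trans_corrected(matrix.balanced(), bt, codes)
    weights = {}
    for c in codes:
        sl = bt.chrom_slice(c)
        weights[c] = _overlap_weights(bt.genome.chrom_lengths[c], bt.bin_size,
                                      sl.stop - sl.start, n_scaled,
                                      bt.start[sl].astype(float), bt.end[sl].astype(float))
    acc = np.zeros((n_scaled, n_scaled))
    acc_n = np.zeros((n_scaled, n_scaled))
    n_pairs = 0
    for a in codes:
        for b in codes:
            if a == b:
                continue
            block = B[bt.chrom_slice(a), bt.chrom_slice(b)]
            mean = np.nanmean(block)
            if not np.isfinite(mean) or mean <= 0:
                continue
            fin = np.isfinite(block)
            num = weights[a] @ np.where(fin, block, 0.0) @ weights[b].T
            den = weights[a] @ fin.astype(float) @ weights[b].T
            with np.errstate(invalid="ignore"):
                scaled = np.where(den > 0, num / den, np.nan) / mean
            ok = np.isfinite(scaled)
            acc[ok] += scaled[ok]
            acc_n[ok] += 1
            n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no valid trans blocks in subset")
    avg = np.where(acc_n > 0, acc / np.maximum(acc_n, 1), np.nan)
    label = subset if isinstance(subset, str) else "custom"
    return ScaledTransMap(avg, np.diagonal(avg).copy(), label, n_pairs)


def telcen_aggregate(matrix: ContactMatrix, subset="all") -> dict:
    """Aggregate trans enrichment of flagged chromosome-end regions.

    Returns ``{"tel_tel", "cen_cen", "tel_cen"}`` where each value is the mean
    observed/expected trans contact over bin pairs carrying the corresponding
    flags divided by the mean over all trans pairs in the subset.
    """
    bt = matrix.bin_table
    codes = _subset_codes(bt, subset)
    if len(codes) < 2:
        raise ValueError("subset must contain at least 2 chromosomes")
    B = _trans_corrected(matrix.balanced(), bt, codes)
    tel = bt.in_telomere_end
    cen = bt.in_centromere_flank
    sums = {"tel_tel": [0.0, 0], "cen_cen": [0.0, 0], "tel_cen": [0.0, 0], "all": [0.0, 0]}
    for ia, a in enumerate(codes):
        for b in codes[ia + 1:]:
            sa, sb = bt.chrom_slice(a), bt.chrom_slice(b)
            block = B[sa, sb]
            m = np.nanmean(block)
            if not np.isfinite(m) or m <= 0:
                continue
            oe = block / m
            fin = np.isfinite(oe)
            ta, tb = tel[sa], tel[sb]
            ca, cb = cen[sa], cen[sb]
            sel = {
                "tel_tel": ta[:, None] & tb[None, :],
                "cen_cen": ca[:, None] & cb[None, :],
                "tel_cen": (ta[:, None] & cb[None, :]) | (ca[:, None] & tb[None, :]),
                "all": np.ones_like(fin),
            }
            for k, s in sel.items():
                s = s & fin
                sums[k][0] += oe[s].sum()
                sums[k][1] += int(s.sum())
    if sums["tel_tel"][1] == 0 and sums["cen_cen"][1] == 0:
        raise ValueError("no flagged (telomere/centromere) bin pairs in subset")
    base = sums["all"][0] / sums["all"][1]
    out = {}
    for k in ("tel_tel", "cen_cen", "tel_cen"):
        s, n = sums[k]
        out[k] = float((s / n) / base) if n else float("nan")
    return out


@dataclass
class TelomerePairMatrix:
    """Pairwise contact frequencies between chromosome-arm terminal regions.

    ``arms`` lists the 2 x n_chroms arm ends in order (chr1p, chr1q, chr2p,
    ...); ``values[i, j]`` is the mean balanced contact between the two
    ``end_size`` terminal regions, normalized by the genome-wide mean trans
    contact. Same-arm entries and arms shorter than ``end_size`` are NaN with
    ``defined`` False — undetectable regions are flagged, never zero-filled.
    """

    arms: list[str]
    values: np.ndarray
    defined: np.ndarray
    end_size: int

    @property
    def mean_defined(self) -> float:
        return float(np.nanmean(self.values[self.defined]))


def telomere_pair_matrix(matrix: ContactMatrix, end_size: int = 1_000_000) -> TelomerePairMatrix:
    """All pairwise cis and trans contacts between terminal arm regions."""
    bt = matrix.bin_table
    if end_size < bt.bin_size:
        raise ValueError("end_size must be >= bin size")
    B = _trans_corrected(matrix.balanced(), bt,
                         [c for c, m in enumerate(bt.genome.is_mito) if not m])
    # genome-wide mean trans contact (non-mito)
    cis = matrix.cis_pair_mask()
    mito = bt.is_mito_bin
    trans_sel = ~cis & ~mito[:, None] & ~mito[None, :]
    vals = B[trans_sel]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        base = np.nanmean(vals) if vals.size else np.nan
    if not np.isfinite(base) or base <= 0:
        raise ValueError("no defined trans contacts to normalize against")

    arms = []
    regions = []  # (chrom_code, bin index array) or None when undefined
    for c, (name, L, cen, m) in enumerate(zip(bt.genome.chrom_names, bt.genome.chrom_lengths,
                                              bt.genome.centromere_mid, bt.genome.is_mito)):
        if m:
            continue
        sl = bt.chrom_slice(c)
        p_len = cen if cen is not None else 0
        q_len = L - cen if cen is not None else L
        for arm, arm_len in (("p", p_len), ("q", q_len)):
            arms.append(f"{name}{arm}")
            if arm_len < end_size:
                regions.append(None)
                continue
            if arm == "p":
                idx = np.flatnonzero((bt.start[sl] < end_size)) + sl.start
            else:
                idx = np.flatnonzero((bt.end[sl] > L - end_size)) + sl.start
            idx = idx[matrix.mask[idx]]
            regions.append((c, idx) if len(idx) else None)
    n = len(arms)
    values = np.full((n, n), np.nan)
    defined = np.zeros((n, n), dtype=bool)
    for i in range(n):
        if regions[i] is None:
            continue
        ci, bi = regions[i]
        for j in range(i, n):
            if regions[j] is None:
                continue
            cj, bj = regions[j]
            if ci == cj and i == j:
                continue  # same arm: cis self-block is not an end-pair contact
            block = B[np.ix_(bi, bj)]
            if np.isfinite(block).any():
                v = float(np.nanmean(block) / base)
                values[i, j] = values[j, i] = v
                defined[i, j] = defined[j, i] = True
    return TelomerePairMatrix(arms, values, defined, end_size)


def virtual_4c(matrix: ContactMatrix, anchor: tuple[str, int, int]) -> np.ndarray:
    """4C-style profile of one anchor interval against the whole genome.

    ``anchor`` is (chrom, start, end). The profile is the mean balanced
    contact between the anchor's unmasked bins and every other bin,
    normalized to sum to 1 over the defined bins of the anchor chromosome.
    Anchor self-bins are excluded (NaN).
    """
    chrom, start, end = anchor
    bt = matrix.bin_table
    code = bt.genome.chrom_names.index(chrom)
    sl = bt.chrom_slice(code)
    in_anchor = np.zeros(bt.n_bins, dtype=bool)
    in_anchor[sl] = (bt.start[sl] < end) & (bt.end[sl] > start)
    in_anchor &= matrix.mask
    if not in_anchor.any():
        raise ValueError("anchor covers no unmasked bin")
    B = matrix.balanced()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        profile = np.nanmean(B[in_anchor], axis=0)
    profile[in_anchor] = np.nan
    on_chrom = np.zeros(bt.n_bins, dtype=bool)
    on_chrom[sl] = True
    norm = np.nansum(profile[on_chrom & np.isfinite(profile)])
    if norm <= 0:
        # anchor spans its whole chromosome: fall back to the genome-wide sum
        norm = np.nansum(profile[np.isfinite(profile)])
    if norm <= 0:
        raise ValueError("anchor chromosome has no defined contacts")
    return profile / norm


def mito_nuclear_score(matrix: ContactMatrix) -> float:
    """Enrichment of mitochondrial-nuclear contacts over a uniform background.

    (mito x nuclear contact sum / total contacts) divided by
    (mito x nuclear bin-pair count / total bin-pair count), on raw counts.
    Values > 1 indicate enrichment; intact mitochondria give near-zero scores.
    """
    bt = matrix.bin_table
    mito = bt.is_mito_bin
    if not mito.any():
        raise ValueError("genome has no mitochondrial contig")
    n = bt.n_bins
    mn_sum = matrix.counts[mito][:, ~mito].sum()
    total = matrix.total_contacts
    if total == 0:
        raise ValueError("empty matrix")
    n_m = int(mito.sum())
    n_nuc = n - n_m
    pair_frac = (n_m * n_nuc) / (n * (n + 1) / 2)
    return float((mn_sum / total) / pair_frac)
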