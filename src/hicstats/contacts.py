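"""Contact-matrix data model, balancing, masking and distance-decay statistics.

The observed map O is held dense and symmetric (desk-scale genomes keep this
well under a GB). Iterative correction (ICE / Sinkhorn) assigns each unmasked
bin a multiplicative weight so that balanced marginals are equal; all
enrichment statistics downstream operate on the balanced map with masked bins
excluded, never deleted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genome import BinTable

__all__ = [
    "ContactMatrix",
    "PsCurve",
    "mask_low_coverage",
    "ic_balance",
    "cis_fraction",
    "ps_curve",
    "long_range_fraction",
    "fit_ps_slope",
]


class ContactMatrix:
    """Symmetric genome-wide binned contact counts with weights and a mask.

    Parameters
    ----------
    bin_table
        The genome tiling the counts are binned on.
    counts
        Dense symmetric nonnegative (n_bins, n_bins) array.
    weights
        Per-bin balancing multipliers; NaN where masked / not yet balanced.
    mask
        Per-bin validity flag (True = usable).
    """

    def __init__(self, bin_table: BinTable, counts: np.ndarray,
                 weights: np.ndarray | None = None, mask: np.ndarray | None = None,
                 balance_converged: bool | None = None):
        counts = np.asarray(counts, dtype=float)
        n = bin_table.n_bins
        if counts.shape != (n, n):
            raise ValueError(f"counts shape {counts.shape} != ({n}, {n})")
        if not np.allclose(counts, counts.T):
            raise ValueError("counts must be symmetric")
        if counts.min() < 0:
            raise ValueError("counts must be nonnegative")
        self.bin_table = bin_table
        self.counts = counts
        self.mask = np.ones(n, dtype=bool) if mask is None else np.asarray(mask, bool).copy()
        if weights is None:
            weights = np.full(n, np.nan)
        self.weights = np.asarray(weights, float).copy()
        self.weights[~self.mask] = np.nan
        self.balance_converged = balance_converged

    @property
    def n_bins(self) -> int:
        return self.bin_table.n_bins

    @property
    def total_contacts(self) -> float:
        """Sum of upper-triangle counts, diagonal included."""
        return float(np.triu(self.counts).sum())

    @property
    def is_balanced(self) -> bool:
        return bool(np.isfinite(self.weights[self.mask]).all()) if self.mask.any() else False

    def balanced(self) -> np.ndarray:
        """Balanced map w_i·O_ij·w_j with NaN on masked rows/columns."""
        if not self.is_balanced:
            raise ValueError("matrix is not balanced; run ic_balance first")
        w = self.weights
        B = self.counts * w[:, None] * w[None, :]
        B[~self.mask, :] = np.nan
        B[:, ~self.mask] = np.nan
        return B

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(self.bin_table, self.counts.copy(), self.weights.copy(),
                             self.mask.copy(), self.balance_converged)

    def cis_pair_mask(self) -> np.ndarray:
        """Boolean (n, n) matrix, True where both bins share a chromosome."""
        code = self.bin_table.chrom_code
        return code[:, None] == code[None, :]


@dataclass
class PsCurve:
    """Contact frequency P as a function of genomic separation s.

    ``mean_contact`` is the average balanced contact per log-spaced distance
    bin, normalized to unit area in log10(s) so curves from different samples
    are compared by shape alone. ``derivative`` is d log10 P / d log10 s,
    a centered finite difference after moving-average smoothing.
    """

    distance_bin_edges: np.ndarray   # bp, log-spaced, len n+1
    mean_contact: np.ndarray         # len n, NaN where empty
    derivative: np.ndarray           # len n, NaN where undefined

    @property
    def distance_centers(self) -> np.ndarray:
        e = self.distance_bin_edges
        return np.sqrt(e[:-1] * e[1:])


def observed_over_expected_cis(block: np.ndarray) -> np.ndarray:
    """Divide each diagonal of a (possibly NaN-masked) cis block by its mean.

    The standard distance normalization: the expected value of a pair at
    separation s is the mean over all pairs of that chromosome at the same
    separation.
    """
    n = block.shape[0]
    oe = np.full_like(block, np.nan)
    for d in range(n):
        vals = np.diagonal(block, offset=d)
        m = np.nanmean(vals) if np.isfinite(vals).any() else np.nan
        if np.isfinite(m) and m > 0:
            idx = np.arange(n - d)
            oe[idx, idx + d] = vals / m
            oe[idx + d, idx] = vals / m
    return oe


def mask_low_coverage(matrix: ContactMatrix, mad_k: float = 5.0,
                      mad_floor: float = 0.1) -> ContactMatrix:
    """Mask bins with zero or anomalously low coverage.

    A bin is masked if its marginal (full row sum; masking never deletes
    stored counts) is zero, or if log10(marginal) falls more than
    ``mad_k`` median absolute deviations below the median log-marginal.
    The MAD is floored at ``mad_floor`` (log10 units) so that on
    near-uniform maps, where the MAD collapses to sampling noise, ordinary
    coverage variation (chromosome ends, compartment identity) is not
    swallowed — the filter targets order-of-magnitude dropouts. Both the
    marginals and the reference median/MAD are computed from the stored
    counts, so the operation is exactly idempotent.
    """
    if mad_k <= 0:
        raise ValueError("mad_k must be > 0")
    out = matrix.copy()
    marg = out.counts.sum(axis=1)
    pos = marg > 0
    new_mask = out.mask & pos
    if pos.any():
        # reference statistics from all covered bins (mask-independent,
        # hence exactly idempotent)
        logm = np.log10(marg[pos])
        med = np.median(logm)
        mad = max(np.median(np.abs(logm - med)), mad_floor)
        cutoff = med - mad_k * mad
        new_mask &= np.where(pos, np.log10(np.where(pos, marg, 1.0)), -np.inf) >= cutoff
    if not new_mask.any():
        raise ValueError("matrix empty after masking")
    out.mask = new_mask
    out.weights[~new_mask] = np.nan
    return out


def ic_balance(matrix: ContactMatrix, max_iter: int = 200, tol: float = 1e-5) -> ContactMatrix:
    """Iterative correction: find weights equalizing balanced marginals.

    Sinkhorn-style symmetric iteration on the unmasked submatrix, diagonal
    included. Convergence is measured as the relative spread
    (max - min) / mean of the balanced marginals; weights are scaled so the
    mean balanced marginal is 1. Non-convergence is reported via a warning and
    ``balance_converged=False``, never silently accepted.
    """
    out = matrix.copy()
    valid = out.mask
    if not valid.any():
        raise ValueError("all bins masked")
    O = out.counts[np.ix_(valid, valid)]
    if (O.sum(axis=1) == 0).any():
        raise ValueError("unmasked bin with zero marginal; run mask_low_coverage first")
    w = np.ones(O.shape[0])
    converged = False
    for _ in range(max_iter):
        m = w * (O @ w)
        spread = (m.max() - m.min()) / m.mean()
        if spread < tol:
            converged = True
            break
        w = w / np.sqrt(m / m.mean())
    if not converged:
        m = w * (O @ w)
        warnings.warn(
            f"ic_balance: marginal spread {(m.max() - m.min()) / m.mean():.2e} "
            f"> tol {tol:g} after {max_iter} iterations"
        )
    # scale so mean balanced marginal is 1
    m = w * (O @ w)
    w = w / np.sqrt(m.mean())
    out.weights = np.full(out.n_bins, np.nan)
    out.weights[valid] = w
    out.balance_converged = converged
    return out


def cis_fraction(matrix: ContactMatrix, exclude_mito: bool = True) -> float:
    """Percentage of contacts with both ends on the same chromosome.

    A count statistic: uses raw (unbalanced) counts, includes diagonal
    self-pairs, and excludes the mitochondrial contig entirely (both from the
    numerator and the denominator) by default.
    """
    bt = matrix.bin_table
    keep = ~bt.is_mito_bin if exclude_mito else np.ones(matrix.n_bins, bool)
    sub = matrix.counts[np.ix_(keep, keep)]
    total = np.triu(sub).sum()
    if total == 0:
        raise ValueError("no contacts on non-mitochondrial chromosomes")
    cis = bt.chrom_code[keep]
    same = cis[:, None] == cis[None, :]
    cis_sum = np.triu(sub * same).sum()
    return float(100.0 * cis_sum / total)


def _pair_distances(bt: BinTable, chrom_code: int) -> np.ndarray:
    sl = bt.chrom_slice(chrom_code)
    mids = bt.mid[sl]
    return np.abs(mids[:, None] - mids[None, :])


def ps_curve(matrix: ContactMatrix, bins_per_decade: int = 10,
             smooth_window: int = 5) -> PsCurve:
    """Average balanced cis contact frequency vs genomic separation.

    Pairs are pooled across chromosomes into log-spaced distance bins
    (``bins_per_decade`` per factor of 10, from one bin size up to the longest
    chromosome). The curve is normalized to unit area in log10(s); the
    derivative d log10 P / d log10 s is a centered finite difference of the
    ``smooth_window``-point moving average, reported at bin centers.
    """
    bt = matrix.bin_table
    B = matrix.balanced()
    s_min = float(bt.bin_size)
    s_max = float(max(bt.genome.chrom_lengths))
    n_edges = int(np.ceil(np.log10(s_max / s_min) * bins_per_decade)) + 1
    edges = np.logspace(np.log10(s_min), np.log10(s_max), n_edges)
    sums = np.zeros(len(edges) - 1)
    cnts = np.zeros(len(edges) - 1)
    for code, mito in enumerate(bt.genome.is_mito):
        if mito:
            continue
        sl = bt.chrom_slice(code)
        sub = B[sl, sl]
        d = _pair_distances(bt, code)
        iu = np.triu_indices(sub.shape[0], k=1)
        vals, dist = sub[iu], d[iu]
        ok = np.isfinite(vals)
        idx = np.digitize(dist[ok], edges) - 1
        inr = (idx >= 0) & (idx < len(sums))
        np.add.at(sums, idx[inr], vals[ok][inr])
        np.add.at(cnts, idx[inr], 1)
    mean = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    if np.sum(np.nan_to_num(mean) > 0) < 3:
        raise ValueError("fewer than 3 nonempty distance bins; P(s) undefined")
    # unit area in log10(s)
    dlog = np.diff(np.log10(edges))
    ok = np.isfinite(mean)
    mean = mean / np.nansum(mean[ok] * dlog[ok])

    logp = np.where(np.nan_to_num(mean) > 0, np.log10(np.where(mean > 0, mean, 1.0)), np.nan)
    sm = _moving_average_nan(logp, smooth_window)
    logs = np.log10(np.sqrt(edges[:-1] * edges[1:]))
    deriv = np.full_like(sm, np.nan)
    for i in range(1, len(sm) - 1):
        if np.isfinite(sm[i - 1]) and np.isfinite(sm[i + 1]):
            deriv[i] = (sm[i + 1] - sm[i - 1]) / (logs[i + 1] - logs[i - 1])
    return PsCurve(edges, mean, deriv)


def _moving_average_nan(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.copy()
    half = window // 2
    out = np.full_like(x, np.nan)
    for i in range(len(x)):
        seg = x[max(0, i - half): i + half + 1]
        if np.isfinite(seg).any():
            out[i] = np.nanmean(seg)
    return out


def fit_ps_slope(curve: PsCurve, s_min: float = 1e5, s_max: float = 1e7) -> float:
    """Log-log slope of P(s) over [s_min, s_max] by least squares."""
    c = curve.distance_centers
    ok = (c >= s_min) & (c <= s_max) & np.isfinite(curve.mean_contact) & (curve.mean_contact > 0)
    if ok.sum() < 3:
        raise ValueError("too few P(s) points in fitting range")
    coef = np.polyfit(np.log10(c[ok]), np.log10(curve.mean_contact[ok]), 1)
    return float(coef[0])


def long_range_fraction(matrix: ContactMatrix, cutoff: float = 2e6) -> float:
    """Fraction of cis contacts separating loci by more than ``cutoff`` bp.

    Uses raw cis counts (off-diagonal pairs measured between bin midpoints;
    self-pairs have distance 0 and count as short-range).
    """
    bt = matrix.bin_table
    total = 0.0
    far = 0.0
    for code, mito in enumerate(bt.genome.is_mito):
        if mito:
            continue
        sl = bt.chrom_slice(code)
        sub = matrix.counts[sl, sl]
        d = _pair_distances(bt, code)
        iu = np.triu_indices(sub.shape[0])
        total += sub[iu].sum()
        far += sub[iu][d[iu] > cutoff].sum()
    if total == 0:
        raise ValueError("no cis contacts")
    return float(far / total)
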