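"""Parametric generator of genome-wide Hi-C contact maps.

The generative model composes, per bin pair, the features the estimators in
this package measure:

* power-law distance decay in cis with exponent ``alpha1`` below a crossover
  ``s0`` and ``alpha2`` above it (continuous at ``s0``);
* two-state compartment block structure: a multiplicative homotypic /
  heterotypic affinity depending on the A/B labels of the two bins
  (cis ``c_AA, c_BB, c_AB``; trans ``t_AA, t_BB, t_AB``);
* planted insulating boundaries attenuating contacts that cross them by
  ``(1 - beta)`` per boundary, applied below 3 Mb separation only (TADs are a
  sub-megabase phenomenon; compartment-scale structure is untouched);
* chromosome-end clustering: contacts between two telomere-end bins (or two
  centromere-flank bins) are multiplied by ``w_tel`` (``w_cen``), cis and
  trans alike;
* a mitochondrial leak: mito-nuclear pairs get ``lambda_mito`` times the mean
  trans weight — the background signal of compromised mitochondria;
* a target genome-wide cis share ``f_cis``: the cis and trans blocks are
  rescaled so that the cis mass is exactly ``f_cis`` and the whole matrix
  sums to 1 over unordered bin pairs.

Maps are drawn as a single multinomial sample of ``n_contacts`` contacts over
unordered bin pairs, so sampled maps obey exact count conservation.

Presets encode the cell states of an in-vitro motor-neuron maturation time
course (primary fibroblast PF, iPSC, motor neurons at weeks 0/3/6) plus an
ALS C9orf72-mutant week-6 state whose nuclear reorganization is arrested
partway between weeks 3 and 6 and whose mito-nuclear background is elevated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .compartments import CompartmentTrack, SWITCH_CATEGORIES
from .contacts import ContactMatrix
from .genome import BinTable

__all__ = [
    "SimParams",
    "SwitchProbs",
    "default_switch_probs",
    "sample_switch_tracks",
    "PlantedTracks",
    "expected_contact_map",
    "sample_contact_map",
    "preset",
    "PRESET_NAMES",
    "default_boundaries",
    "simulate_state",
    "sample_expression_table",
]

BOUNDARY_RANGE_BP = 3_000_000  # boundaries only attenuate below this separation


@dataclass
class SimParams:
    """Parameters of the generative contact-map model. See module docstring."""

    alpha1: float = 1.0            # cis decay exponent below s0
    alpha2: float = 1.0            # cis decay exponent above s0
    s0: float = 2e6                # crossover distance, bp
    f_cis: float = 0.7             # genome-wide cis contact share
    c_AA: float = 2.0
    c_BB: float = 2.0
    c_AB: float = 1.0
    t_AA: float = 1.3
    t_BB: float = 1.3
    t_AB: float = 1.0
    boundaries: list | None = None          # explicit [(chrom, bp, beta), ...]
    boundary_spacing: float = 1.5e6         # used when boundaries is None
    boundary_beta: float = 0.5
    w_tel: float = 1.0
    w_cen: float = 1.0
    lambda_mito: float = 0.0
    n_contacts: int = 2_000_000
    seed: int = 0

    def __post_init__(self):
        for name in ("c_AA", "c_BB", "c_AB", "t_AA", "t_BB", "t_AB", "w_tel", "w_cen"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 < self.f_cis < 1):
            raise ValueError("f_cis must be in (0, 1)")
        if self.lambda_mito < 0:
            raise ValueError("lambda_mito must be >= 0")
        if self.n_contacts < 1:
            raise ValueError("n_contacts must be >= 1")
        if self.boundaries is not None:
            for chrom, pos, beta in self.boundaries:
                if not (0 < beta <= 1):
                    raise ValueError(f"boundary strength beta={beta} outside (0, 1]")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimParams":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("boundaries") is not None:
            d["boundaries"] = [tuple(b) for b in d["boundaries"]]
        return cls(**d)


@dataclass
class SwitchProbs:
    """Joint probabilities of the eight switch categories plus ambiguous.

    ``probs`` maps AAA..BBB and "ambiguous" to probabilities summing to 1.
    ``ev_magnitude_mean``/``ev_noise_sd`` parameterize the planted per-bin
    eigenvector magnitude for A/B bins; ambiguous bins sit near zero.
    ``mean_domain_length`` is the mean length of the contiguous domains the
    categories are smoothed into.
    """

    probs: dict = field(default_factory=dict)
    ev_magnitude_mean: float = 1.0
    ev_noise_sd: float = 0.15
    ambiguous_ev_sd: float = 0.02
    mean_domain_length: float = 1e6

    def __post_init__(self):
        total = sum(self.probs.values())
        if any(p < 0 for p in self.probs.values()):
            raise ValueError("probabilities must be >= 0")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"switch probabilities sum to {total}, not 1")


def default_switch_probs() -> SwitchProbs:
    """The default category mix: 16.5% always-A, 19.9% always-B, 7% for each
    of the six mixed orders, remainder ambiguous."""
    probs = {"AAA": 0.165, "BBB": 0.199}
    for c in SWITCH_CATEGORIES:
        if c not in probs:
            probs[c] = 0.07
    probs["ambiguous"] = round(1.0 - sum(probs.values()), 12)
    return SwitchProbs(probs=probs)


@dataclass
class PlantedTracks:
    """Planted truth from :func:`sample_switch_tracks`: three per-state
    compartment tracks (PF-like, iPSC-like, MN-like order) and the per-bin
    joint category."""

    tracks: list[CompartmentTrack]
    category: np.ndarray


def sample_switch_tracks(bin_table: BinTable, probs: SwitchProbs | None = None,
                         seed: int = 0) -> PlantedTracks:
    """Draw three correlated A/B label tracks with block (domain) structure.

    Categories are assigned per contiguous domain rather than per bin, giving
    maps the megabase block structure real compartments have. Domain lengths
    are 1 + Poisson(mean - 1) bins around the configured mean; the domain
    categories are a random permutation of a fixed genome-wide composition
    matching the category probabilities (largest-remainder rounding), so the
    planted genome fractions realize the probabilities up to domain-length
    variability rather than drifting with an independent draw per domain.
    Planted EV values: A/B bins get ±(magnitude ~ Normal(mean, sd), floored
    away from the call threshold); ambiguous bins get near-zero values in all
    three states.
    """
    probs = probs or default_switch_probs()
    rng = np.random.default_rng(seed)
    bt = bin_table
    cats = list(probs.probs.keys())
    p = np.array([probs.probs[c] for c in cats])
    mean_len_bins = max(1.0, probs.mean_domain_length / bt.bin_size)
    # draw domain segmentation first
    segments: list[tuple[int, int]] = []   # (global start bin, length)
    for code, mito in enumerate(bt.genome.is_mito):
        sl = bt.chrom_slice(code)
        n = sl.stop - sl.start
        if mito:
            continue
        pos = 0
        while pos < n:
            length = 1 + rng.poisson(mean_len_bins - 1.0)
            length = min(length, n - pos)
            segments.append((sl.start + pos, length))
            pos += length
    # fixed composition over domains: largest-remainder apportionment
    D = len(segments)
    quota = p * D
    counts = np.floor(quota).astype(int)
    rem = D - counts.sum()
    order = np.argsort(quota - np.floor(quota))[::-1]
    counts[order[:rem]] += 1
    domain_cats = np.repeat(np.array(cats, dtype=object), counts)
    rng.shuffle(domain_cats)
    category = np.full(bt.n_bins, "ambiguous", dtype=object)
    for (start, length), cat in zip(segments, domain_cats):
        category[start: start + length] = cat
    tracks = []
    for state in range(3):
        ev = np.zeros(bt.n_bins)
        for i, cat in enumerate(category):
            if cat == "ambiguous":
                ev[i] = rng.normal(0.0, probs.ambiguous_ev_sd)
            else:
                mag = abs(rng.normal(probs.ev_magnitude_mean, probs.ev_noise_sd))
                mag = max(mag, 0.2)  # keep planted A/B bins clear of the call band
                ev[i] = mag if cat[state] == "A" else -mag
        ev[bt.is_mito_bin] = 0.0
        tracks.append(CompartmentTrack(bt, ev, orientation_ref="planted"))
    return PlantedTracks(tracks, category)


def default_boundaries(bin_table: BinTable, spacing: float, beta: float) -> list:
    """Evenly spaced planted boundaries, one every ``spacing`` bp per
    non-mito chromosome, staying ``spacing`` clear of the chromosome ends."""
    out = []
    for name, L, mito in zip(bin_table.genome.chrom_names,
                             bin_table.genome.chrom_lengths,
                             bin_table.genome.is_mito):
        if mito:
            continue
        pos = spacing
        while pos < L - spacing / 2:
            out.append((name, float(pos), float(beta)))
            pos += spacing
    return out


def _affinity_codes(track: CompartmentTrack) -> np.ndarray:
    """0 = A, 1 = B, 2 = ambiguous/undefined."""
    call = track.call
    code = np.full(len(call), 2, dtype=np.intp)
    code[call == "A"] = 0
    code[call == "B"] = 1
    return code


def expected_contact_map(bin_table: BinTable, labels: CompartmentTrack,
                         params: SimParams) -> np.ndarray:
    """Dense expected contact-probability matrix under the generative model.

    Symmetric, nonnegative; the upper triangle (diagonal included) sums to 1
    with cis mass exactly ``params.f_cis``. Ambiguous bins interact with the
    heterotypic affinity, so they carry no compartment signal.
    """
    bt = bin_table
    p = params
    bin_size = bt.bin_size
    max_len = max(L for L, m in zip(bt.genome.chrom_lengths, bt.genome.is_mito) if not m)
    if not (bin_size < p.s0 < max_len):
        raise ValueError(f"s0={p.s0:g} outside (bin_size, max chromosome length)")
    code = _affinity_codes(labels)
    cis_aff = np.array([[p.c_AA, p.c_AB, p.c_AB],
                        [p.c_AB, p.c_BB, p.c_AB],
                        [p.c_AB, p.c_AB, p.c_AB]])
    trans_aff = np.array([[p.t_AA, p.t_AB, p.t_AB],
                          [p.t_AB, p.t_BB, p.t_AB],
                          [p.t_AB, p.t_AB, p.t_AB]])
    boundaries = p.boundaries
    if boundaries is None:
        boundaries = default_boundaries(bt, p.boundary_spacing, p.boundary_beta)

    n = bt.n_bins
    W = np.zeros((n, n))
    tel = bt.in_telomere_end
    cen = bt.in_centromere_flank
    mito = bt.is_mito_bin

    # ---- cis blocks
    for c, is_m in enumerate(bt.genome.is_mito):
        sl = bt.chrom_slice(c)
        if is_m:
            continue  # single-bin contig: no informative cis pairs
        mids = bt.mid[sl]
        s = np.abs(mids[:, None] - mids[None, :])
        s_eff = np.maximum(s, bin_size / 2.0)
        decay = np.where(
            s_eff <= p.s0,
            s_eff ** (-p.alpha1),
            p.s0 ** (p.alpha2 - p.alpha1) * s_eff ** (-p.alpha2),
        )
        block = decay * cis_aff[np.ix_(code[sl], code[sl])]
        # boundary attenuation via prefix sums of log(1 - beta)
        chrom = bt.genome.chrom_names[c]
        bpos = sorted(b[1] for b in boundaries if b[0] == chrom)
        if bpos:
            betas = {pos: b for ch, pos, b in boundaries if ch == chrom}
            bpos_arr = np.asarray(bpos)
            cross = np.searchsorted(bpos_arr, mids)  # boundaries left of each bin mid
            logb = np.log1p(-np.array([betas[x] for x in bpos_arr]))
            cum = np.concatenate([[0.0], np.cumsum(logb)])
            prefix = cum[cross]
            # product of (1 - beta) over boundaries strictly between the mids
            atten = np.exp(-np.abs(prefix[:, None] - prefix[None, :]))
            block = np.where(s < BOUNDARY_RANGE_BP, block * atten, block)
        both_tel = tel[sl][:, None] & tel[sl][None, :]
        both_cen = cen[sl][:, None] & cen[sl][None, :]
        block = block * np.where(both_tel, p.w_tel, 1.0) * np.where(both_cen, p.w_cen, 1.0)
        W[sl, sl] = block

    cis_pairs = bt.chrom_code[:, None] == bt.chrom_code[None, :]

    # ---- trans (non-mito x non-mito)
    t_block = trans_aff[np.ix_(code, code)]
    both_tel = tel[:, None] & tel[None, :]
    both_cen = cen[:, None] & cen[None, :]
    t_block = t_block * np.where(both_tel, p.w_tel, 1.0) * np.where(both_cen, p.w_cen, 1.0)
    trans_sel = ~cis_pairs & ~mito[:, None] & ~mito[None, :]
    W[trans_sel] = t_block[trans_sel]

    # ---- mito-nuclear leak: lambda_mito x mean trans weight
    if mito.any():
        mean_trans = W[trans_sel].mean() if trans_sel.any() else 0.0
        mn_sel = (mito[:, None] ^ mito[None, :])
        W[mn_sel] = p.lambda_mito * mean_trans
        # mito self-pair carries no signal of interest
        mi = np.flatnonzero(mito)
        W[np.ix_(mi, mi)] = 0.0

    # ---- rescale: cis mass (non-mito) = f_cis; everything else = 1 - f_cis
    iu = np.triu_indices(n)
    cis_sel_u = cis_pairs[iu] & ~(mito[iu[0]] | mito[iu[1]])
    vals = W[iu]
    cis_mass = vals[cis_sel_u].sum()
    other_mass = vals[~cis_sel_u].sum()
    if cis_mass <= 0:
        raise ValueError("expected map has zero cis mass")
    scale_cis = p.f_cis / cis_mass
    scale_other = (1.0 - p.f_cis) / other_mass if other_mass > 0 else 0.0
    Wn = np.where(cis_pairs & ~(mito[:, None] | mito[None, :]), W * scale_cis, W * scale_other)
    return Wn


def sample_contact_map(bin_table: BinTable, expected: np.ndarray,
                       n_contacts: int, seed: int = 0) -> ContactMatrix:
    """Multinomial draw of ``n_contacts`` contacts over unordered bin pairs.

    The returned matrix has symmetric counts and ``total_contacts`` equal to
    ``n_contacts`` exactly.
    """
    if n_contacts < 1:
        raise ValueError("n_contacts must be >= 1")
    n = bin_table.n_bins
    if expected.shape != (n, n):
        raise ValueError("expected matrix shape mismatch")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n)
    pvals = expected[iu].astype(float)
    total = pvals.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"expected upper triangle sums to {total:.6f}, not 1")
    pvals = pvals / total
    draws = rng.multinomial(n_contacts, pvals)
    counts = np.zeros((n, n))
    counts[iu] = draws
    counts = counts + np.triu(counts, k=1).T
    return ContactMatrix(bin_table, counts)


PRESET_NAMES = ("PF", "IPSC", "MN_W0", "MN_W3", "MN_W6", "ALS_MN_W6")

# Maturation trajectory (see docs/methods.md): cis share rises 0.70 -> 0.85;
# compartment affinity dips at iPSC and peaks at MN_W6; long-range cis decay
# steepens (alpha2); telomere/centromere clustering switches on at MN_W0 and
# rises to MN_W6; planted boundaries strengthen with maturation. ALS_MN_W6
# sits between MN_W3 and MN_W6, close to W3 (arrested maturation), with a
# doubled mito-nuclear leak.
_PRESETS: dict[str, dict] = {
    "PF":        dict(f_cis=0.70, alpha1=0.95, alpha2=1.05, c_AA=2.2, c_BB=2.2,
                      t_AA=1.35, t_BB=1.35, w_tel=1.0, w_cen=1.0,
                      boundary_beta=0.45, lambda_mito=0.8),
    "IPSC":      dict(f_cis=0.70, alpha1=0.95, alpha2=1.25, c_AA=1.6, c_BB=1.6,
                      t_AA=1.15, t_BB=1.15, w_tel=1.0, w_cen=1.0,
                      boundary_beta=0.40, lambda_mito=0.8),
    "MN_W0":     dict(f_cis=0.72, alpha1=1.0, alpha2=1.5, c_AA=1.8, c_BB=1.7,
                      t_AA=1.20, t_BB=1.20, w_tel=1.5, w_cen=1.5,
                      boundary_beta=0.45, lambda_mito=0.8),
    "MN_W3":     dict(f_cis=0.78, alpha1=1.0, alpha2=1.7, c_AA=2.0, c_BB=1.9,
                      t_AA=1.30, t_BB=1.25, w_tel=2.0, w_cen=2.0,
                      boundary_beta=0.55, lambda_mito=0.8),
    "MN_W6":     dict(f_cis=0.85, alpha1=1.0, alpha2=1.9, c_AA=2.3, c_BB=2.1,
                      t_AA=1.45, t_BB=1.35, w_tel=3.0, w_cen=3.0,
                      boundary_beta=0.65, lambda_mito=0.8),
    "ALS_MN_W6": dict(f_cis=0.80, alpha1=1.0, alpha2=1.75, c_AA=2.1, c_BB=1.95,
                      t_AA=1.33, t_BB=1.28, w_tel=2.2, w_cen=2.2,
                      boundary_beta=0.58, lambda_mito=1.6),
}


def preset(name: str) -> SimParams:
    """Fixed parameter set emulating one cell state of the maturation course."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}")
    return SimParams(**_PRESETS[name])


def simulate_state(bin_table: BinTable, params: SimParams,
                   labels: CompartmentTrack, n_contacts: int | None = None,
                   seed: int | None = None) -> ContactMatrix:
    """Convenience: expected map under ``params`` + one multinomial sample."""
    E = expected_contact_map(bin_table, labels, params)
    return sample_contact_map(bin_table, E,
                              n_contacts or params.n_contacts,
                              params.seed if seed is None else seed)


def sample_expression_table(bin_table: BinTable, planted: PlantedTracks,
                            genes_per_bin: float = 0.5, seed: int = 0,
                            sample_names: tuple = ("PF", "IPSC", "MN")):
    """Synthetic per-gene TPM table coupled to the planted compartments.

    Genes are placed uniformly; in each state, genes in A bins draw from a
    high-expression log-normal and genes in B/ambiguous bins from a low one,
    emulating euchromatin being the transcribed compartment.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    bt = bin_table
    rows = []
    gid = 0
    for i in range(bt.n_bins):
        if bt.is_mito_bin[i]:
            continue
        for _ in range(rng.poisson(genes_per_bin)):
            start = int(rng.integers(bt.start[i], bt.end[i]))
            rows.append({"gene_id": f"gene{gid:05d}",
                         "chrom": bt.genome.chrom_names[bt.chrom_code[i]],
                         "start": start, "end": min(start + 1000, int(bt.end[i])),
                         "_bin": i})
            gid += 1
    df = pd.DataFrame(rows)
    for state, name in enumerate(sample_names):
        call = planted.tracks[state].call
        tpm = np.empty(len(df))
        for r, b in enumerate(df["_bin"]):
            if call[b] == "A":
                tpm[r] = rng.lognormal(mean=3.0, sigma=1.0)
            else:
                tpm[r] = rng.lognormal(mean=0.5, sigma=1.0)
        df[f"TPM_{name}"] = tpm
    return df.drop(columns="_bin")
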