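"""Genome and bin-table bookkeeping.

Coordinates are 0-based, half-open, in bp throughout. A genome is an ordered
set of chromosomes with lengths, optional centromere midpoints and at most one
mitochondrial contig. A :class:`BinTable` tiles each chromosome into fixed-size
bins (the last bin may be short) and annotates each bin with its arm and with
flags marking chromosome-end ("telomeric") and centromere-flanking regions —
the coordinate backbone for every downstream statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Genome",
    "BinTable",
    "build_bin_table",
    "read_chromsizes",
    "read_centromeres",
    "test_genome",
    "scaled_human_genome",
]


@dataclass(frozen=True)
class Genome:
    """Ordered chromosomes with lengths, centromere midpoints and a mito flag.

    Parameters
    ----------
    chrom_names
        Ordered chromosome identifiers.
    chrom_lengths
        Length in bp per chromosome, same order.
    centromere_mid
        Centromere midpoint in bp per chromosome; ``None`` where absent
        (acrocentric-style contigs, the mitochondrial contig).
    is_mito
        Flag per chromosome; at most one may be True.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    centromere_mid: tuple[int | None, ...] = field(default=None)
    is_mito: tuple[bool, ...] = field(default=None)

    def __post_init__(self):
        n = len(self.chrom_names)
        if len(set(self.chrom_names)) != n:
            raise ValueError("duplicate chromosome names")
        if len(self.chrom_lengths) != n:
            raise ValueError("chrom_lengths length mismatch")
        if self.centromere_mid is None:
            object.__setattr__(self, "centromere_mid", (None,) * n)
        if self.is_mito is None:
            object.__setattr__(self, "is_mito", (False,) * n)
        if len(self.centromere_mid) != n or len(self.is_mito) != n:
            raise ValueError("annotation length mismatch")
        for name, L, cen in zip(self.chrom_names, self.chrom_lengths, self.centromere_mid):
            if L <= 0:
                raise ValueError(f"chromosome {name}: length must be > 0")
            if cen is not None and not (0 < cen < L):
                raise ValueError(f"chromosome {name}: centromere_mid outside (0, length)")
        if sum(self.is_mito) > 1:
            raise ValueError("at most one mitochondrial contig allowed")

    @property
    def n_chroms(self) -> int:
        return len(self.chrom_names)

    @property
    def mito_name(self) -> str | None:
        for name, m in zip(self.chrom_names, self.is_mito):
            if m:
                return name
        return None

    def length_of(self, chrom: str) -> int:
        return self.chrom_lengths[self.chrom_names.index(chrom)]


class BinTable:
    """Fixed-size tiling of a genome with arm and end-region annotations.

    Wraps a :class:`pandas.DataFrame` with columns ``chrom, start, end, arm,
    in_telomere_end, in_centromere_flank`` plus integer chromosome codes for
    fast vectorized work.
    """

    def __init__(self, genome: Genome, bin_size: int, df: pd.DataFrame):
        self.genome = genome
        self.bin_size = int(bin_size)
        self.df = df
        self.chrom_code = df["chrom_code"].to_numpy()
        self.start = df["start"].to_numpy()
        self.end = df["end"].to_numpy()
        self.mid = (self.start + self.end) / 2.0
        self.in_telomere_end = df["in_telomere_end"].to_numpy()
        self.in_centromere_flank = df["in_centromere_flank"].to_numpy()
        self.is_mito_bin = np.asarray(
            [genome.is_mito[c] for c in self.chrom_code], dtype=bool
        )
        # per-chromosome half-open bin-index ranges, in genome order
        self.chrom_offsets = np.searchsorted(
            self.chrom_code, np.arange(genome.n_chroms + 1)
        )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_bins(self) -> int:
        return len(self.df)

    def chrom_slice(self, chrom: str | int) -> slice:
        """Bin-index slice covering one chromosome."""
        code = chrom if isinstance(chrom, int) else self.genome.chrom_names.index(chrom)
        return slice(self.chrom_offsets[code], self.chrom_offsets[code + 1])

    def bin_id(self, chrom: str, pos: int) -> int:
        """Genome-wide bin index containing position ``pos`` on ``chrom``."""
        code = self.genome.chrom_names.index(chrom)
        L = self.genome.chrom_lengths[code]
        if not (0 <= pos < L):
            raise ValueError(f"position {pos} outside {chrom} (length {L})")
        return int(self.chrom_offsets[code] + pos // self.bin_size)

    def same_table(self, other: "BinTable") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.genome.chrom_names == other.genome.chrom_names
            and self.genome.chrom_lengths == other.genome.chrom_lengths
        )


def build_bin_table(genome: Genome, bin_size: int, end_size: int | None = None) -> BinTable:
    """Tile ``genome`` into ``bin_size`` bins and annotate arms and end regions.

    ``end_size`` (default ``bin_size``) controls both the telomere-end flag
    (bins within ``end_size`` of a chromosome terminus) and the centromere
    flank flag (bin midpoint within ``end_size`` of ``centromere_mid``).
    Non-mito chromosomes shorter than ``2 * end_size`` are rejected: their two
    end regions would overlap and every end statistic would be degenerate.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    end_size = bin_size if end_size is None else int(end_size)
    if end_size < bin_size:
        raise ValueError("end_size must be >= bin_size")

    rows = []
    for code, (name, L, cen, mito) in enumerate(
        zip(genome.chrom_names, genome.chrom_lengths, genome.centromere_mid, genome.is_mito)
    ):
        if not mito and L < 2 * end_size:
            raise ValueError(
                f"chromosome {name} (length {L}) shorter than 2*end_size={2 * end_size}; "
                "telomere-end flags would overlap"
            )
        starts = np.arange(0, L, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, L)
        mids = (starts + ends) / 2.0
        if cen is None:
            arm = np.full(len(starts), "q", dtype=object)
            cen_flank = np.zeros(len(starts), dtype=bool)
        else:
            # bins spanning the centromere assigned by midpoint
            arm = np.where(mids <= cen, "p", "q").astype(object)
            cen_flank = np.abs(mids - cen) <= end_size
        tel = (starts < end_size) | (ends > L - end_size)
        if mito:
            tel[:] = False
        for i in range(len(starts)):
            rows.append(
                (name, code, int(starts[i]), int(ends[i]), arm[i], bool(tel[i]), bool(cen_flank[i]))
            )
    df = pd.DataFrame(
        rows,
        columns=["chrom", "chrom_code", "start", "end", "arm", "in_telomere_end", "in_centromere_flank"],
    )
    bt = BinTable(genome, bin_size, df)
    bt.end_size = end_size
    return bt


def read_chromsizes(path) -> pd.Series:
    """Read a UCSC two-column chromsizes TSV into a name → length Series."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], comment="#")
    return df.set_index("chrom")["length"]


def read_centromeres(path) -> pd.Series:
    """Read a three-column (chrom, mid_bp, label) TSV into a name → mid Series."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "mid", "label"], comment="#")
    return df.set_index("chrom")["mid"]


def test_genome(with_mito: bool = True) -> Genome:
    """Desk-scale genome: 8 chromosomes of 30–60 Mb plus a 16.6 kb mito contig.

    Small enough that a full simulate → balance → estimate cycle at 250 kb
    resolution runs in seconds, yet large enough for compartment, insulation
    and territory statistics to be well-posed.
    """
    Mb = 1_000_000
    names = ["chr1", "chr2", "chr3", "chr4", "chr5", "chr6", "chr7", "chr8"]
    lengths = [60 * Mb, 55 * Mb, 50 * Mb, 45 * Mb, 42 * Mb, 38 * Mb, 34 * Mb, 30 * Mb]
    cens = [24 * Mb, 22 * Mb, 20 * Mb, 18 * Mb, 21 * Mb, 15 * Mb, 13 * Mb, 12 * Mb]
    mito = [False] * 8
    if with_mito:
        names = names + ["chrM"]
        lengths = lengths + [16_600]
        cens = cens + [None]
        mito = mito + [True]
    return Genome(tuple(names), tuple(lengths), tuple(cens), tuple(mito))


# hg38 autosome lengths and approximate centromere midpoints, Mb
_HG38_LEN_MB = [
    248.96, 242.19, 198.30, 190.21, 181.54, 170.81, 159.35, 145.14, 138.39,
    133.80, 135.09, 133.28, 114.36, 107.04, 101.99, 90.34, 83.26, 80.37,
    58.62, 64.44, 46.71, 50.82,
]
_HG38_CEN_MB = [
    123.4, 93.9, 90.9, 50.0, 48.8, 59.8, 60.1, 45.2, 43.0, 39.8, 53.4, 35.5,
    17.7, 17.2, 19.0, 36.8, 25.1, 18.5, 26.2, 28.1, 12.0, 15.0,
]


def scaled_human_genome(scale: float = 0.2, with_mito: bool = True) -> Genome:
    """22 autosomes with human-proportioned lengths/centromeres, scaled down.

    At ``scale=0.2`` the genome totals ~575 Mb, giving >5,000 bins at 100 kb —
    enough for the genome-fraction statistics (compartment switch taxonomy)
    while keeping dense matrices in memory.
    """
    names = [f"chr{i}" for i in range(1, 23)]
    lengths = [int(L * 1e6 * scale) for L in _HG38_LEN_MB]
    cens = [int(c * 1e6 * scale) for c in _HG38_CEN_MB]
    mito: list[bool] = [False] * 22
    cen_out: list[int | None] = list(cens)
    if with_mito:
        names.append("chrM")
        lengths.append(16_600)
        cen_out.append(None)
        mito.append(True)
    return Genome(tuple(names), tuple(lengths), tuple(cen_out), tuple(mito))
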