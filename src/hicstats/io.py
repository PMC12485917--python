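"""Reading and writing contact maps and genomic tracks.

Three contact formats are supported:

* ``pairs`` — 4DN-style text: ``readID chrom1 pos1 chrom2 pos2 strand1
  strand2``, ``#`` header lines; positions are aggregated into the bins of a
  supplied :class:`~hicstats.genome.BinTable`.
* ``triplet_tsv`` — ``bin1_id  bin2_id  count`` with ``bin1_id <= bin2_id``
  (upper triangle only).
* ``cool`` — an HDF5 layout mirroring the cooler schema (``chroms/``,
  ``bins/`` with chrom/start/end/weight, ``pixels/`` with
  bin1_id/bin2_id/count), written and read with h5py.

Round trips reproduce counts exactly. Per-bin scalar tracks go to bedGraph,
intervals (boundaries, switch categories) to BED.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import h5py

from .contacts import ContactMatrix
from .genome import BinTable, Genome

__all__ = ["read_contacts", "write_contacts", "write_bedgraph", "write_bed",
           "write_boundaries_bed"]


def read_contacts(path, fmt: str, bin_table: BinTable | None = None) -> ContactMatrix:
    """Read a contact matrix; ``pairs`` and ``triplet_tsv`` need a BinTable."""
    if fmt == "pairs":
        return _read_pairs(path, bin_table)
    if fmt == "triplet_tsv":
        return _read_triplet(path, bin_table)
    if fmt == "cool":
        return _read_cool(path, bin_table)
    raise ValueError(f"unknown format {fmt!r}; use pairs, triplet_tsv or cool")


def write_contacts(matrix: ContactMatrix, path, fmt: str) -> None:
    if fmt == "triplet_tsv":
        _write_triplet(matrix, path)
    elif fmt == "cool":
        _write_cool(matrix, path)
    else:
        raise ValueError(f"unsupported output format {fmt!r}; use triplet_tsv or cool")


def _read_pairs(path, bt: BinTable) -> ContactMatrix:
    if bt is None:
        raise ValueError("pairs format requires a bin_table")
    n = bt.n_bins
    counts = np.zeros((n, n))
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            if len(f) < 5:
                raise ValueError(f"{path}:{lineno}: malformed pairs record: {line!r}")
            _, c1, p1, c2, p2 = f[:5]
            try:
                b1 = bt.bin_id(c1, int(p1))
                b2 = bt.bin_id(c2, int(p2))
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: {e}") from None
            counts[b1, b2] += 1
            if b1 != b2:
                counts[b2, b1] += 1
    return ContactMatrix(bt, counts)


def _read_triplet(path, bt: BinTable) -> ContactMatrix:
    if bt is None:
        raise ValueError("triplet_tsv format requires a bin_table")
    df = pd.read_csv(path, sep="\t", header=None, names=["bin1", "bin2", "count"],
                     comment="#")
    n = bt.n_bins
    b1 = df["bin1"].to_numpy(int)
    b2 = df["bin2"].to_numpy(int)
    if (b1 < 0).any() or (b2 >= n).any() or (b1 > b2).any():
        bad = df[(b1 < 0) | (b2 >= n) | (b1 > b2)].iloc[0]
        raise ValueError(f"triplet record out of range or lower-triangle: {tuple(bad)}")
    key = b1 * n + b2
    if len(np.unique(key)) != len(key):
        dup = df[pd.Series(key).duplicated(keep=False)].iloc[0]
        raise ValueError(f"duplicate mirrored entry for bin pair ({dup['bin1']}, {dup['bin2']})")
    counts = np.zeros((n, n))
    counts[b1, b2] = df["count"].to_numpy(float)
    counts = np.triu(counts) + np.triu(counts, k=1).T
    return ContactMatrix(bt, counts)


def _write_triplet(matrix: ContactMatrix, path) -> None:
    iu = np.triu_indices(matrix.n_bins)
    vals = matrix.counts[iu]
    nz = vals != 0
    df = pd.DataFrame({"bin1": iu[0][nz], "bin2": iu[1][nz], "count": vals[nz]})
    # store integer counts as integers so round trips are bit-exact
    if np.all(df["count"] == np.floor(df["count"])):
        df["count"] = df["count"].astype(np.int64)
    df.to_csv(path, sep="\t", header=False, index=False)


def _write_cool(matrix: ContactMatrix, path) -> None:
    bt = matrix.bin_table
    g = bt.genome
    iu = np.triu_indices(matrix.n_bins)
    vals = matrix.counts[iu]
    nz = vals != 0
    with h5py.File(path, "w") as fh:
        fh.attrs["bin-size"] = bt.bin_size
        fh.attrs["format"] = "HDF5::Cooler-like"
        chroms = fh.create_group("chroms")
        chroms.create_dataset("name", data=np.array(g.chrom_names, dtype="S"))
        chroms.create_dataset("length", data=np.array(g.chrom_lengths, dtype=np.int64))
        bins = fh.create_group("bins")
        bins.create_dataset("chrom", data=bt.chrom_code.astype(np.int32))
        bins.create_dataset("start", data=bt.start.astype(np.int64))
        bins.create_dataset("end", data=bt.end.astype(np.int64))
        bins.create_dataset("weight", data=matrix.weights)
        pixels = fh.create_group("pixels")
        pixels.create_dataset("bin1_id", data=iu[0][nz].astype(np.int64))
        pixels.create_dataset("bin2_id", data=iu[1][nz].astype(np.int64))
        pixels.create_dataset("count", data=vals[nz])


def _read_cool(path, bin_table: BinTable | None = None) -> ContactMatrix:
    with h5py.File(path, "r") as fh:
        names = tuple(n.decode() for n in fh["chroms/name"][:])
        lengths = tuple(int(x) for x in fh["chroms/length"][:])
        bin_size = int(fh.attrs["bin-size"])
        starts = fh["bins/start"][:]
        ends = fh["bins/end"][:]
        codes = fh["bins/chrom"][:]
        if bin_table is not None:
            # adopt the caller's (annotated) table after checking it matches
            bt = bin_table
            if (bt.genome.chrom_names != names or len(bt.start) != len(starts)
                    or not np.array_equal(bt.start, starts)):
                raise ValueError("supplied bin_table does not match the stored bins")
        else:
            mito = tuple(n in ("chrM", "MT", "chrMT") for n in names)
            genome = Genome(names, lengths, (None,) * len(names), mito)
            bt = BinTable.__new__(BinTable)
            # rebuild the bin table from the stored bins to preserve tiling
            df = pd.DataFrame({
                "chrom": [names[c] for c in codes], "chrom_code": codes.astype(int),
                "start": starts.astype(int), "end": ends.astype(int),
                "arm": "q", "in_telomere_end": False, "in_centromere_flank": False,
            })
            BinTable.__init__(bt, genome, bin_size, df)
        n = len(starts)
        counts = np.zeros((n, n))
        b1 = fh["pixels/bin1_id"][:]
        b2 = fh["pixels/bin2_id"][:]
        counts[b1, b2] = fh["pixels/count"][:]
        counts = np.triu(counts) + np.triu(counts, k=1).T
        weights = fh["bins/weight"][:]
    if np.isnan(weights).all():
        mask = np.ones(n, bool)   # never balanced: all bins usable
    else:
        mask = np.isfinite(weights)
    return ContactMatrix(bt, counts, weights=weights, mask=mask)


def write_bedgraph(bin_table: BinTable, values: np.ndarray, path,
                   track_name: str = "track") -> None:
    """Write a per-bin scalar as bedGraph, skipping undefined (NaN) bins."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track_name}"\n')
        for i, v in enumerate(values):
            if np.isfinite(v):
                fh.write(f"{bin_table.genome.chrom_names[bin_table.chrom_code[i]]}\t"
                         f"{bin_table.start[i]}\t{bin_table.end[i]}\t{v:.6g}\n")


def write_bed(intervals, path) -> None:
    """Write (chrom, start, end, name[, score]) tuples as BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def write_boundaries_bed(boundaries, bin_size: int, path) -> None:
    """Boundary calls as BED; score = strength x 1000, clamped to 1000."""
    rows = []
    for b in boundaries:
        score = min(1000, int(round(b.strength * 1000)))
        name = "strong" if b.is_strong else "weak"
        rows.append((b.chrom, b.start, b.start + bin_size, name, score))
    write_bed(rows, path)
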