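"""Orchestration: simulate -> analyze -> compare across sample sets.

`run_pipeline` takes a :class:`RunConfig` (usually from YAML), produces the
full per-sample statistics bundle (balanced matrix, EV1 track, saddle
strengths, P(s), cis %, insulation + boundaries, telomere/centromere
aggregates, telomere pair matrix, mito score) and cross-sample summaries
(switch table when three states are given, boundary-set comparison), and
writes a deterministic JSON summary plus bedGraph/BED/TSV tracks.

`compare_groups` contrasts two groups of per-sample statistics with an exact
label-permutation test (appropriate at the n<=4 clone counts typical of these
designs) plus a Welch t-test as a secondary, comparability-oriented output.
"""

from __future__ import annotations

import itertools
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import io as hio
from .compartments import classify_switches, compute_ev1, saddle_strength
from .contacts import (cis_fraction, fit_ps_slope, ic_balance,
                       long_range_fraction, mask_low_coverage, ps_curve)
from .genome import build_bin_table, scaled_human_genome, test_genome
from .insulation import (aggregate_insulation, call_boundaries,
                         compare_boundary_sets, insulation_track)
from .simulate import (PRESET_NAMES, default_switch_probs, preset,
                       sample_switch_tracks, simulate_state)
from .territories import (mito_nuclear_score, telcen_aggregate,
                          telomere_pair_matrix)

logger = logging.getLogger("hicstats")

__all__ = ["RunConfig", "run_pipeline", "compare_groups", "analyze_sample"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    samples: list = field(default_factory=list)  # dicts: name + preset | path/format
    genome: str = "test"             # test | scaled_human | chromsizes TSV path
    bin_size: int = 250_000
    end_size: int = 1_000_000
    window: int = 750_000
    flank: int = 750_000
    strong_threshold: float = 0.1
    mad_k: float = 5.0
    n_contacts: int = 2_000_000
    seed: int = 0
    outdir: str = "hicstats_out"

    def validate(self) -> None:
        names = [s["name"] for s in self.samples]
        if len(set(names)) != len(names):
            raise ValueError("sample names must be unique")
        if not self.samples:
            raise ValueError("config lists no samples")
        for s in self.samples:
            if "preset" in s:
                if s["preset"] not in PRESET_NAMES:
                    raise ValueError(f"sample {s['name']}: unknown preset {s['preset']!r}")
            elif "path" in s:
                if not os.path.exists(s["path"]):
                    raise ValueError(f"sample {s['name']}: file not found: {s['path']}")
            else:
                raise ValueError(f"sample {s['name']}: needs 'preset' or 'path'")
        if self.genome not in ("test", "scaled_human") and not os.path.exists(self.genome):
            raise ValueError(f"genome {self.genome!r} is neither a known name nor a file")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            cfg = cls(**yaml.safe_load(fh))
        cfg.validate()
        return cfg


def _build_genome(name: str):
    if name == "test":
        return test_genome()
    if name == "scaled_human":
        return scaled_human_genome()
    raise ValueError("file-based genomes need centromeres; pass a prepared Genome "
                     "through the library API instead")


def analyze_sample(matrix, reference_track, *, window: int, flank: int,
                   strong_threshold: float = 0.1, mad_k: float = 5.0,
                   end_size: int = 1_000_000) -> dict:
    """All per-sample statistics on one raw contact matrix.

    Returns a dict with scalar statistics under "stats" and the intermediate
    objects (balanced matrix, tracks, boundaries) for further use.
    """
    m = mask_low_coverage(matrix, mad_k)
    m = ic_balance(m)
    stats: dict[str, float] = {}
    stats["cis_percent"] = cis_fraction(m)
    stats["long_range_fraction"] = long_range_fraction(m)
    curve = ps_curve(m)
    stats["ps_slope_0.1_10Mb"] = fit_ps_slope(curve)
    ev = compute_ev1(m, reference_track)
    for scope in ("cis", "trans"):
        sad = saddle_strength(m, ev, scope=scope)
        stats[f"strength_AA_{scope}"] = sad.strength_AA
        stats[f"strength_BB_{scope}"] = sad.strength_BB
    ins = insulation_track(m, window)
    bnd = call_boundaries(ins, strong_threshold)
    strong = [b for b in bnd if b.is_strong]
    stats["n_boundaries"] = float(len(bnd))
    stats["n_strong_boundaries"] = float(len(strong))
    stats["mean_boundary_strength"] = float(np.mean([b.strength for b in bnd])) if bnd else 0.0
    tc = telcen_aggregate(m)
    stats["tel_tel"] = tc["tel_tel"]
    stats["cen_cen"] = tc["cen_cen"]
    stats["tel_cen"] = tc["tel_cen"]
    tpm = telomere_pair_matrix(m, end_size=end_size)
    stats["telomere_pair_mean"] = tpm.mean_defined
    if matrix.bin_table.is_mito_bin.any():
        stats["mito_nuclear_score"] = mito_nuclear_score(m)
    return {"stats": stats, "matrix": m, "ev": ev, "ps": curve,
            "insulation": ins, "boundaries": bnd, "telomere_pairs": tpm}


_STATE_INDEX = {"PF": 0, "IPSC": 1}   # any MN/ALS preset uses the third state


def run_pipeline(config: RunConfig) -> dict:
    """Run the full simulate/load -> analyze -> compare pipeline."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    genome = _build_genome(config.genome)
    bt = build_bin_table(genome, config.bin_size, config.end_size)
    planted = sample_switch_tracks(bt, default_switch_probs(), seed=config.seed)

    results: dict[str, dict] = {}
    summary: dict = {"samples": {}}
    failures = []
    for k, s in enumerate(config.samples):
        name = s["name"]
        try:
            if "preset" in s:
                params = preset(s["preset"])
                state = _STATE_INDEX.get(s["preset"], 2)
                labels = planted.tracks[state]
                mat = simulate_state(bt, params, labels,
                                     n_contacts=s.get("n_contacts", config.n_contacts),
                                     seed=config.seed + 1000 + k)
                ref = labels.ev1
            else:
                mat = hio.read_contacts(s["path"], s.get("format", "cool"), bt)
                ref = np.ones(bt.n_bins)
            res = analyze_sample(mat, ref, window=config.window, flank=config.flank,
                                 strong_threshold=config.strong_threshold,
                                 mad_k=config.mad_k, end_size=config.end_size)
            results[name] = res
            summary["samples"][name] = {k2: round(float(v), 6)
                                        for k2, v in res["stats"].items()}
            hio.write_bedgraph(bt, res["ev"].ev1,
                               os.path.join(config.outdir, f"{name}.ev1.bedgraph"), "EV1")
            hio.write_bedgraph(bt, res["insulation"].score,
                               os.path.join(config.outdir, f"{name}.insulation.bedgraph"),
                               "insulation")
            hio.write_boundaries_bed(res["boundaries"], bt.bin_size,
                                     os.path.join(config.outdir, f"{name}.boundaries.bed"))
            curve = res["ps"]
            pd.DataFrame({"s_bp": curve.distance_centers,
                          "mean_contact": curve.mean_contact,
                          "derivative": curve.derivative}).to_csv(
                os.path.join(config.outdir, f"{name}.ps.tsv"), sep="\t", index=False)
        except Exception as e:   # partial outputs retained, failure logged
            logger.error("sample %s failed: %s", name, e)
            failures.append(name)
    if failures:
        summary["failed_samples"] = failures

    names = list(results)
    if len(names) == 3:
        try:
            table = classify_switches([results[n]["ev"] for n in names])
            summary["switch_fractions"] = {c: round(float(f), 6)
                                           for c, f in table.fractions.items()}
        except Exception as e:
            logger.error("switch classification failed: %s", e)
    if len(names) >= 2:
        a, b = names[0], names[-1]
        parts = compare_boundary_sets(results[a]["boundaries"], results[b]["boundaries"])
        summary["boundary_comparison"] = {
            "a": a, "b": b,
            "a_specific": len(parts["a_specific"]),
            "common": len(parts["common"]),
            "b_specific": len(parts["b_specific"]),
        }
    with open(os.path.join(config.outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=1)
    if failures:
        raise RuntimeError(f"pipeline finished with failed samples: {failures}")
    summary["_results"] = results
    return summary


def _exact_permutation_p(x: np.ndarray, y: np.ndarray, max_exact: int = 20000,
                         seed: int = 0) -> float:
    """Two-sided permutation p-value for a difference in group means.

    Exact enumeration over label assignments when feasible, else Monte Carlo.
    """
    pooled = np.concatenate([x, y])
    nx = len(x)
    obs = abs(x.mean() - y.mean())
    idx = np.arange(len(pooled))
    combos = None
    from math import comb
    if comb(len(pooled), nx) <= max_exact:
        combos = itertools.combinations(idx, nx)
        count = total = 0
        for c in combos:
            sel = np.zeros(len(pooled), bool)
            sel[list(c)] = True
            d = abs(pooled[sel].mean() - pooled[~sel].mean())
            count += d >= obs - 1e-12
            total += 1
        return count / total
    rng = np.random.default_rng(seed)
    count = 0
    B = max_exact
    for _ in range(B):
        rng.shuffle(idx)
        d = abs(pooled[idx[:nx]].mean() - pooled[idx[nx:]].mean())
        count += d >= obs - 1e-12
    return (count + 1) / (B + 1)


def compare_groups(control: list[dict], case: list[dict], seed: int = 0) -> pd.DataFrame:
    """Contrast two groups of per-sample statistic dicts.

    Each element is a ``{"stats": {...}}`` bundle (or a bare stats dict).
    Reports group means, the case-minus-control difference, the per-group
    standard deviations (clone-level variability), an exact permutation
    p-value and a Welch t-test p-value per statistic.
    """
    if not control or not case:
        raise ValueError("each group needs at least one sample")

    def _stats(r):
        return r["stats"] if "stats" in r else r

    keys = sorted(set.intersection(*[set(_stats(r)) for r in control + case]))
    rows = []
    for k in keys:
        x = np.array([_stats(r)[k] for r in control], float)
        y = np.array([_stats(r)[k] for r in case], float)
        if len(x) > 1 and len(y) > 1 and (np.std(x) > 0 or np.std(y) > 0):
            welch = float(sps.ttest_ind(y, x, equal_var=False).pvalue)
            perm = float(_exact_permutation_p(x, y, seed=seed))
        else:
            welch, perm = float("nan"), float("nan")
        rows.append({"statistic": k,
                     "mean_control": x.mean(), "mean_case": y.mean(),
                     "difference": y.mean() - x.mean(),
                     "sd_control": x.std(ddof=1) if len(x) > 1 else 0.0,
                     "sd_case": y.std(ddof=1) if len(y) > 1 else 0.0,
                     "p_permutation": perm, "p_welch": welch})
    return pd.DataFrame(rows)
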