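"""Deterministic on-disk fixtures: copying-model panels and two-locus panels.

Fixtures stand in for downloaded datasets in tests and examples: every file
is reproducible bit-for-bit from the spec's seed, and a sidecar ``truth.json``
records the generating parameters (versioned schema).  The copying-fixture
site-frequency model is a pragmatic neutral-like stand-in (1/x-weighted
frequencies, panel-MAF filtered); statistics needing genuine coalescent
structure should simulate through :mod:`stratld.ancestral` instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import ancestral, copying
from .haplotypes import HaplotypeMatrix
from .io import write_haplotypes_vcf, write_sample_times
from .theory import TwoLocusParams

__all__ = ["FixtureSpec", "make_copying_fixture", "make_twolocus_fixture", "random_panel"]

TRUTH_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class FixtureSpec:
    """A named, seeded fixture scenario; all parameters echoed into truth.json."""

    name: str
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed is mandatory and must be an integer")


def random_panel(k: int, s: int, total_morgans: float, rng, maf_min: float = 0.05,
                 chrom_bp: int = 40_000_000):
    """Random reference panel with neutral-like site frequencies.

    Site frequencies are drawn with density proportional to 1/x on
    (1/(2k), 1-1/(2k)) and columns are kept only if the realised panel minor
    allele frequency is strictly above ``maf_min`` (mirroring common-variant
    ascertainment).  Positions are uniform over ``chrom_bp`` with a uniform
    1 cM/Mb map scaled to ``total_morgans``.

    Returns ``(panel, positions_bp, map_pos)``.
    """
    if k < 1 or s < 1:
        raise ValueError("need k >= 1 and s >= 1")
    cols = []
    p_min = 1.0 / (2 * max(k, 2))
    tries = 0
    while len(cols) < s:
        tries += 1
        if tries > 1000 * s:
            raise ValueError("panel MAF filter left the fixture infeasible")
        p = p_min * ((1.0 - p_min) / p_min) ** rng.random()  # density 1/x on (p_min, 1-p_min)
        col = (rng.random(k) < p).astype(np.int8)
        maf = min(col.mean(), 1.0 - col.mean())
        if maf > maf_min:
            cols.append(col)
    panel = np.column_stack(cols)
    pos = np.sort(rng.choice(chrom_bp, size=s, replace=False)) + 1
    map_pos = pos / chrom_bp * total_morgans
    return panel, pos.astype(np.int64), map_pos


def make_copying_fixture(spec: FixtureSpec, outdir) -> dict:
    """Write panel VCF + query VCF + genetic map + truth JSON for the copying HMM.

    Parameters in ``spec.params`` (with defaults): ``K`` 100, ``S`` 2000,
    ``lam`` 100.0 per Morgan, ``eps`` 0.01, ``total_morgans`` 0.4,
    ``maf_min`` 0.05.  Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = dict(K=100, S=2000, lam=100.0, eps=0.01, total_morgans=0.4, maf_min=0.05)
    p.update(spec.params)
    rng = np.random.default_rng(spec.seed)
    panel, pos, map_pos = random_panel(
        p["K"], p["S"], p["total_morgans"], rng, maf_min=p["maf_min"]
    )
    params = copying.CopyingParams(p["lam"], p["eps"])
    query, path = copying.sample_generative(panel, map_pos, params, rng)

    chrom = np.array(["1"] * p["S"], dtype=object)
    panel_m = HaplotypeMatrix(
        genotypes=panel, positions_bp=pos, map_pos=map_pos, chrom=chrom,
        row_names=[f"panel{i}" for i in range(p["K"])],
    )
    query_m = HaplotypeMatrix(
        genotypes=query[None, :], positions_bp=pos, map_pos=map_pos, chrom=chrom,
        row_names=["query"],
    )
    paths = {
        "panel_vcf": outdir / f"{spec.name}.panel.vcf",
        "query_vcf": outdir / f"{spec.name}.query.vcf",
        "map": outdir / f"{spec.name}.map.txt",
        "truth": outdir / f"{spec.name}.truth.json",
    }
    write_haplotypes_vcf(panel_m, paths["panel_vcf"])
    write_haplotypes_vcf(query_m, paths["query_vcf"])
    _write_uniform_map(paths["map"], pos, map_pos)
    truth = {
        "schema_version": TRUTH_SCHEMA_VERSION,
        "kind": "copying",
        "name": spec.name,
        "seed": int(spec.seed),
        "lam": float(p["lam"]),
        "eps": float(p["eps"]),
        "K": int(p["K"]),
        "S": int(p["S"]),
        "total_morgans": float(p["total_morgans"]),
        "maf_min": float(p["maf_min"]),
        "hidden_path": [int(x) for x in path],
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return {k: str(v) for k, v in paths.items()}


def _write_uniform_map(path, pos, map_pos):
    with open(path, "w") as fh:
        fh.write("chr\tposition\trate_cM_Mb\tmap_cM\n")
        for bp, m in zip(pos, map_pos):
            rate = 100.0 * map_pos[-1] / pos[-1] * 1e6  # uniform cM/Mb
            fh.write(f"1\t{int(bp)}\t{rate:.6f}\t{100.0 * m:.8f}\n")


def make_twolocus_fixture(spec: FixtureSpec, outdir) -> dict:
    """Write a serial-sampling two-locus panel fixture (VCF + ages TSV + truth).

    Parameters in ``spec.params`` (defaults): ``rho`` 1.0, ``theta`` 0.4,
    ``t_a`` 0.0 (coalescent units), ``n_modern`` 2, ``n_ancient`` 0,
    ``n_reps`` 1, ``ne_ref`` 1e4, ``locus_bp`` 10000.  Replicates are emitted
    on contig pairs ``rep{i}_locusA`` / ``rep{i}_locusB``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = dict(rho=1.0, theta=0.4, t_a=0.0, n_modern=2, n_ancient=0, n_reps=1,
             ne_ref=1e4, locus_bp=10_000)
    p.update(spec.params)
    rng = np.random.default_rng(spec.seed)
    params = TwoLocusParams(rho=p["rho"], theta=p["theta"], t_a=p["t_a"])
    config = ancestral.HaplotypeSampleConfig(
        n_modern=p["n_modern"], n_ancient=p["n_ancient"], t_a=p["t_a"]
    )
    genos, pos, chroms, maps = [], [], [], []
    reps_truth = []
    haps = None
    for i in range(int(p["n_reps"])):
        panel = ancestral.simulate_panel(
            params, config, rng, locus_bp=int(p["locus_bp"]), ne_ref=p["ne_ref"]
        )
        haps = panel.haps
        genos.append(haps.genotypes)
        pos.append(haps.positions_bp)
        # large per-replicate map offset keeps the global map non-decreasing and
        # pushes cross-replicate site pairs far outside any LD bin range
        maps.append(haps.map_pos + 10.0 * i)
        chroms.append(np.array([f"rep{i}_{c}" for c in haps.chrom], dtype=object))
        reps_truth.append(
            {
                "t_mrca_a": panel.t_mrca_a,
                "t_mrca_b": panel.t_mrca_b,
                "L_a": panel.L_a,
                "L_b": panel.L_b,
                "n_sites": int(haps.n_sites),
            }
        )
    combined = HaplotypeMatrix(
        genotypes=np.hstack(genos),
        positions_bp=np.concatenate(pos),
        map_pos=np.concatenate(maps),
        sample_times=haps.sample_times,
        chrom=np.concatenate(chroms),
        row_names=list(haps.row_names),
    )
    paths = {
        "vcf": outdir / f"{spec.name}.vcf",
        "times": outdir / f"{spec.name}.times.tsv",
        "map": outdir / f"{spec.name}.map.txt",
        "truth": outdir / f"{spec.name}.truth.json",
    }
    write_haplotypes_vcf(combined, paths["vcf"])
    write_sample_times(combined, paths["times"])
    # two non-recombining loci: flat map within each locus contig, the
    # inter-locus distance rho/(4*ne_ref) carried on the locusB contig, and a
    # large per-replicate offset; values are globally cumulative (read back
    # with attach_map(..., cumulative=True))
    sep_cm = 100.0 * p["rho"] / (4.0 * p["ne_ref"])
    with open(paths["map"], "w") as fh:
        fh.write("chr\tposition\trate_cM_Mb\tmap_cM\n")
        for i in range(int(p["n_reps"])):
            for locus, cm in (("locusA", 1000.0 * i), ("locusB", 1000.0 * i + sep_cm)):
                for bp in (1, int(p["locus_bp"])):
                    fh.write(f"rep{i}_{locus}\t{bp}\t0.0\t{cm:.8f}\n")
    truth = {
        "schema_version": TRUTH_SCHEMA_VERSION,
        "kind": "twolocus",
        "name": spec.name,
        "seed": int(spec.seed),
        "rho": float(p["rho"]),
        "theta": float(p["theta"]),
        "t_a": float(p["t_a"]),
        "n_modern": int(p["n_modern"]),
        "n_ancient": int(p["n_ancient"]),
        "ne_ref": float(p["ne_ref"]),
        "replicates": reps_truth,
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    return {k: str(v) for k, v in paths.items()}
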