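"""Format I/O: VCF haplotype panels, HapMap-style genetic maps, sidecar tables.

Coordinate conventions: VCF is 1-based inclusive (standard); all internal
window arithmetic is 0-based half-open.  Genetic maps are the 4-column
HapMap text dialect (chromosome, position bp, rate cM/Mb, cumulative map cM)
with linear interpolation of the cumulative map on basepairs and constant
extrapolation beyond the mapped range; map values are exposed in Morgans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .haplotypes import MISSING, HaplotypeMatrix

__all__ = [
    "GeneticMap",
    "read_genetic_map",
    "read_genetic_maps",
    "attach_map",
    "interpolate_map",
    "read_haplotypes_vcf",
    "write_haplotypes_vcf",
    "read_sample_times",
    "write_sample_times",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneticMap:
    """Cumulative genetic map for one chromosome (positions bp, map in cM)."""

    chrom: str
    positions_bp: np.ndarray
    cm: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "positions_bp", np.asarray(self.positions_bp, dtype=np.int64))
        object.__setattr__(self, "cm", np.asarray(self.cm, dtype=float))
        if self.positions_bp.size != self.cm.size or self.positions_bp.size == 0:
            raise ValueError("map needs matching, non-empty position and cM arrays")
        if np.any(np.diff(self.positions_bp) <= 0):
            raise ValueError("map positions must be strictly increasing")
        if np.any(np.diff(self.cm) < 0):
            raise ValueError("cumulative map must be non-decreasing")

    def interpolate(self, bp) -> np.ndarray:
        """Genetic position in Morgans at basepair coordinates (clamped at the ends)."""
        return np.interp(np.asarray(bp, dtype=float), self.positions_bp, self.cm) / 100.0


def read_genetic_maps(path) -> dict:
    """Read a HapMap-format genetic map into per-chromosome cumulative maps.

    Header plus 4 whitespace-separated columns (chrom, position bp, rate
    cM/Mb, cumulative map cM); the cumulative map restarts per chromosome.
    """
    df = pd.read_csv(path, sep=r"\s+", header=0)
    if df.shape[1] < 4:
        raise ValueError(f"{path}: expected 4 columns (chrom, pos, rate, map cM)")
    chroms = df.iloc[:, 0].astype(str).to_numpy()
    cm = df.iloc[:, 3].to_numpy(dtype=float)
    same = chroms[1:] == chroms[:-1]
    bad = np.nonzero((np.diff(cm) < 0) & same)[0]
    if bad.size:
        # +3: 1-based line numbering plus the header line
        raise ValueError(f"{path}: map column decreases at line {int(bad[0]) + 3}")
    out = {}
    for c in dict.fromkeys(chroms):
        sel = chroms == c
        out[c] = GeneticMap(c, df.iloc[:, 1].to_numpy(dtype=np.int64)[sel], cm[sel])
    return out


def read_genetic_map(path) -> GeneticMap:
    """Read a single-chromosome HapMap-format genetic map (see :func:`read_genetic_maps`)."""
    maps = read_genetic_maps(path)
    if len(maps) != 1:
        raise ValueError(f"{path}: expected one chromosome, found {sorted(maps)}")
    return next(iter(maps.values()))


def attach_map(
    haps: HaplotypeMatrix, maps, chrom_gap: float = 10.0, cumulative: bool = False
) -> HaplotypeMatrix:
    """Set ``haps.map_pos`` from per-chromosome maps.

    ``maps`` is a :class:`GeneticMap` or a dict of them keyed by chromosome.
    By default each chromosome's map is taken to restart at 0 (the HapMap
    convention) and chromosomes are separated by ``chrom_gap`` Morgans, so
    the global map stays non-decreasing while cross-chromosome site pairs
    land far outside any LD bin range.  With ``cumulative=True`` the map
    values are trusted as already globally cumulative (used for synthetic
    maps that carry meaningful inter-contig distances, e.g. two
    non-recombining loci on separate artificial contigs).  Returns ``haps``
    (modified in place).
    """
    if isinstance(maps, GeneticMap):
        maps = {maps.chrom: maps}
    pos = np.zeros(haps.n_sites)
    offset = 0.0
    for c in dict.fromkeys(haps.chrom):
        sel = haps.chrom == c
        if c not in maps:
            raise ValueError(f"no genetic map for chromosome {c!r}")
        pos[sel] = maps[c].interpolate(haps.positions_bp[sel]) + offset
        if not cumulative:
            offset = pos[sel].max() + chrom_gap
    haps.map_pos = pos
    return haps


def interpolate_map(gmap: GeneticMap, bp):
    """Functional alias for :meth:`GeneticMap.interpolate`."""
    return gmap.interpolate(bp)


def read_haplotypes_vcf(
    path,
    region: str | None = None,
    gmap: GeneticMap | None = None,
    haploid: bool = False,
) -> HaplotypeMatrix:
    """Read biallelic SNVs from a VCF into a :class:`HaplotypeMatrix`.

    Phased diploid genotypes become two haplotype rows per sample, haploid
    genotypes one row; a sample with any unphased heterozygote is represented
    as an unphased-diploid dosage row (ploidy flag ``'D'``).  With
    ``haploid=True`` every sample must be haploid or homozygous/phased —
    an unphased heterozygote raises, naming the offending record.
    Multiallelic sites and indels are skipped and counted in the log.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records = []
    skipped = 0
    it = vcf(region) if region else vcf
    for v in it:
        if len(v.ALT) != 1 or not v.is_snp:
            skipped += 1
            continue
        records.append((v.CHROM, v.POS, [list(g) for g in v.genotypes]))
    vcf.close()
    if skipped:
        logger.info("skipped %d non-SNV/multiallelic records in %s", skipped, path)
    if not records:
        raise ValueError(f"no biallelic SNVs found in {path}")

    n_sites = len(records)
    # per-sample structure: 'hap' (one row), 'phased' (two rows),
    # 'dip' (one unphased-diploid dosage row)
    kinds = []
    for si, name in enumerate(samples):
        all_haploid = True
        unphased_het_at = None
        for chrom, pos, gts in records:
            g = gts[si]
            if len(g) == 2:  # [allele, phased_flag] - haploid call
                continue
            all_haploid = False
            a0, a1, phased = g[0], g[1], bool(g[2])
            if not phased and a0 != a1 and min(a0, a1) >= 0 and unphased_het_at is None:
                unphased_het_at = (chrom, pos)
        if all_haploid:
            kinds.append("hap")
        elif unphased_het_at is not None:
            if haploid:
                raise ValueError(
                    f"unphased heterozygote for sample {name} at "
                    f"{unphased_het_at[0]}:{unphased_het_at[1]} in haploid mode"
                )
            kinds.append("dip")
        elif haploid:
            kinds.append("hap")  # homozygous diploid collapses to a pseudohaploid row
        else:
            kinds.append("phased")

    rows, names, ploidy = [], [], []
    for si, name in enumerate(samples):
        kind = kinds[si]
        if kind == "hap":
            row = np.array(
                [gts[si][0] if gts[si][0] >= 0 else MISSING for _, _, gts in records],
                dtype=np.int8,
            )
            rows.append(row)
            names.append(name)
            ploidy.append("H")
        elif kind == "phased":
            for which in (0, 1):
                row = np.array(
                    [
                        gts[si][which] if gts[si][which] >= 0 else MISSING
                        for _, _, gts in records
                    ],
                    dtype=np.int8,
                )
                rows.append(row)
                names.append(f"{name}_{which}")
                ploidy.append("H")
        else:
            row = np.empty(n_sites, dtype=np.int8)
            for j, (_, _, gts) in enumerate(records):
                a0, a1 = gts[si][0], gts[si][1]
                row[j] = MISSING if min(a0, a1) < 0 else a0 + a1
            rows.append(row)
            names.append(name)
            ploidy.append("D")

    chroms = np.array([r[0] for r in records], dtype=object)
    pos = np.array([r[1] for r in records], dtype=np.int64)
    map_pos = gmap.interpolate(pos) if gmap is not None else None
    return HaplotypeMatrix(
        genotypes=np.vstack(rows),
        positions_bp=pos,
        map_pos=map_pos,
        chrom=chroms,
        ploidy=np.array(ploidy, dtype=object),
        row_names=names,
    )


def write_haplotypes_vcf(haps: HaplotypeMatrix, path) -> None:
    """Write a :class:`HaplotypeMatrix` as an uncompressed VCF 4.2 (GT only).

    Haplotype rows are emitted as haploid samples; unphased-diploid rows as
    diploid samples with '/'-separated genotypes.  The output round-trips
    through :func:`read_haplotypes_vcf` and standard VCF parsers.
    """
    g = haps.genotypes
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=stratld\n")
        for c in dict.fromkeys(haps.chrom):
            length = int(haps.positions_bp[haps.chrom == c].max()) + 1000
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(n) for n in haps.row_names)
            + "\n"
        )
        for j in range(haps.n_sites):
            calls = []
            for i in range(haps.n_rows):
                x = int(g[i, j])
                if haps.ploidy[i] == "H":
                    calls.append("." if x < 0 else str(x))
                else:
                    if x < 0:
                        calls.append("./.")
                    else:
                        calls.append({0: "0/0", 1: "0/1", 2: "1/1"}[x])
            fh.write(
                f"{haps.chrom[j]}\t{int(haps.positions_bp[j])}\t.\tA\tT\t.\tPASS\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def write_sample_times(haps: HaplotypeMatrix, path) -> None:
    """Write the per-row sampling-age sidecar TSV (columns: sample, age_gens)."""
    pd.DataFrame(
        {"sample": haps.row_names, "age_gens": haps.sample_times}
    ).to_csv(path, sep="\t", index=False)


def read_sample_times(path) -> pd.DataFrame:
    """Read a sampling-age sidecar TSV written by :func:`write_sample_times`."""
    return pd.read_csv(path, sep="\t")
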