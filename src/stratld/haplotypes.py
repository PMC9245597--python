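"""Container for phased/pseudohaploid haplotype data with map positions and ages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HaplotypeMatrix", "MISSING"]

#: missing-genotype code in :attr:`HaplotypeMatrix.genotypes`
MISSING = -1


@dataclass
class HaplotypeMatrix:
    """Binary haplotypes with basepair and genetic-map coordinates.

    Rows are haplotypes (``ploidy == 'H'``, alleles 0/1) or unphased diploid
    samples (``ploidy == 'D'``, derived-allele dosages 0/1/2); ``MISSING``
    (-1) marks missing calls.  Sites are ordered by ``(chrom, position)``;
    basepair positions are strictly increasing within each chromosome and map
    positions (Morgans) are non-decreasing overall.  ``sample_times`` are ages
    per row, in generations before present by convention (0 = modern).
    """

    genotypes: np.ndarray
    positions_bp: np.ndarray
    map_pos: np.ndarray | None = None
    sample_times: np.ndarray | None = None
    ploidy: np.ndarray | None = None
    chrom: np.ndarray | None = None
    row_names: list | None = None

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-dimensional (rows x sites)")
        n, s = self.genotypes.shape
        self.positions_bp = np.asarray(self.positions_bp, dtype=np.int64)
        if self.positions_bp.size != s:
            raise ValueError("positions_bp length must match the site dimension")
        if self.chrom is None:
            self.chrom = np.array(["1"] * s, dtype=object)
        else:
            self.chrom = np.asarray(self.chrom, dtype=object)
            if self.chrom.size != s:
                raise ValueError("chrom length must match the site dimension")
        for c in dict.fromkeys(self.chrom):
            p = self.positions_bp[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions_bp must be strictly increasing within {c!r}")
        if self.map_pos is None:
            self.map_pos = np.zeros(s)
        else:
            self.map_pos = np.asarray(self.map_pos, dtype=float)
            if self.map_pos.size != s:
                raise ValueError("map_pos length must match the site dimension")
            if np.any(np.diff(self.map_pos) < 0):
                raise ValueError("map_pos must be non-decreasing")
        if self.sample_times is None:
            self.sample_times = np.zeros(n)
        else:
            self.sample_times = np.asarray(self.sample_times, dtype=float)
            if self.sample_times.size != n:
                raise ValueError("sample_times length must match the row dimension")
            if np.any(self.sample_times < 0):
                raise ValueError("sample_times must be >= 0")
        if self.ploidy is None:
            self.ploidy = np.array(["H"] * n, dtype=object)
        else:
            self.ploidy = np.asarray(self.ploidy, dtype=object)
            if self.ploidy.size != n:
                raise ValueError("ploidy length must match the row dimension")
            if not set(self.ploidy) <= {"H", "D"}:
                raise ValueError("ploidy flags must be 'H' or 'D'")
        if self.row_names is None:
            self.row_names = [f"hap{i}" for i in range(n)]

    @property
    def n_rows(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def take_sites(self, index) -> "HaplotypeMatrix":
        index = np.asarray(index)
        return HaplotypeMatrix(
            genotypes=self.genotypes[:, index],
            positions_bp=self.positions_bp[index],
            map_pos=self.map_pos[index],
            sample_times=self.sample_times.copy(),
            ploidy=self.ploidy.copy(),
            chrom=self.chrom[index],
            row_names=list(self.row_names),
        )

    def take_rows(self, index) -> "HaplotypeMatrix":
        index = np.asarray(index)
        return HaplotypeMatrix(
            genotypes=self.genotypes[index, :],
            positions_bp=self.positions_bp.copy(),
            map_pos=self.map_pos.copy(),
            sample_times=self.sample_times[index],
            ploidy=self.ploidy[index],
            chrom=self.chrom.copy(),
            row_names=[self.row_names[i] for i in np.atleast_1d(index)],
        )

    def frequencies(self) -> np.ndarray:
        """Per-site derived-allele frequency, missing-aware, dosage-aware."""
        g = self.genotypes
        hap = self.ploidy == "H"
        derived = np.zeros(self.n_sites)
        total = np.zeros(self.n_sites)
        gh = g[hap]
        obs = gh >= 0
        derived += np.where(obs, gh, 0).sum(axis=0)
        total += obs.sum(axis=0)
        gd = g[~hap]
        obs = gd >= 0
        derived += np.where(obs, gd, 0).sum(axis=0)
        total += 2 * obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return derived / total

    def allele_counts(self):
        """(derived count, total allele count) per site, missing-aware."""
        g = self.genotypes
        hap = self.ploidy == "H"
        gh, gd = g[hap], g[~hap]
        obs_h, obs_d = gh >= 0, gd >= 0
        derived = np.where(obs_h, gh, 0).sum(axis=0) + np.where(obs_d, gd, 0).sum(axis=0)
        total = obs_h.sum(axis=0) + 2 * obs_d.sum(axis=0)
        return derived.astype(float), total.astype(float)
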