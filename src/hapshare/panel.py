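"""Phased haplotype panel: the substrate of painting, IBD detection and ROH.

A panel holds H haplotypes (two per diploid individual, interleaved) over S
biallelic sites with base-pair and genetic (cM) coordinates.  Alleles are 0/1;
255 marks missing data (tolerated by QC, rejected by exact-matching stages).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = 255


@dataclass
class HaplotypePanel:
    """H x S phased binary alleles with per-site coordinates.

    Attributes
    ----------
    alleles
        uint8 matrix, shape (H, S); haplotypes ``2i`` and ``2i+1`` belong to
        individual ``individuals[i]``.
    site_chrom
        Chromosome identifier per site (string array); sites of one
        chromosome must be contiguous and cM-sorted.
    site_bp, site_cM
        1-based physical position and genetic position per site.
    individuals
        Individual identifiers, length H/2.
    ref, alt
        Optional REF/ALT bases per site (needed for strand-ambiguity QC).
    """

    alleles: np.ndarray
    site_chrom: np.ndarray
    site_bp: np.ndarray
    site_cM: np.ndarray
    individuals: list[str]
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        self.site_chrom = np.asarray(self.site_chrom)
        self.site_bp = np.asarray(self.site_bp, dtype=np.int64)
        self.site_cM = np.asarray(self.site_cM, dtype=np.float64)
        self.individuals = list(self.individuals)
        self.validate()

    # -- basic shape queries -------------------------------------------------
    @property
    def n_hap(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_ind(self) -> int:
        return self.n_hap // 2

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def chromosomes(self) -> list:
        """Chromosome ids in panel order."""
        seen: list = []
        for c in self.site_chrom:
            if not seen or seen[-1] != c:
                seen.append(c)
        return seen

    def chrom_slice(self, chrom) -> slice:
        idx = np.nonzero(self.site_chrom == chrom)[0]
        if idx.size == 0:
            raise KeyError(f"chromosome {chrom!r} not in panel")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def validate(self) -> None:
        H, S = self.alleles.shape
        if H % 2:
            raise ValueError("haplotype count must be even (diploid panel)")
        if len(self.individuals) != H // 2:
            raise ValueError("individuals length must equal H/2")
        if not (self.site_bp.shape == self.site_cM.shape == (S,)):
            raise ValueError("site coordinate arrays must have length S")
        ok = (self.alleles <= 1) | (self.alleles == MISSING)
        if not ok.all():
            raise ValueError("alleles must be 0/1 (or 255 for missing)")
        for c in self.chromosomes():
            sl = self.chrom_slice(c)
            if np.any(np.diff(self.site_cM[sl]) < 0):
                raise ValueError(f"site_cM not non-decreasing on chromosome {c}")

    def has_missing(self) -> bool:
        return bool((self.alleles == MISSING).any())

    # -- derived views -------------------------------------------------------
    def genotypes(self) -> np.ndarray:
        """Diploid dosage matrix (n_ind x S), int8; -1 where either allele missing."""
        a = self.alleles[0::2].astype(np.int16)
        b = self.alleles[1::2].astype(np.int16)
        g = a + b
        g[(a == MISSING) | (b == MISSING)] = -1
        return g.astype(np.int8)

    def site_weights(self) -> np.ndarray:
        """Per-site cM ownership: midpoints between neighbours, clamped at
        chromosome ends.  Sums to the chromosome cM span, so painted
        chunklengths conserve total map length exactly."""
        w = np.empty(self.n_sites)
        for c in self.chromosomes():
            sl = self.chrom_slice(c)
            cm = self.site_cM[sl]
            if cm.size == 1:
                w[sl] = 0.0
                continue
            lo = np.empty_like(cm)
            hi = np.empty_like(cm)
            lo[0] = cm[0]
            lo[1:] = (cm[1:] + cm[:-1]) / 2
            hi[:-1] = lo[1:]
            hi[-1] = cm[-1]
            w[sl] = hi - lo
        return w

    def total_map_length_cM(self) -> float:
        """Sum over chromosomes of cM(last site) - cM(first site)."""
        total = 0.0
        for c in self.chromosomes():
            sl = self.chrom_slice(c)
            total += float(self.site_cM[sl][-1] - self.site_cM[sl][0])
        return total

    def subset_sites(self, keep: np.ndarray) -> "HaplotypePanel":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.nonzero(keep)[0]
        return HaplotypePanel(
            alleles=self.alleles[:, keep],
            site_chrom=self.site_chrom[keep],
            site_bp=self.site_bp[keep],
            site_cM=self.site_cM[keep],
            individuals=self.individuals,
            ref=None if self.ref is None else np.asarray(self.ref)[keep],
            alt=None if self.alt is None else np.asarray(self.alt)[keep],
        )

    def subset_individuals(self, keep_idx: np.ndarray) -> "HaplotypePanel":
        keep_idx = np.asarray(keep_idx, dtype=np.int64)
        hap_idx = np.empty(2 * keep_idx.size, dtype=np.int64)
        hap_idx[0::2] = 2 * keep_idx
        hap_idx[1::2] = 2 * keep_idx + 1
        return HaplotypePanel(
            alleles=self.alleles[hap_idx],
            site_chrom=self.site_chrom,
            site_bp=self.site_bp,
            site_cM=self.site_cM,
            individuals=[self.individuals[i] for i in keep_idx],
            ref=self.ref,
            alt=self.alt,
        )
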