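"""Readers, writers and site/individual QC.

Phased VCF is the exchange format for panels (read through cyvcf2, written
as plain VCF 4.2 text); genetic maps are PLINK ``.map`` tables with linear
interpolation of cM positions; coancestry matrices go to square labelled TSV
(fineSTRUCTURE-style layout).  QC mirrors the usual array pipeline:
strand-ambiguous removal, site missingness, MAF, Hardy-Weinberg exact test,
individual missingness, followed by windowed LD pruning and
variance-standardised allele-frequency PCA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import MISSING, HaplotypePanel

logger = logging.getLogger(__name__)

_AMBIGUOUS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_phased_vcf(path: str, map_path: str | None = None) -> HaplotypePanel:
    """Load a phased diploid VCF into a panel.

    Biallelic sites only (multi-allelic records are skipped with a warning);
    any unphased non-missing genotype is an error naming the record.  cM
    positions are zero unless a PLINK .map is given.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    haps: list = []
    chroms: list = []
    bps: list = []
    refs: list = []
    alts: list = []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        col = np.empty(2 * len(samples), dtype=np.uint8)
        for si, g in enumerate(v.genotypes):
            a, b, phased = g[0], g[1], g[-1]
            if not phased and not (a < 0 and b < 0):
                raise ValueError(
                    f"unphased genotype at {v.CHROM}:{v.POS} sample {samples[si]}"
                )
            col[2 * si] = MISSING if a < 0 else a
            col[2 * si + 1] = MISSING if b < 0 else b
        haps.append(col)
        chroms.append(v.CHROM)
        bps.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
    if n_multi:
        logger.warning("skipped %d multi-allelic records", n_multi)
    alleles = np.array(haps, dtype=np.uint8).T
    site_chrom = np.array(chroms)
    site_bp = np.array(bps, dtype=np.int64)
    if map_path is not None:
        site_cM = genetic_positions(map_path, site_chrom, site_bp)
    else:
        site_cM = np.zeros(site_bp.size)
    return HaplotypePanel(
        alleles=alleles,
        site_chrom=site_chrom,
        site_bp=site_bp,
        site_cM=site_cM,
        individuals=samples,
        ref=np.array(refs),
        alt=np.array(alts),
    )


def write_phased_vcf(panel: HaplotypePanel, path: str) -> None:
    ref = panel.ref if panel.ref is not None else np.full(panel.n_sites, "A")
    alt = panel.alt if panel.alt is not None else np.full(panel.n_sites, "G")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in panel.chromosomes():
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.individuals)
            + "\n"
        )
        a = panel.alleles
        for k in range(panel.n_sites):
            gts = []
            for i in range(panel.n_ind):
                x, y = a[2 * i, k], a[2 * i + 1, k]
                gts.append(
                    f"{'.' if x == MISSING else x}|{'.' if y == MISSING else y}"
                )
            fh.write(
                f"{panel.site_chrom[k]}\t{panel.site_bp[k]}\tsnp{k}\t{ref[k]}\t{alt[k]}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------

def write_map(panel: HaplotypePanel, path: str) -> None:
    """PLINK .map: chrom, snp id, cM, bp."""
    pd.DataFrame(
        {
            "chrom": panel.site_chrom,
            "snp": [f"snp{k}" for k in range(panel.n_sites)],
            "cM": panel.site_cM,
            "bp": panel.site_bp,
        }
    ).to_csv(path, sep="\t", header=False, index=False)


def read_map(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["chrom", "snp", "cM", "bp"])
    df["chrom"] = df["chrom"].astype(str)
    return df


def genetic_positions(map_source, site_chrom, site_bp) -> np.ndarray:
    """cM for each site by linear interpolation of the map, constant beyond
    the map ends; a site on a chromosome absent from the map is an error."""
    mp = read_map(map_source) if not isinstance(map_source, pd.DataFrame) else map_source
    site_chrom = np.asarray(site_chrom).astype(str)
    site_bp = np.asarray(site_bp, dtype=np.int64)
    out = np.empty(site_bp.size)
    for chrom in pd.unique(site_chrom):
        rows = mp[mp["chrom"] == chrom].sort_values("bp")
        if rows.empty:
            raise ValueError(f"chromosome {chrom} absent from genetic map")
        sel = site_chrom == chrom
        out[sel] = np.interp(site_bp[sel], rows["bp"].values, rows["cM"].values)
    return out


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass
class QCParams:
    max_site_missing: float = 0.05
    min_maf: float = 0.02
    min_hwe_p: float = 1e-6
    max_indiv_missing: float = 0.05
    drop_strand_ambiguous: bool = True

    def __post_init__(self) -> None:
        for f in ("max_site_missing", "min_maf", "max_indiv_missing"):
            if not 0 <= getattr(self, f) <= 1:
                raise ValueError(f"{f} must be in [0, 1]")


def hwe_exact_p(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test p-value (two-sided, mid-p off)."""
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_rare = n_het + 2 * min(n_hom1, n_hom2)
    # distribution of heterozygote count conditional on n and n_rare
    probs = np.zeros(n_rare + 1)
    mid = n_rare * (2 * n - n_rare) // (2 * n)
    if mid % 2 != n_rare % 2:
        mid += 1
    probs[mid] = 1.0
    het = mid
    while het > 1:
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        probs[het - 2] = probs[het] * het * (het - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        het -= 2
    het = mid
    while het <= n_rare - 2:
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        probs[het + 2] = probs[het] * 4.0 * hom_r * hom_c / ((het + 2.0) * (het + 1.0))
        het += 2
    probs /= probs.sum()
    return float(min(1.0, probs[probs <= probs[n_het] * (1 + 1e-12)].sum()))


def qc_filter(panel: HaplotypePanel, params: QCParams | None = None):
    """Site then individual QC; returns (filtered panel, report dict)."""
    params = params or QCParams()
    gt = panel.genotypes()
    n_ind, S = gt.shape
    keep = np.ones(S, dtype=bool)
    report = {"n_sites": S, "n_individuals": n_ind}

    if params.drop_strand_ambiguous and panel.ref is not None and panel.alt is not None:
        amb = np.array(
            [(r, a) in _AMBIGUOUS for r, a in zip(panel.ref, panel.alt)]
        )
        keep &= ~amb
        report["strand_ambiguous"] = int(amb.sum())
    else:
        report["strand_ambiguous"] = 0

    valid = gt >= 0
    miss = 1.0 - valid.mean(axis=0)
    bad = keep & (miss > params.max_site_missing)
    report["site_missingness"] = int(bad.sum())
    keep &= ~bad

    with np.errstate(invalid="ignore"):
        p = np.where(valid, gt, 0).sum(axis=0) / np.maximum(2.0 * valid.sum(axis=0), 1)
    maf = np.minimum(p, 1 - p)
    bad = keep & (maf < params.min_maf)
    report["maf"] = int(bad.sum())
    keep &= ~bad

    n_hwe = 0
    for k in np.nonzero(keep)[0]:
        col = gt[:, k]
        ok = col >= 0
        pval = hwe_exact_p(
            int(np.count_nonzero(col[ok] == 1)),
            int(np.count_nonzero(col[ok] == 0)),
            int(np.count_nonzero(col[ok] == 2)),
        )
        if pval < params.min_hwe_p:
            keep[k] = False
            n_hwe += 1
    report["hwe"] = n_hwe

    out = panel.subset_sites(keep)
    ind_miss = 1.0 - (out.genotypes() >= 0).mean(axis=1)
    ind_keep = ind_miss <= params.max_indiv_missing
    report["individual_missingness"] = int((~ind_keep).sum())
    if not ind_keep.all():
        out = out.subset_individuals(np.nonzero(ind_keep)[0])
    report["sites_retained"] = int(keep.sum())
    report["individuals_retained"] = int(ind_keep.sum())
    return out, report


# ---------------------------------------------------------------------------
# LD pruning and allele-frequency PCA
# ---------------------------------------------------------------------------

def ld_prune(
    genotypes: np.ndarray,
    window_snp: int = 1000,
    step: int = 50,
    r2_max: float = 0.2,
) -> np.ndarray:
    """Greedy windowed LD pruning (PLINK --indep-pairwise semantics): within
    each window, for every pair with r^2 > r2_max the later site is removed;
    deterministic.  Returns indices of retained sites."""
    gt = np.array(genotypes, dtype=float, copy=True)
    gt[gt < 0] = np.nan
    n, S = gt.shape
    kept = np.ones(S, dtype=bool)
    col_mean = np.nanmean(gt, axis=0)
    filled = np.where(np.isnan(gt), col_mean, gt)
    centred = filled - filled.mean(axis=0)
    norm = np.sqrt((centred**2).sum(axis=0))
    norm[norm == 0] = np.inf  # monomorphic: correlates with nothing
    for start in range(0, max(S - 1, 1), step):
        idx = np.nonzero(kept[start : min(start + window_snp, S)])[0] + start
        if idx.size < 2:
            continue
        X = centred[:, idx] / norm[idx]
        r2 = (X.T @ X) ** 2
        alive = np.ones(idx.size, dtype=bool)
        for j in range(1, idx.size):
            if alive[j] and np.any(alive[:j] & (r2[:j, j] > r2_max)):
                alive[j] = False
        kept[idx[~alive]] = False
        if start + window_snp >= S:
            break
    return np.nonzero(kept)[0]


def allele_pca(genotypes: np.ndarray, k: int):
    """Variance-standardised genotype PCA: centre by 2p, scale by
    sqrt(2p(1-p)), mean-impute missing, SVD.  Returns (coords, explained)."""
    gt = np.array(genotypes, dtype=float, copy=True)
    gt[gt < 0] = np.nan
    p = np.nanmean(gt, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.all():
        logger.warning("dropping %d monomorphic sites before PCA", int((~poly).sum()))
    gt = gt[:, poly]
    p = p[poly]
    X = (gt - 2 * p) / np.sqrt(2 * p * (1 - p))
    X = np.where(np.isnan(X), 0.0, X)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError("need 1 <= k <= n_individuals")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    coords = U[:, :k] * s[:k]
    for j in range(k):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            coords[:, j] = -coords[:, j]
    explained = (s**2) / max((s**2).sum(), 1e-300)
    return coords, explained[:k]


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------

def write_matrix_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t")


def read_matrix_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
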