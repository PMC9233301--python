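"""Runs of homozygosity and the two inbreeding coefficients F_ROH and F_SNP.

The ROH scan re-implements the PLINK sliding-window procedure: 50-SNP
windows pass with at most 1 heterozygote and 5 missing calls; a SNP is a run
candidate when at least 5% of the windows covering it pass; maximal candidate
runs are reported if they hold >= 50 SNPs, span >= 1500 kb, contain no
inter-SNP gap > 1000 kb and average at least one SNP per 50 kb.

F_ROH is the fraction of the genome (autosomal constant 2,879,248,291 bp for
human data; configurable for simulated genomes) in ROH longer than 1.5 Mb —
inbreeding relative to an unknown base generation.  F_SNP is the
excess-homozygosity estimate of inbreeding in the current generation,
(O(HOM) - E(HOM)) / (N - E(HOM)) with the HWE expectation computed from
within-group allele frequencies (sample-size corrected): 0 means random
mating, > 0 consanguinity, < 0 inbreeding avoidance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GENOME_BP = 2_879_248_291


@dataclass
class ROHParams:
    window_snp: int = 50
    window_het_max: int = 1
    window_missing_max: int = 5
    min_snp: int = 50
    min_kb: float = 1500.0
    max_gap_kb: float = 1000.0
    min_density_kb_per_snp: float = 50.0
    window_hit_threshold: float = 0.05

    def __post_init__(self) -> None:
        for f, v in self.__dict__.items():
            if v <= 0:
                raise ValueError(f"{f} must be positive")


def _roh_one(gt: np.ndarray, bp: np.ndarray, p: ROHParams) -> list:
    """ROH intervals (start_idx, end_idx inclusive) for one individual/chromosome."""
    S = gt.size
    W = p.window_snp
    if S < W:
        return []
    het = (gt == 1).astype(np.int64)
    mis = (gt < 0).astype(np.int64)
    ch = np.concatenate([[0], np.cumsum(het)])
    cm = np.concatenate([[0], np.cumsum(mis)])
    # window w covers SNPs [w, w+W); passes on het/missing caps
    nw = S - W + 1
    wh = ch[W:] - ch[:-W]
    wm = cm[W:] - cm[:-W]
    passing = ((wh <= p.window_het_max) & (wm <= p.window_missing_max)).astype(np.int64)
    cp = np.concatenate([[0], np.cumsum(passing)])
    # windows covering SNP k: indices [max(0, k-W+1), min(nw-1, k)]
    k = np.arange(S)
    w_lo = np.maximum(0, k - W + 1)
    w_hi = np.minimum(nw - 1, k)
    covering = (w_hi - w_lo + 1).astype(float)
    hits = (cp[w_hi + 1] - cp[w_lo]).astype(float)
    candidate = hits / covering >= p.window_hit_threshold
    out = []
    i = 0
    while i < S:
        if not candidate[i]:
            i += 1
            continue
        j = i
        while j + 1 < S and candidate[j + 1]:
            j += 1
        # split the candidate run at gaps > max_gap_kb
        s = i
        for t in range(i, j + 1):
            if t > s and (bp[t] - bp[t - 1]) / 1000.0 > p.max_gap_kb:
                out.append((s, t - 1))
                s = t
        out.append((s, j))
        i = j + 1
    final = []
    for s, e in out:
        n_snp = e - s + 1
        kb = (bp[e] - bp[s]) / 1000.0
        if n_snp < p.min_snp or kb < p.min_kb:
            continue
        if kb / n_snp > p.min_density_kb_per_snp:
            continue
        final.append((s, e))
    return final


def detect_roh(
    genotypes: np.ndarray,
    site_bp: np.ndarray,
    site_chrom: np.ndarray,
    individuals,
    params: ROHParams | None = None,
) -> pd.DataFrame:
    """PLINK-style window ROH scan over a diploid dosage matrix (0/1/2, -1
    missing).  Returns one row per ROH: individual, chrom, start_bp, end_bp,
    n_snp, kb."""
    params = params or ROHParams()
    genotypes = np.asarray(genotypes)
    site_bp = np.asarray(site_bp, dtype=np.int64)
    site_chrom = np.asarray(site_chrom)
    rows = []
    for chrom in pd.unique(site_chrom):
        sel = site_chrom == chrom
        bp = site_bp[sel]
        if np.any(np.diff(bp) < 0):
            raise ValueError(f"unsorted positions on chromosome {chrom}")
        block = genotypes[:, sel]
        for ii, ind in enumerate(individuals):
            for s, e in _roh_one(block[ii], bp, params):
                rows.append(
                    (ind, chrom, int(bp[s]), int(bp[e]), e - s + 1, (bp[e] - bp[s]) / 1000.0)
                )
    return pd.DataFrame(
        rows, columns=["individual", "chrom", "start_bp", "end_bp", "n_snp", "kb"]
    )


def f_roh(roh: pd.DataFrame, individuals, genome_bp: int = GENOME_BP,
          min_length_bp: float = 1_500_000) -> pd.Series:
    """Fraction of the genome in ROH strictly longer than 1.5 Mb."""
    out = pd.Series(0.0, index=list(individuals), name="F_ROH")
    if len(roh):
        lengths = roh["end_bp"] - roh["start_bp"]
        big = roh[lengths > min_length_bp]
        sums = (big["end_bp"] - big["start_bp"]).groupby(big["individual"]).sum()
        out.loc[sums.index] = sums / genome_bp
    return out


def f_snp_ratio(o_hom: float, e_hom: float, n: float) -> float:
    """The excess-homozygosity ratio (O(HOM) - E(HOM)) / (N - E(HOM))."""
    denom = n - e_hom
    if denom == 0:
        return float("nan")
    return (o_hom - e_hom) / denom


def f_snp(genotypes: np.ndarray, individuals, group_assignment: pd.Series) -> pd.DataFrame:
    """Per-individual F_SNP = (O_HOM - E_HOM) / (N - E_HOM), frequencies and
    HWE expectation computed within each individual's cluster group over the
    group's polymorphic sites."""
    genotypes = np.asarray(genotypes)
    individuals = list(individuals)
    groups = pd.Series(group_assignment).reindex(individuals)
    if groups.isna().any():
        raise ValueError("every individual needs a group")
    rows = []
    for grp in groups.unique():
        member_idx = [i for i, ind in enumerate(individuals) if groups.iloc[i] == grp]
        g = genotypes[member_idx]
        valid = g >= 0
        n_copies = 2.0 * valid.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(valid, g, 0).sum(axis=0) / np.maximum(n_copies, 1)
        poly = (p > 0) & (p < 1) & (n_copies > 2)
        pg = p[poly]
        ng = n_copies[poly]
        e_site = 1.0 - 2.0 * pg * (1.0 - pg) * ng / (ng - 1.0)
        gp = g[:, poly]
        vp = valid[:, poly]
        for row, (gi, vi) in enumerate(zip(gp, vp)):
            N = int(vi.sum())
            o_hom = int(np.count_nonzero((gi != 1) & vi))
            e_hom = float(e_site[vi].sum())
            fsnp = f_snp_ratio(o_hom, e_hom, N)
            rows.append((individuals[member_idx[row]], grp, fsnp, o_hom, e_hom, N))
    df = pd.DataFrame(
        rows, columns=["individual", "group", "F_SNP", "O_HOM", "E_HOM", "N"]
    ).set_index("individual")
    return df.loc[individuals]
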