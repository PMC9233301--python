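"""Forward-in-time pedigree and recombination simulator with ground-truth IBD.

Emulates multi-subpopulation phased SNP panels: a discrete-generation pedigree
(monogamous male/female pairing, per-generation subpopulation sizes, migration
of fathers between subpopulations, optional first-cousin matings), gamete
transmission under the Haldane crossover model (Poisson, no interference), and
genotyping on top of founder haplotypes with configurable allele-frequency
law, genotype error and phase-switch error.

Because founder haplotypes are all unrelated, identity by descent is defined
unambiguously over the simulated generations: two final haplotypes are IBD on
an interval exactly where their ancestry mosaics carry the same founder
haplotype.  ``truth_ibd`` extracts these segments as a truth set for the
detection, demography and inbreeding modules.

Population-genetic calibration: mothers are drawn uniformly among the
``N/2`` females of a subpopulation and fathers follow a random perfect
matching of females to males, which keeps the per-generation coalescence
probability of two lineages in distinct individuals at exactly ``1/(2N)``
(diploid effective size = census size) while producing full-sib families, so
"first cousins" carry the textbook kinship of 1/16.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import HaplotypePanel

logger = logging.getLogger(__name__)

FEMALE, MALE = 0, 1

# non-strand-ambiguous REF/ALT pairs cycled across simulated sites
_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"))


@dataclass(frozen=True)
class ChromosomeSpec:
    length_cM: float
    n_sites: int
    length_bp: int

    @property
    def name(self) -> str:  # overridden positionally when building panels
        return ""


@dataclass
class SimConfig:
    """Study conditions for one simulated panel.

    ``size_per_generation`` may be an int (constant everywhere), a sequence of
    per-subpop constants, or an (n_subpops, G+1) array giving the diploid
    count of every subpopulation at every generation (0 = founders).  A size
    of 0 founds the subpopulation later: its first non-empty generation draws
    both parents through the migration row.
    """

    n_subpops: int = 1
    size_per_generation: object = 100
    migration: np.ndarray | None = None  # rows sum to 1; row s = father-subpop law for children of subpop s
    cousin_mating_rate: float = 0.0
    n_generations: int = 10
    chromosomes: tuple = ((100.0, 3000, 100_000_000),)
    maf_law: tuple = ("uniform", 0.02, 0.5)
    genotype_error_rate: float = 0.0
    phase_switch_rate: float = 0.0
    sample_size: object = None  # None = all final individuals; int or per-subpop sequence
    seed: int = 0

    def __post_init__(self) -> None:
        self.chromosomes = tuple(
            c if isinstance(c, ChromosomeSpec) else ChromosomeSpec(*c)
            for c in self.chromosomes
        )
        if self.migration is None:
            self.migration = np.eye(self.n_subpops)
        self.migration = np.asarray(self.migration, dtype=float)
        self.validate()

    def validate(self) -> None:
        G = self.n_generations
        if G < 0:
            raise ValueError("n_generations must be >= 0")
        sizes = self.sizes_table()
        active = sizes > 0
        if np.any(sizes[active] < 2):
            raise ValueError("insufficient parents: subpop sizes must be >= 2 when non-zero")
        if sizes[:, 0].sum() < 2:
            raise ValueError("insufficient parents: need >= 2 founders")
        if self.migration.shape != (self.n_subpops, self.n_subpops):
            raise ValueError("migration must be n_subpops x n_subpops")
        if np.any(self.migration < 0) or not np.allclose(self.migration.sum(axis=1), 1.0):
            raise ValueError("migration rows must be non-negative and sum to 1")
        for r in (self.cousin_mating_rate, self.genotype_error_rate, self.phase_switch_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")

    def sizes_table(self) -> np.ndarray:
        """(n_subpops, G+1) diploid counts."""
        G = self.n_generations
        s = self.size_per_generation
        if np.isscalar(s):
            return np.full((self.n_subpops, G + 1), int(s), dtype=int)
        s = np.asarray(s, dtype=int)
        if s.ndim == 1:
            if s.size != self.n_subpops:
                raise ValueError("per-subpop sizes must have length n_subpops")
            return np.repeat(s[:, None], G + 1, axis=1)
        if s.shape != (self.n_subpops, G + 1):
            raise ValueError("size table must be (n_subpops, G+1)")
        return s

    def maf_sampler(self, rng: np.random.Generator, n: int) -> np.ndarray:
        kind = self.maf_law[0]
        if kind == "uniform":
            lo, hi = self.maf_law[1], self.maf_law[2]
            return rng.uniform(lo, hi, n)
        if kind == "beta":
            a, b = self.maf_law[1], self.maf_law[2]
            return np.clip(rng.beta(a, b, n), 1e-3, 1 - 1e-3)
        raise ValueError(f"unknown maf_law {kind!r}")


def _stage_rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stage,)))


@dataclass
class Generation:
    subpop: np.ndarray
    sex: np.ndarray
    mother: np.ndarray  # index into previous generation, -1 for founders
    father: np.ndarray

    @property
    def n(self) -> int:
        return self.subpop.size


@dataclass
class Pedigree:
    generations: list
    n_subpops: int
    cousin_matings: int = 0
    cousin_fallbacks: int = 0

    @property
    def n_generations(self) -> int:
        return len(self.generations) - 1

    @property
    def final(self) -> Generation:
        return self.generations[-1]


def _assign_sexes(subpop: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Exactly floor(n/2) females within every subpopulation."""
    sex = np.full(subpop.size, MALE, dtype=np.int8)
    for s in np.unique(subpop):
        idx = np.nonzero(subpop == s)[0]
        sex[idx[rng.permutation(idx.size)[: idx.size // 2]]] = FEMALE
    return sex


def simulate_pedigree(config: SimConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Build the G-generation pedigree; generation 0 are unrelated founders."""
    rng = rng if rng is not None else _stage_rng(config, 0)
    sizes = config.sizes_table()
    G = config.n_generations
    nsub = config.n_subpops

    gens: list[Generation] = []
    n0 = int(sizes[:, 0].sum())
    subpop0 = np.repeat(np.arange(nsub), sizes[:, 0])
    gens.append(
        Generation(subpop0, _assign_sexes(subpop0, rng), np.full(n0, -1), np.full(n0, -1))
    )
    # children_of[g][parent] = child indices in generation g whose mother or father is `parent`
    children_of: list[dict] = [defaultdict(list)]
    cousin_matings = fallbacks = 0

    for g in range(1, G + 1):
        prev = gens[-1]
        # per-subpop female/male pools and the monogamous pairing
        females = [np.nonzero((prev.subpop == s) & (prev.sex == FEMALE))[0] for s in range(nsub)]
        males = [np.nonzero((prev.subpop == s) & (prev.sex == MALE))[0] for s in range(nsub)]
        partner = np.full(prev.n, -1)
        for s in range(nsub):
            f, m = females[s], males[s]
            k = min(f.size, m.size)
            if k:
                partner[f[:k]] = m[rng.permutation(m.size)[:k]]
        # consanguineous unions: with probability cousin_mating_rate a
        # female's partner is replaced by one of her male first cousins
        # (falling back to the assigned partner when she has none)
        if config.cousin_mating_rate > 0:
            for s in range(nsub):
                for fem in females[s]:
                    if partner[fem] >= 0 and rng.random() < config.cousin_mating_rate:
                        cands = _male_cousins(gens, children_of, int(fem))
                        if cands:
                            partner[fem] = cands[rng.integers(len(cands))]
                            cousin_matings += 1
                        else:
                            fallbacks += 1

        sub_list, mo_list, fa_list = [], [], []
        for s in range(nsub):
            n_child = int(sizes[s, g])
            if n_child == 0:
                continue
            prev_size = int(sizes[s, g - 1])
            row = config.migration[s].copy()
            # drop empty father subpops and renormalise
            avail = np.array([males[t].size > 0 for t in range(nsub)])
            row[~avail] = 0.0
            if row.sum() == 0:
                raise ValueError(f"insufficient parents: no available fathers for subpop {s}")
            row = row / row.sum()

            if prev_size == 0:
                # newly founded subpop: mothers drawn through the migration row too
                msub = rng.choice(nsub, n_child, p=row)
                mavail = np.array([females[t].size > 0 for t in range(nsub)])
                if not mavail[np.unique(msub)].all():
                    raise ValueError(f"insufficient parents: no mothers for new subpop {s}")
                mothers = np.array([rng.choice(females[t]) for t in msub])
            else:
                if females[s].size == 0:
                    raise ValueError(f"insufficient parents: no females in subpop {s}")
                mothers = rng.choice(females[s], n_child)

            fsub = rng.choice(nsub, n_child, p=row)
            fathers = np.empty(n_child, dtype=int)
            for i in range(n_child):
                t = fsub[i]
                if t == prev.subpop[mothers[i]] and partner[mothers[i]] >= 0:
                    fathers[i] = partner[mothers[i]]
                else:
                    fathers[i] = males[t][rng.integers(males[t].size)]
            sub_list.append(np.full(n_child, s))
            mo_list.append(mothers)
            fa_list.append(fathers)

        subpop = np.concatenate(sub_list)
        mother = np.concatenate(mo_list)
        father = np.concatenate(fa_list)
        gens.append(Generation(subpop, _assign_sexes(subpop, rng), mother, father))
        cmap: dict = defaultdict(list)
        for child, (m, f) in enumerate(zip(mother, father)):
            cmap[int(m)].append(child)
            if f != m:
                cmap[int(f)].append(child)
        children_of.append(cmap)

    if fallbacks:
        logger.info("cousin mating fell back to regular choice %d times", fallbacks)
    return Pedigree(gens, nsub, cousin_matings, fallbacks)


def _male_cousins(gens: list, children_of: list, i: int) -> list:
    """Male first cousins of individual ``i`` of the latest built generation."""
    g = len(gens) - 1  # i lives in generation g
    if g < 2:
        return []
    cur, par, gpar = gens[g], gens[g - 1], gens[g - 2]
    sibs: set = set()
    for p in (cur.mother[i], cur.father[i]):  # parents of i, in generation g-1
        for gp in (par.mother[p], par.father[p]):  # grandparents, generation g-2
            if gp < 0:
                continue
            for q in children_of[g - 1][int(gp)]:
                if q != p:
                    sibs.add(q)
    out = []
    for s in sibs:
        for c in children_of[g][int(s)]:
            if c != i and cur.sex[c] == MALE:
                out.append(c)
    return out


# ---------------------------------------------------------------------------
# haplotype transmission
# ---------------------------------------------------------------------------

@dataclass
class AncestryMosaic:
    """Founder-haplotype mosaics of the final generation.

    ``haps[h][c] = (starts, ids)``: ordered interval starts in cM (first is
    0.0) and the founder haplotype carried on each interval of chromosome
    ``c``; the last interval runs to ``chrom_lengths_cM[c]``.  Haplotypes
    ``2i`` and ``2i+1`` belong to ``individuals[i]``.
    """

    haps: list
    chrom_lengths_cM: list
    individuals: list
    n_founder_haps: int
    chrom_names: list | None = None

    def __post_init__(self) -> None:
        if self.chrom_names is None:
            self.chrom_names = [f"chr{c + 1}" for c in range(len(self.chrom_lengths_cM))]

    @property
    def n_ind(self) -> int:
        return len(self.haps) // 2

    def subset(self, keep_idx) -> "AncestryMosaic":
        keep_idx = np.asarray(keep_idx, dtype=int)
        haps = []
        for i in keep_idx:
            haps.append(self.haps[2 * i])
            haps.append(self.haps[2 * i + 1])
        return AncestryMosaic(
            haps, self.chrom_lengths_cM, [self.individuals[i] for i in keep_idx],
            self.n_founder_haps, self.chrom_names,
        )


def _recombine(h0, h1, xs: np.ndarray, first: int):
    """Alternate pieces of the two parental mosaics at crossover points ``xs``."""
    haps = (h0, h1)
    out_s, out_i = [], []
    prev = 0.0
    cur = first
    for x in np.append(xs, np.inf):
        s, ids = haps[cur]
        i0 = int(np.searchsorted(s, prev, side="right")) - 1
        i1 = len(s) if x == np.inf else int(np.searchsorted(s, x, side="left"))
        if i1 > i0:
            seg = s[i0:i1].copy()
            seg[0] = prev
            out_s.append(seg)
            out_i.append(ids[i0:i1])
        prev = x
        cur ^= 1
    starts = np.concatenate(out_s)
    ids = np.concatenate(out_i)
    keep = np.empty(ids.size, dtype=bool)
    keep[0] = True
    keep[1:] = ids[1:] != ids[:-1]
    return starts[keep], ids[keep]


def transmit_haplotypes(
    pedigree: Pedigree, config: SimConfig, rng: np.random.Generator | None = None
) -> AncestryMosaic:
    """Drop haplotypes through the pedigree; crossovers ~ Poisson(L_cM/100)."""
    rng = rng if rng is not None else _stage_rng(config, 1)
    lengths = [c.length_cM for c in config.chromosomes]
    n0 = pedigree.generations[0].n
    cur = [
        [[(np.array([0.0]), np.array([2 * i + h])) for _ in lengths] for h in (0, 1)]
        for i in range(n0)
    ]
    for g in range(1, pedigree.n_generations + 1):
        gen = pedigree.generations[g]
        nxt = []
        for child in range(gen.n):
            ent = []
            for parent in (gen.mother[child], gen.father[child]):
                p0, p1 = cur[parent]
                hap = []
                for c, L in enumerate(lengths):
                    ncx = rng.poisson(L / 100.0) if L > 0 else 0
                    first = int(rng.integers(2))
                    if ncx == 0:
                        hap.append((p0 if first == 0 else p1)[c])
                    else:
                        xs = np.sort(rng.uniform(0.0, L, ncx))
                        hap.append(_recombine(p0[c], p1[c], xs, first))
                ent.append(hap)
            nxt.append(ent)
        cur = nxt

    n_final = pedigree.final.n
    haps = []
    for i in range(n_final):
        haps.append(cur[i][0])
        haps.append(cur[i][1])
    individuals = [f"I{i:05d}" for i in range(n_final)]
    return AncestryMosaic(haps, lengths, individuals, 2 * n0)


# ---------------------------------------------------------------------------
# ground-truth IBD
# ---------------------------------------------------------------------------

def _merge_touching(ivals: list) -> list:
    ivals.sort()
    out = []
    for s, e in ivals:
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1][1] = e
        else:
            out.append([s, e])
    return out


def truth_ibd(
    mosaic: AncestryMosaic, min_cM: float = 0.0, pairs: list | None = None
) -> pd.DataFrame:
    """All maximal intervals where two haplotypes carry the same founder.

    ``pairs`` restricts to specific haplotype-index pairs (global indices,
    ``2i+h``); by default every pair is scanned, including an individual's own
    two haplotypes (self-pairs measure autozygosity).  Returns a frame with
    columns id_a, hap_a, id_b, hap_b, chrom, start_cM, end_cM, length_cM.
    """
    if min_cM < 0:
        raise ValueError("min_cM must be >= 0")
    rows = []
    nh = len(mosaic.haps)
    for c, L in enumerate(mosaic.chrom_lengths_cM):
        shared: dict = defaultdict(list)
        if pairs is None:
            by_founder: dict = defaultdict(list)
            for hg in range(nh):
                starts, ids = mosaic.haps[hg][c]
                ends = np.append(starts[1:], L)
                for s, e, f in zip(starts, ends, ids):
                    by_founder[int(f)].append((hg, s, e))
            for lst in by_founder.values():
                for i in range(len(lst)):
                    h1, s1, e1 = lst[i]
                    for j in range(i + 1, len(lst)):
                        h2, s2, e2 = lst[j]
                        if h1 == h2:
                            continue
                        s, e = max(s1, s2), min(e1, e2)
                        if e > s:
                            shared[(h1, h2) if h1 < h2 else (h2, h1)].append([s, e])
        else:
            for h1, h2 in pairs:
                h1, h2 = (h1, h2) if h1 < h2 else (h2, h1)
                ivs = _intersect_mosaics(mosaic.haps[h1][c], mosaic.haps[h2][c], L)
                if ivs:
                    shared[(h1, h2)].extend(ivs)
        for (h1, h2), ivals in shared.items():
            for s, e in _merge_touching(ivals):
                if e - s >= min_cM:
                    rows.append(
                        (
                            mosaic.individuals[h1 // 2], h1 % 2,
                            mosaic.individuals[h2 // 2], h2 % 2,
                            mosaic.chrom_names[c], s, e, e - s,
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=["id_a", "hap_a", "id_b", "hap_b", "chrom", "start_cM", "end_cM", "length_cM"],
    )


def _intersect_mosaics(a, b, L: float) -> list:
    sa, ia = a
    sb, ib = b
    ea = np.append(sa[1:], L)
    eb = np.append(sb[1:], L)
    out = []
    i = j = 0
    while i < len(sa) and j < len(sb):
        if ia[i] == ib[j]:
            s, e = max(sa[i], sb[j]), min(ea[i], eb[j])
            if e > s:
                out.append([s, e])
        if ea[i] <= eb[j]:
            i += 1
        else:
            j += 1
    return out


def autozygosity(mosaic: AncestryMosaic, min_cM: float = 0.0) -> pd.Series:
    """Per-individual fraction of the genome where the two haplotypes are IBD."""
    pairs = [(2 * i, 2 * i + 1) for i in range(mosaic.n_ind)]
    seg = truth_ibd(mosaic, min_cM=min_cM, pairs=pairs)
    total = float(sum(mosaic.chrom_lengths_cM))
    out = pd.Series(0.0, index=mosaic.individuals)
    if len(seg):
        sums = seg.groupby("id_a")["length_cM"].sum()
        out.loc[sums.index] = sums / total
    return out


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def genotype_panel(
    mosaic: AncestryMosaic, config: SimConfig, rng: np.random.Generator | None = None
) -> HaplotypePanel:
    """Read alleles through the mosaics from founder haplotypes.

    Sites sit on a regular cM grid per chromosome; bp positions follow the
    fixed cM->bp factor implied by the chromosome spec.  Genotype errors flip
    single alleles; phase-switch errors swap an individual's two haplotypes
    from a site onward (state resets at each chromosome, as phasing would).
    """
    rng = rng if rng is not None else _stage_rng(config, 2)
    nh = len(mosaic.haps)
    chrom_names, bp_all, cm_all = [], [], []
    allele_cols = []
    for c, spec in enumerate(config.chromosomes):
        S = spec.n_sites
        cm = (np.arange(S) + 0.5) * spec.length_cM / S
        bp = np.minimum(
            (cm * (spec.length_bp / spec.length_cM)).astype(np.int64) + 1, spec.length_bp
        )
        freqs = config.maf_sampler(rng, S)
        founder = (rng.random((mosaic.n_founder_haps, S)) < freqs).astype(np.uint8)
        block = np.empty((nh, S), dtype=np.uint8)
        for h in range(nh):
            starts, ids = mosaic.haps[h][c]
            fid = ids[np.searchsorted(starts, cm, side="right") - 1]
            block[h] = founder[fid, np.arange(S)]
        allele_cols.append(block)
        chrom_names.append(np.full(S, f"chr{c + 1}"))
        bp_all.append(bp)
        cm_all.append(cm)

    alleles = np.concatenate(allele_cols, axis=1)
    site_chrom = np.concatenate(chrom_names)
    site_bp = np.concatenate(bp_all)
    site_cM = np.concatenate(cm_all)

    if config.genotype_error_rate > 0:
        flip = rng.random(alleles.shape) < config.genotype_error_rate
        alleles = np.where(flip, 1 - alleles, alleles).astype(np.uint8)
    if config.phase_switch_rate > 0:
        offset = 0
        for spec in config.chromosomes:
            S = spec.n_sites
            for i in range(nh // 2):
                sw = rng.random(S) < config.phase_switch_rate
                par = np.cumsum(sw) % 2 == 1
                if par.any():
                    a = alleles[2 * i, offset : offset + S].copy()
                    b = alleles[2 * i + 1, offset : offset + S]
                    alleles[2 * i, offset : offset + S] = np.where(par, b, a)
                    alleles[2 * i + 1, offset : offset + S] = np.where(par, a, b)
            offset += S

    n_sites = alleles.shape[1]
    ref = np.array([_ALLELE_PAIRS[k % len(_ALLELE_PAIRS)][0] for k in range(n_sites)])
    alt = np.array([_ALLELE_PAIRS[k % len(_ALLELE_PAIRS)][1] for k in range(n_sites)])
    return HaplotypePanel(
        alleles=alleles,
        site_chrom=site_chrom,
        site_bp=site_bp,
        site_cM=site_cM,
        individuals=list(mosaic.individuals),
        ref=ref,
        alt=alt,
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    config: SimConfig
    pedigree: Pedigree
    mosaic: AncestryMosaic  # sampled individuals only
    panel: HaplotypePanel
    labels: pd.Series  # individual id -> subpop label

    def truth_ibd(self, min_cM: float = 0.0, pairs=None) -> pd.DataFrame:
        return truth_ibd(self.mosaic, min_cM=min_cM, pairs=pairs)


def simulate(config: SimConfig) -> SimResult:
    """Pedigree -> transmission -> sampling -> genotypes, all from config.seed."""
    ped = simulate_pedigree(config)
    mosaic = transmit_haplotypes(ped, config)
    final_sub = ped.final.subpop
    samp = config.sample_size
    if samp is None:
        keep = np.arange(ped.final.n)
    else:
        per = np.full(config.n_subpops, samp, dtype=int) if np.isscalar(samp) else np.asarray(samp, dtype=int)
        rng = _stage_rng(config, 3)
        keep_parts = []
        for s in range(config.n_subpops):
            pool = np.nonzero(final_sub == s)[0]
            if per[s] > pool.size:
                raise ValueError(f"cannot sample {per[s]} from subpop {s} of size {pool.size}")
            keep_parts.append(np.sort(rng.choice(pool, per[s], replace=False)))
        keep = np.concatenate(keep_parts)
    mosaic = mosaic.subset(keep)
    panel = genotype_panel(mosaic, config)
    labels = pd.Series(
        [f"pop{final_sub[i]}" for i in keep], index=mosaic.individuals, name="subpop"
    )
    return SimResult(config, ped, mosaic, panel, labels)
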