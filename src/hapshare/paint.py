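"""PBWT-style chunk painting: coancestry matrices and their PCA.

Each recipient haplotype is tiled into chunks, attributing every site to the
donor haplotype carrying the longest identical interval covering that site
(ChromoPainter-like contract: chunkcounts = number of chunks, chunklengths =
their summed genetic length, both aggregated to the individual level).  Both
haplotypes of the recipient's own individual are excluded as donors.
Per-chromosome matrices are summed into genome totals, and each chunklengths
row conserves twice the total map length exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .panel import HaplotypePanel

logger = logging.getLogger(__name__)


@dataclass
class PaintConfig:
    chunks_per_region: int = 100  # stored for ChromoPainter compatibility; no c-factor rescaling
    tie_break: str = "seeded-random"  # or "split-equally"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chunks_per_region < 1:
            raise ValueError("chunks_per_region must be >= 1")
        if self.tie_break not in ("seeded-random", "split-equally"):
            raise ValueError(f"unknown tie_break {self.tie_break!r}")


@dataclass
class CoancestryMatrix:
    """N x N chunkcounts and chunklengths (cM); row = recipient, column = donor."""

    chunkcounts: pd.DataFrame
    chunklengths: pd.DataFrame
    total_map_length_cM: float

    def validate(self, rtol: float = 1e-6) -> None:
        for m in (self.chunkcounts, self.chunklengths):
            if not np.allclose(np.diag(m.values), 0.0):
                raise ValueError("coancestry diagonal must be zero")
            if (m.values < 0).any():
                raise ValueError("coancestry entries must be non-negative")
        rows = self.chunklengths.values.sum(axis=1)
        expect = 2.0 * self.total_map_length_cM
        if expect > 0 and not np.allclose(rows, expect, rtol=rtol):
            raise ValueError("chunklengths rows do not conserve 2 x map length")


def maximal_matches(panel: HaplotypePanel, target_hap: int) -> list:
    """Set-maximal matches of one haplotype against all other individuals.

    Returns ``(donor_hap, start_site, end_site_exclusive)`` tuples (global
    site indices): maximal identical intervals not strictly contained in a
    longer identical interval with any other donor.  The two haplotypes of
    the target's own individual are excluded.
    """
    if panel.n_hap < 4:
        raise ValueError("need >=2 other individuals")
    if not 0 <= target_hap < panel.n_hap:
        raise IndexError("target_hap out of range")
    own = target_hap // 2
    runs: list = []
    for chrom in panel.chromosomes():
        sl = panel.chrom_slice(chrom)
        block = panel.alleles[:, sl]
        tgt = block[target_hap]
        off = sl.start
        for h in range(panel.n_hap):
            if h // 2 == own:
                continue
            eq = block[h] == tgt
            k = 0
            S = eq.size
            while k < S:
                if eq[k]:
                    s = k
                    while k < S and eq[k]:
                        k += 1
                    runs.append((h, off + s, off + k))
                else:
                    k += 1
    return _set_maximal(runs)


def _set_maximal(runs: list) -> list:
    """Drop runs strictly contained in a longer run (with any donor).

    A run (s, e) survives iff no run starts no later and ends no earlier
    while being strictly longer; with runs sorted by (start asc, end desc)
    that reduces to: end equals its start-group's maximum and exceeds every
    earlier-starting run's end.
    """
    if not runs:
        return []
    order = sorted(runs, key=lambda r: (r[1], -r[2]))
    out = []
    max_end_before = -1
    i = 0
    n = len(order)
    while i < n:
        s = order[i][1]
        group_max_e = order[i][2]
        j = i
        while j < n and order[j][1] == s:
            h, _, e = order[j]
            if e == group_max_e and e > max_end_before:
                out.append((h, s, e))
            j += 1
        max_end_before = max(max_end_before, group_max_e)
        i = j
    return sorted(out)


def paint_panel(panel: HaplotypePanel, config: PaintConfig | None = None) -> CoancestryMatrix:
    """Paint every haplotype and aggregate chunk counts/lengths to individuals."""
    config = config or PaintConfig()
    if panel.has_missing():
        raise ValueError("painting requires a panel without missing alleles")
    if panel.n_hap < 4:
        raise ValueError("need >=2 other individuals")
    N = panel.n_ind
    counts = np.zeros((N, N))
    lengths = np.zeros((N, N))
    weights = panel.site_weights()
    for ci, chrom in enumerate(panel.chromosomes()):
        sl = panel.chrom_slice(chrom)
        if sl.stop - sl.start < 2:
            logger.warning("chromosome %s has <2 sites; skipped", chrom)
            continue
        block = np.ascontiguousarray(panel.alleles[:, sl])
        w = np.ascontiguousarray(weights[sl])
        if config.tie_break == "seeded-random":
            rkeys = _kernels.site_randoms(config.seed, ci, block.shape[1])
            _kernels.paint_chromosome(block, w, rkeys, counts, lengths)
        else:
            _kernels.paint_chromosome_split(block, w, counts, lengths)
    ids = panel.individuals
    return CoancestryMatrix(
        chunkcounts=pd.DataFrame(counts, index=ids, columns=ids),
        chunklengths=pd.DataFrame(lengths, index=ids, columns=ids),
        total_map_length_cM=panel.total_map_length_cM(),
    )


def coancestry_pca(matrix: CoancestryMatrix, k: int, which: str = "chunkcounts") -> pd.DataFrame:
    """PCA of the coancestry matrix: rows normalised to sum 1, columns
    centred, SVD; returns the first k left components scaled by singular
    values, sign-fixed so each component's largest-magnitude loading is
    positive."""
    X = getattr(matrix, which).values.astype(float)
    N = X.shape[0]
    if not 1 <= k <= N:
        raise ValueError("need N >= k >= 1")
    rs = X.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    X = X / rs
    X = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    coords = U[:, :k] * s[:k]
    for j in range(k):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            coords[:, j] = -coords[:, j]
    return pd.DataFrame(
        coords, index=getattr(matrix, which).index, columns=[f"PC{j + 1}" for j in range(k)]
    )
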