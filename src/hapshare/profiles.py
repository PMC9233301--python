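"""Between-cluster relationship statistics.

Copying vectors summarise where a cluster's haplotypes are painted from;
nnls sharing profiles (beta) express a target cluster's mean copying as a
non-negative mixture of the other clusters' profiles; total variation
distance compares copying vectors; Hudson's FST (ratio of averages over
sites) measures allele-frequency differentiation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _nnls

from .paint import CoancestryMatrix
from .panel import HaplotypePanel


def _chunklengths_frame(chunklengths) -> pd.DataFrame:
    if isinstance(chunklengths, CoancestryMatrix):
        return chunklengths.chunklengths
    return chunklengths


def cluster_donations(chunklengths, assignment: pd.Series) -> pd.DataFrame:
    """Per-individual chunklengths received, summed over donor clusters."""
    M = _chunklengths_frame(chunklengths)
    donors = M.columns.to_series().map(assignment)
    if donors.isna().any():
        raise ValueError("every individual must be assigned to a cluster")
    return M.T.groupby(donors).sum().T  # rows: recipients, cols: donor clusters


def copying_vectors(chunklengths, assignment: pd.Series) -> pd.DataFrame:
    """Per-cluster mean received-chunklengths profile over donor clusters,
    normalised to sum 1."""
    received = cluster_donations(chunklengths, assignment)
    groups = received.index.to_series().map(assignment)
    mean = received.groupby(groups).mean()
    if (assignment.value_counts() == 0).any() or mean.isna().any().any():
        raise ValueError("empty cluster")
    totals = mean.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("cluster with zero copying total")
    return mean.div(totals, axis=0)


def nnls_profile(chunklengths, assignment: pd.Series, target_cluster) -> pd.Series:
    """Sharing profile beta_g of a target cluster over all other clusters.

    X: donations from each source cluster to each target individual;
    Y: mean donations between source clusters (diagonal retained).  Solves
    min ||xbar - Y^T beta||^2, beta >= 0, then renormalises to sum 1.
    """
    received = cluster_donations(chunklengths, assignment)
    clusters = list(received.columns)
    if target_cluster not in clusters:
        raise KeyError(f"unknown cluster {target_cluster!r}")
    sources = [c for c in clusters if c != target_cluster]
    if not sources:
        raise ValueError("need >= 2 clusters")
    groups = received.index.to_series().map(assignment)
    in_target = groups == target_cluster
    X = received.loc[in_target, sources]
    if X.empty:
        raise ValueError("empty cluster")
    xbar = X.mean(axis=0).values
    Y = received.loc[~in_target].groupby(groups[~in_target]).mean().loc[sources, sources].values
    if not np.isfinite(Y).all() or np.allclose(Y, 0):
        raise ValueError("degenerate source system")
    beta, _ = _nnls(Y.T, xbar)
    total = beta.sum()
    if total <= 0:
        raise ValueError("degenerate source system")
    return pd.Series(beta / total, index=sources, name=str(target_cluster))


def tvd(a, b) -> float:
    """Total variation distance between two copying vectors: 0.5 * sum |a-b|."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    return 0.5 * float(np.abs(a - b).sum())


def tvd_matrix(vectors: pd.DataFrame) -> pd.DataFrame:
    labels = list(vectors.index)
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, li in enumerate(labels):
        for lj in labels[i + 1 :]:
            v = tvd(vectors.loc[li].values, vectors.loc[lj].values)
            out.loc[li, lj] = out.loc[lj, li] = v
    return out


def hudson_fst(panel_or_freqs, group_a, group_b) -> float:
    """Hudson's FST, ratio of averages over sites.

    Per site: numerator (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1),
    denominator p1(1-p2) + p2(1-p1); FST = sum(num)/sum(den).  Accepts a
    phased panel plus two lists of individual ids, or a tuple
    (p1, n1, p2, n2) of per-site frequencies and allele-copy counts.
    Sites monomorphic in both groups are skipped.
    """
    if isinstance(panel_or_freqs, HaplotypePanel):
        panel = panel_or_freqs
        idx = {v: i for i, v in enumerate(panel.individuals)}

        def freqs(group):
            rows = []
            for g in group:
                rows += [2 * idx[g], 2 * idx[g] + 1]
            al = panel.alleles[rows]
            if (al == 255).any():
                al = np.ma.masked_equal(al, 255)
                n = al.count(axis=0).astype(float)
                p = al.mean(axis=0).filled(np.nan)
            else:
                n = np.full(al.shape[1], float(len(rows)))
                p = al.mean(axis=0)
            return np.asarray(p, dtype=float), n

        p1, n1 = freqs(group_a)
        p2, n2 = freqs(group_b)
    else:
        p1, n1, p2, n2 = (np.atleast_1d(np.asarray(x, dtype=float)) for x in panel_or_freqs)
    if np.any(n1 <= 1) or np.any(n2 <= 1):
        raise ValueError("need >= 2 allele copies per group per site")
    poly = ~(((p1 == 0) & (p2 == 0)) | ((p1 == 1) & (p2 == 1)))
    p1, n1, p2, n2 = p1[poly], n1[poly], p2[poly], n2[poly]
    if p1.size == 0:
        raise ValueError("no polymorphic sites")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.sum() / den.sum())


def fst_matrix(panel: HaplotypePanel, assignment: pd.Series) -> pd.DataFrame:
    labels = sorted(assignment.unique())
    members = {c: list(assignment.index[assignment == c]) for c in labels}
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, li in enumerate(labels):
        for lj in labels[i + 1 :]:
            v = hudson_fst(panel, members[li], members[lj])
            out.loc[li, lj] = out.loc[lj, li] = v
    return out
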