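"""IBD segment detection, gap merging and within-cluster sharing summaries.

Detection is exact haplotype matching: every maximal pairwise identical
interval of genetic length >= ``min_cM`` is reported via a PBWT long-match
scan (linear in panel size).  Genotype and phase-switch errors split true
segments; ``merge_ibd`` rejoins adjacent segments across short, nearly
concordant gaps (gap < 0.6 cM containing at most one discordant site, the
refinedIBD merge convention, applied here at the haplotype level).

Segments are carried as a DataFrame with one row per segment: id_a, hap_a,
id_b, hap_b (pair canonicalised, a < b), chrom, start/end bp, cM and site
coordinates, and length_cM = cM(last site) - cM(first site).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import _kernels
from .panel import HaplotypePanel

SEGMENT_COLUMNS = [
    "id_a", "hap_a", "id_b", "hap_b", "chrom",
    "start_bp", "end_bp", "start_cM", "end_cM", "length_cM",
    "start_site", "end_site",
]


def _min_sites_for(cm: np.ndarray, min_cM: float) -> int | None:
    """Smallest site count that any interval spanning >= min_cM must contain.

    None when no window of the chromosome spans min_cM (nothing detectable).
    """
    j = np.searchsorted(cm, cm + min_cM, side="left")
    valid = j < cm.size
    if not valid.any():
        return None
    return int(np.min(j[valid] - np.nonzero(valid)[0] + 1))


def detect_ibd(panel: HaplotypePanel, min_cM: float = 1.0) -> pd.DataFrame:
    """All maximal identical haplotype intervals >= min_cM between individuals."""
    if panel.has_missing():
        raise ValueError("IBD detection requires a panel without missing alleles")
    if min_cM <= 0:
        raise ValueError("min_cM must be positive")
    rows = []
    for chrom in panel.chromosomes():
        sl = panel.chrom_slice(chrom)
        cm = panel.site_cM[sl]
        if np.any(np.diff(cm) < 0):
            raise ValueError(f"unsorted cM positions on chromosome {chrom}")
        T = _min_sites_for(cm, min_cM)
        if T is None:
            continue
        block = np.ascontiguousarray(panel.alleles[:, sl].T)
        hits = _kernels.pbwt_long_matches(block, max(T, 2))
        if hits.size == 0:
            continue
        st, en = hits[:, 2], hits[:, 3]
        span = cm[en - 1] - cm[st]
        cross = (hits[:, 0] // 2) != (hits[:, 1] // 2)
        keep = (span >= min_cM) & cross
        bp = panel.site_bp[sl]
        for h1, h2, s, e in hits[keep]:
            rows.append(
                (
                    panel.individuals[h1 // 2], int(h1 % 2),
                    panel.individuals[h2 // 2], int(h2 % 2),
                    chrom,
                    int(bp[s]), int(bp[e - 1]),
                    float(cm[s]), float(cm[e - 1]), float(cm[e - 1] - cm[s]),
                    int(sl.start + s), int(sl.start + e),
                )
            )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def merge_ibd(
    segments: pd.DataFrame,
    panel: HaplotypePanel,
    max_gap_cM: float = 0.6,
    max_discordant: int = 1,
) -> pd.DataFrame:
    """Merge adjacent same-pair, same-phase segments across small gaps.

    Two consecutive segments merge when the intervening gap is < max_gap_cM
    and contains at most ``max_discordant`` sites where the two haplotypes
    carry different alleles; merging proceeds transitively left to right.
    """
    if segments.empty:
        return segments.copy()
    hap_index = {ind: i for i, ind in enumerate(panel.individuals)}
    out = []
    for (id_a, hap_a, id_b, hap_b, chrom), grp in segments.groupby(
        ["id_a", "hap_a", "id_b", "hap_b", "chrom"], sort=False
    ):
        grp = grp.sort_values("start_site")
        ha = 2 * hap_index[id_a] + hap_a
        hb = 2 * hap_index[id_b] + hap_b
        aa = panel.alleles[ha]
        ab = panel.alleles[hb]
        cur = grp.iloc[0].to_dict()
        for _, nxt in grp.iloc[1:].iterrows():
            g0, g1 = int(cur["end_site"]), int(nxt["start_site"])  # gap sites [g0, g1)
            gap_cm = panel.site_cM[g1] - panel.site_cM[g0 - 1]
            discordant = int(np.count_nonzero(aa[g0:g1] != ab[g0:g1]))
            if g1 >= g0 and gap_cm < max_gap_cM and discordant <= max_discordant:
                cur["end_site"] = int(nxt["end_site"])
                cur["end_bp"] = int(nxt["end_bp"])
                cur["end_cM"] = float(nxt["end_cM"])
                cur["length_cM"] = float(cur["end_cM"] - cur["start_cM"])
            else:
                out.append(cur)
                cur = nxt.to_dict()
        out.append(cur)
    return pd.DataFrame(out, columns=SEGMENT_COLUMNS).reset_index(drop=True)


def sharing_summary(segments: pd.DataFrame, assignment: pd.Series) -> pd.DataFrame:
    """Per-individual mean IBD sharing with same-cluster partners.

    For each individual, over all other members of its cluster: the mean of
    per-partner total segment cM and the mean of per-partner segment counts
    (partners sharing nothing contribute zeros).  Individuals in singleton
    clusters get NaN means.
    """
    ids = assignment.index
    totals = pd.DataFrame(0.0, index=ids, columns=["sum_cM", "n_seg"])
    if len(segments):
        seg = segments[segments["id_a"] != segments["id_b"]]
        same = seg["id_a"].map(assignment).values == seg["id_b"].map(assignment).values
        seg = seg[same]
        for col in ("id_a", "id_b"):
            g = seg.groupby(col)["length_cM"].agg(["sum", "size"])
            totals.loc[g.index, "sum_cM"] += g["sum"].values
            totals.loc[g.index, "n_seg"] += g["size"].values
    sizes = assignment.map(assignment.value_counts())
    denom = (sizes - 1).astype(float)
    denom[denom <= 0] = np.nan
    return pd.DataFrame(
        {
            "cluster": assignment,
            "mean_total_cM": totals["sum_cM"] / denom,
            "mean_n_segments": totals["n_seg"] / denom,
        }
    )


def segment_overlap_stats(
    detected: pd.DataFrame,
    truth: pd.DataFrame,
    min_detected_cM: float = 2.0,
    min_truth_cM: float = 2.0,
) -> tuple:
    """Length-weighted precision and recall of detected segments vs a truth set.

    Precision: fraction of detected length (segments >= min_detected_cM)
    overlapping truth of any length; recall: fraction of truth length
    (segments >= min_truth_cM) overlapping detections of any length.  Both
    frames use the (id_a, hap_a, id_b, hap_b, chrom) key with cM intervals.
    """

    def grouped(df, min_len):
        out: dict = {}
        for r in df.itertuples():
            if r.length_cM >= min_len:
                out.setdefault((r.id_a, r.hap_a, r.id_b, r.hap_b, r.chrom), []).append(
                    (r.start_cM, r.end_cM)
                )
        return out

    def overlap_len(num: dict, den: dict) -> tuple:
        total = ov = 0.0
        for key, ivals in num.items():
            total += sum(e - s for s, e in ivals)
            other = den.get(key)
            if not other:
                continue
            for s, e in ivals:
                for s2, e2 in other:
                    ov += max(0.0, min(e, e2) - max(s, s2))
        return ov, total

    det_all = grouped(detected, 0.0)
    det_min = {k: [iv for iv in v if iv[1] - iv[0] >= min_detected_cM] for k, v in det_all.items()}
    det_min = {k: v for k, v in det_min.items() if v}
    truth_all = grouped(truth, 0.0)
    truth_min = {k: [iv for iv in v if iv[1] - iv[0] >= min_truth_cM] for k, v in truth_all.items()}
    truth_min = {k: v for k, v in truth_min.items() if v}
    ov_p, len_d = overlap_len(det_min, truth_all)
    ov_r, len_t = overlap_len(truth_min, det_all)
    precision = ov_p / len_d if len_d else float("nan")
    recall = ov_r / len_t if len_t else float("nan")
    return precision, recall


def rank_test(values_a, values_b) -> tuple:
    """Mann-Whitney U with two-sided p: exact when m*n <= 200 and tie-free,
    normal approximation with tie correction otherwise."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size * b.size <= 200 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
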