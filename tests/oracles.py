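"""Independent brute-force oracles used by the test suite.

These re-derive expected results directly from the published rules (greedy
longest-covering-match painting with the seeded splitmix64 tie-break, maximal
identical runs, the PLINK-style ROH window rules) without touching the
package's kernels.
"""

import numpy as np

M64 = (1 << 64) - 1


def sm64(x: int) -> int:
    z = (x + 0x9E3779B97F4A7C15) & M64
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & M64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & M64
    return z ^ (z >> 31)


def site_weights(cm):
    cm = np.asarray(cm, dtype=float)
    S = cm.size
    if S == 1:
        return np.zeros(1)
    lo = np.empty(S)
    hi = np.empty(S)
    lo[0] = cm[0]
    lo[1:] = (cm[1:] + cm[:-1]) / 2
    hi[:-1] = lo[1:]
    hi[-1] = cm[-1]
    return hi - lo


def _cover_len(a, h, t, k):
    S = a.shape[1]
    if a[h, k] != a[t, k]:
        return 0
    s = k
    while s > 0 and a[h, s - 1] == a[t, s - 1]:
        s -= 1
    e = k + 1
    while e < S and a[h, e] == a[t, e]:
        e += 1
    return e - s


def oracle_paint(alleles_by_chrom, cms, seed):
    """Greedy site-by-site painting: longest covering match per site, seeded
    tie rule, chunk accumulation to individual-level count/length matrices."""
    H = alleles_by_chrom[0].shape[0]
    N = H // 2
    counts = np.zeros((N, N))
    lengths = np.zeros((N, N))
    for ci, (a, cm) in enumerate(zip(alleles_by_chrom, cms)):
        S = a.shape[1]
        base = sm64((seed + ci * 0x632BE59BD9B4E019) & M64)
        r = [sm64((base + k) & M64) for k in range(S)]
        w = site_weights(cm)
        for t in range(H):
            it = t // 2
            donor = np.full(S, -1)
            for k in range(S):
                best_len, best_h, best_key = 0, -1, -1
                for h in range(H):
                    if h // 2 == it:
                        continue
                    ln = _cover_len(a, h, t, k)
                    if ln == 0:
                        continue
                    key = sm64((r[k] + h * 0x9E3779B97F4A7C15) & M64)
                    if ln > best_len or (ln == best_len and key > best_key):
                        best_len, best_h, best_key = ln, h, key
                donor[k] = best_h
            last = -1
            for k in range(S):
                if donor[k] == -1:
                    donor[k] = last
                else:
                    last = donor[k]
            nxt = -1
            for k in range(S - 1, -1, -1):
                if donor[k] == -1:
                    donor[k] = nxt
                else:
                    nxt = donor[k]
            if donor[0] == -1:
                continue
            cur, acc = donor[0], w[0]
            for k in range(1, S):
                if donor[k] == cur:
                    acc += w[k]
                else:
                    counts[it, cur // 2] += 1
                    lengths[it, cur // 2] += acc
                    cur, acc = donor[k], w[k]
            counts[it, cur // 2] += 1
            lengths[it, cur // 2] += acc
    return counts, lengths


def brute_identity_runs(a, cm, min_cM):
    """All maximal pairwise identical runs of genetic span >= min_cM."""
    H, S = a.shape
    out = set()
    for x in range(H):
        for y in range(x + 1, H):
            k = 0
            while k < S:
                if a[x, k] == a[y, k]:
                    s = k
                    while k < S and a[x, k] == a[y, k]:
                        k += 1
                    if cm[k - 1] - cm[s] >= min_cM:
                        out.add((x, y, s, k))
                else:
                    k += 1
    return out


def brute_roh(gt, bp, p):
    """Direct application of the ROH window/run rules for one individual."""
    S = gt.size
    W = p.window_snp
    if S < W:
        return []
    passing = []
    for w in range(S - W + 1):
        win = gt[w : w + W]
        passing.append(
            int(np.sum(win == 1) <= p.window_het_max and np.sum(win < 0) <= p.window_missing_max)
        )
    candidate = np.zeros(S, dtype=bool)
    for k in range(S):
        wins = [w for w in range(max(0, k - W + 1), min(S - W, k) + 1)]
        hits = sum(passing[w] for w in wins)
        candidate[k] = hits / len(wins) >= p.window_hit_threshold
    rois = []
    i = 0
    while i < S:
        if not candidate[i]:
            i += 1
            continue
        j = i
        while j + 1 < S and candidate[j + 1]:
            j += 1
        s = i
        for t in range(i + 1, j + 1):
            if (bp[t] - bp[t - 1]) / 1000.0 > p.max_gap_kb:
                rois.append((s, t - 1))
                s = t
        rois.append((s, j))
        i = j + 1
    out = []
    for s, e in rois:
        n_snp = e - s + 1
        kb = (bp[e] - bp[s]) / 1000.0
        if n_snp >= p.min_snp and kb >= p.min_kb and kb / n_snp <= p.min_density_kb_per_snp:
            out.append((s, e))
    return out


def random_panel_blocks(rng, max_ind=5, max_sites=200, n_chrom_max=2):
    """Random small multi-chromosome panels for property tests."""
    n_ind = int(rng.integers(2, max_ind + 1))
    H = 2 * n_ind
    blocks, cms = [], []
    for _ in range(int(rng.integers(1, n_chrom_max + 1))):
        S = int(rng.integers(5, max_sites + 1))
        blocks.append(rng.integers(0, 2, (H, S)).astype(np.uint8))
        cms.append(np.sort(rng.uniform(0, 50, S)))
    return n_ind, blocks, cms
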