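"""Numba kernels: chunk painting and PBWT long-match scanning.

Hot loops over the H x S allele matrix live here.  Both kernels define their
behaviour purely in terms of the panel contents plus a seed, so the pure
Python brute-force oracles used in the tests can reproduce them exactly.

Tie-break rule (seeded-random painting): each site ``k`` of chromosome ``c``
owns a 64-bit value ``r_k = splitmix64(splitmix64(seed + c*C1) + k)``; a
donor haplotype ``h`` competing at that site has key
``splitmix64(r_k + h*C2)`` and the largest key wins among donors whose
covering match is longest.  C1 = 0x632BE59BD9B4E019, C2 = 0x9E3779B97F4A7C15.
"""

from __future__ import annotations

import numba
import numpy as np
from numba import njit

_C1 = np.uint64(0x632BE59BD9B4E019)
_C2 = np.uint64(0x9E3779B97F4A7C15)


@njit(numba.uint64(numba.uint64), cache=False, inline="always")
def _splitmix64(x):
    z = x + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


_M64 = (1 << 64) - 1


def splitmix64_py(x: int) -> int:
    """Reference splitmix64 (pure Python, used for per-site tie values)."""
    z = (x + 0x9E3779B97F4A7C15) & _M64
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _M64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _M64
    return z ^ (z >> 31)


def site_randoms(seed: int, chrom_index: int, n_sites: int) -> np.ndarray:
    """Per-site 64-bit values feeding the donor tie-break."""
    base = splitmix64_py((int(seed) + int(chrom_index) * int(_C1)) & _M64)
    out = np.empty(n_sites, dtype=np.uint64)
    for k in range(n_sites):
        out[k] = splitmix64_py((base + k) & _M64)
    return out


@njit(cache=False)
def paint_chromosome(alleles, w, rkeys, counts, lengths):
    """Seeded-random painting of one chromosome.

    For every recipient haplotype, each site is attributed to the donor
    haplotype (not of the recipient's own individual) whose identical
    interval covering that site is longest, ties broken by the seeded key;
    maximal same-donor runs form chunks.  ``counts``/``lengths`` are N x N
    recipient-individual x donor-individual accumulators updated in place.
    """
    H, S = alleles.shape
    best_len = np.zeros(S, np.int64)
    best_hap = np.empty(S, np.int64)
    best_key = np.zeros(S, np.uint64)
    for t in range(H):
        it = t // 2
        for k in range(S):
            best_len[k] = 0
            best_hap[k] = -1
        for h in range(H):
            if h // 2 == it:
                continue
            hk = np.uint64(h) * _C2
            k = 0
            while k < S:
                if alleles[h, k] == alleles[t, k]:
                    s = k
                    while k < S and alleles[h, k] == alleles[t, k]:
                        k += 1
                    ln = k - s
                    for j in range(s, k):
                        if ln > best_len[j]:
                            best_len[j] = ln
                            best_hap[j] = h
                            best_key[j] = _splitmix64(rkeys[j] + hk)
                        elif ln == best_len[j]:
                            kk = _splitmix64(rkeys[j] + hk)
                            if kk > best_key[j]:
                                best_hap[j] = h
                                best_key[j] = kk
                else:
                    k += 1
        # sites where no donor carries the recipient's allele inherit the
        # neighbouring chunk's donor (previous if any, else next)
        last = np.int64(-1)
        for k in range(S):
            if best_hap[k] == -1:
                best_hap[k] = last
            else:
                last = best_hap[k]
        nxt = np.int64(-1)
        for k in range(S - 1, -1, -1):
            if best_hap[k] == -1:
                best_hap[k] = nxt
            else:
                nxt = best_hap[k]
        if best_hap[0] == -1:
            continue  # no donor matched anywhere on this chromosome
        cur = best_hap[0]
        acc = w[0]
        for k in range(1, S):
            if best_hap[k] == cur:
                acc += w[k]
            else:
                counts[it, cur // 2] += 1.0
                lengths[it, cur // 2] += acc
                cur = best_hap[k]
                acc = w[k]
        counts[it, cur // 2] += 1.0
        lengths[it, cur // 2] += acc


@njit(cache=False)
def paint_chromosome_split(alleles, w, counts, lengths):
    """Split-equally painting: tied longest donors share each site's weight;
    a donor's maximal tied run contributes 1/m chunks, m = tie multiplicity
    at the run's first site."""
    H, S = alleles.shape
    best_len = np.zeros(S, np.int64)
    ncand = np.zeros(S, np.float64)
    for t in range(H):
        it = t // 2
        for k in range(S):
            best_len[k] = 0
            ncand[k] = 0.0
        for h in range(H):  # pass 1: longest covering match per site
            if h // 2 == it:
                continue
            k = 0
            while k < S:
                if alleles[h, k] == alleles[t, k]:
                    s = k
                    while k < S and alleles[h, k] == alleles[t, k]:
                        k += 1
                    ln = k - s
                    for j in range(s, k):
                        if ln > best_len[j]:
                            best_len[j] = ln
                else:
                    k += 1
        for h in range(H):  # pass 2: tie multiplicities
            if h // 2 == it:
                continue
            k = 0
            while k < S:
                if alleles[h, k] == alleles[t, k]:
                    s = k
                    while k < S and alleles[h, k] == alleles[t, k]:
                        k += 1
                    ln = k - s
                    for j in range(s, k):
                        if ln == best_len[j]:
                            ncand[j] += 1.0
                else:
                    k += 1
        for h in range(H):  # pass 3: accumulate
            if h // 2 == it:
                continue
            ih = h // 2
            k = 0
            while k < S:
                if alleles[h, k] == alleles[t, k]:
                    s = k
                    while k < S and alleles[h, k] == alleles[t, k]:
                        k += 1
                    ln = k - s
                    j = s
                    while j < k:
                        if ln == best_len[j]:
                            j0 = j
                            while j < k and ln == best_len[j]:
                                lengths[it, ih] += w[j] / ncand[j]
                                j += 1
                            counts[it, ih] += 1.0 / ncand[j0]
                        else:
                            j += 1
                else:
                    k += 1


@njit(cache=False)
def pbwt_long_matches(alleles_T, min_sites):
    """All maximal pairwise matches of >= min_sites sites on one chromosome.

    ``alleles_T`` is site-major (S x H).  Positional prefix (a) and
    divergence (d) arrays are carried across sites; a match is reported once,
    at the site where the two haplotypes' alleles diverge (or at the end of
    the chromosome), with its exact maximal span.  Returns an (n, 4) int64
    array of (hap_lo, hap_hi, start_site, end_site_exclusive).
    """
    S, H = alleles_T.shape
    a = np.arange(H, dtype=np.int64)
    d = np.zeros(H, dtype=np.int64)
    a0 = np.empty(H, dtype=np.int64)
    a1 = np.empty(H, dtype=np.int64)
    d0 = np.empty(H, dtype=np.int64)
    d1 = np.empty(H, dtype=np.int64)
    cap = 1024
    out = np.empty((cap, 4), dtype=np.int64)
    n_out = 0
    for k in range(S + 1):
        if k >= min_sites:
            i = 0
            while i < H:
                j = i + 1
                while j < H and d[j] <= k - min_sites:
                    j += 1
                if j - i >= 2:
                    for x in range(i, j):
                        hx = a[x]
                        for y in range(x + 1, j):
                            hy = a[y]
                            if k < S and alleles_T[k, hx] == alleles_T[k, hy]:
                                continue  # match keeps extending
                            st = k - min_sites
                            while st > 0 and alleles_T[st - 1, hx] == alleles_T[st - 1, hy]:
                                st -= 1
                            if n_out == cap:
                                cap *= 2
                                grown = np.empty((cap, 4), dtype=np.int64)
                                grown[:n_out] = out
                                out = grown
                            lo, hi = (hx, hy) if hx < hy else (hy, hx)
                            out[n_out, 0] = lo
                            out[n_out, 1] = hi
                            out[n_out, 2] = st
                            out[n_out, 3] = k
                            n_out += 1
                i = j
        if k == S:
            break
        # PBWT extension with column k
        u = 0
        v = 0
        p = k + 1
        q = k + 1
        for i in range(H):
            h = a[i]
            di = d[i]
            if di > p:
                p = di
            if di > q:
                q = di
            if alleles_T[k, h] == 0:
                a0[u] = h
                d0[u] = p
                u += 1
                p = 0
            else:
                a1[v] = h
                d1[v] = q
                v += 1
                q = 0
        a[:u] = a0[:u]
        a[u:] = a1[:v]
        d[:u] = d0[:u]
        d[u:] = d1[:v]
    return out[:n_out]
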