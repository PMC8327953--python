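"""Numba kernels for pairwise IBS tract accumulation.

Two computation strategies are provided:

``pair_run_sums``
    The literal definition: for every unordered haplotype pair, the maximal
    run of consecutive identical-by-state sites containing each test site is
    accumulated.  Exact, used as the default and as the reference for the
    brute-force oracle tests.

``ehh_sums_xp`` / ``ehh_sums_nsl``
    The haplotype-homozygosity formulation used by the reference scan tools:
    the mean pairwise tract length at a core site equals the sum over
    extension distances of the fraction of pairs identical throughout the
    extended interval.  This form admits the two standard truncations —
    stop once homozygosity decays below a cutoff, and cap the extension at a
    maximum number of sites from the core — which bound tract lengths the
    same way the reference implementation does.

Both agree exactly when the cutoff and cap are disabled.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def pair_run_sums(H, max_extend):
    """Accumulate IBS run lengths over all haplotype pairs.

    Parameters
    ----------
    H : (n, S) uint8 array
    max_extend : int
        Cap on the extension (in sites) either side of the core; <= 0
        disables the cap.

    Returns
    -------
    (sum_ibs, sum_derived) : float64 arrays of length S
        ``sum_ibs[k]`` is the sum over all pairs of the run length at k
        (0 for pairs differing at k); ``sum_derived[k]`` restricts the sum
        to pairs in which both haplotypes carry allele 1 at k.
    """
    n, S = H.shape
    sum_ibs = np.zeros(S, dtype=np.float64)
    sum_der = np.zeros(S, dtype=np.float64)
    for i in range(n):
        for j in range(i + 1, n):
            prev = -1
            for k in range(S + 1):
                if k == S or H[i, k] != H[j, k]:
                    # sites prev+1 .. k-1 form one maximal IBS run
                    run = k - prev - 1
                    if run > 0:
                        for t in range(prev + 1, k):
                            if max_extend > 0:
                                lo = prev + 1
                                hi = k - 1
                                if t - max_extend > lo:
                                    lo = t - max_extend
                                if t + max_extend < hi:
                                    hi = t + max_extend
                                length = hi - lo + 1
                            else:
                                length = run
                            sum_ibs[t] += length
                            if H[i, t] == 1:
                                sum_der[t] += length
                    prev = k
    return sum_ibs, sum_der


@njit(cache=True)
def _refine(cls, alleles, remap):
    """Split haplotype identity classes by the alleles at one more site."""
    n = cls.shape[0]
    for i in range(remap.shape[0]):
        remap[i] = -1
    nxt = 0
    for h in range(n):
        key = cls[h] * 2 + alleles[h]
        if remap[key] == -1:
            remap[key] = nxt
            nxt += 1
        cls[h] = remap[key]
    return nxt


@njit(cache=True)
def ehh_sums_xp(H1, H2, cutoff, max_extend):
    """Mean-tract sums for both populations, homozygosity formulation.

    Extension from each core site proceeds independently to the left and
    right.  A step's contribution is the fraction of within-population pairs
    identical throughout the interval (the core site itself is the first
    step).  Extension stops when the *pooled* homozygosity falls below
    ``cutoff`` (that step still excluded), when ``max_extend`` sites from
    the core are reached, or at the matrix edge.  ``cutoff <= 0`` and
    ``max_extend <= 0`` disable the respective truncations, in which case
    the returned per-pair means equal ``pair_run_sums`` on each population
    divided by that population's pair count.
    """
    n1 = H1.shape[0]
    n2 = H2.shape[0]
    S = H1.shape[1]
    n = n1 + n2
    pairs1 = n1 * (n1 - 1) / 2.0
    pairs2 = n2 * (n2 - 1) / 2.0
    pairs_pool = n * (n - 1) / 2.0
    sl1 = np.zeros(S, dtype=np.float64)
    sl2 = np.zeros(S, dtype=np.float64)
    H = np.empty((n, S), dtype=np.uint8)
    H[:n1] = H1
    H[n1:] = H2
    cls = np.empty(n, dtype=np.int64)
    remap = np.empty(4 * n + 4, dtype=np.int64)
    size_all = np.empty(n, dtype=np.int64)
    size_p1 = np.empty(n, dtype=np.int64)
    for k in range(S):
        for side in range(2):
            # both directions condition on the core-site allele split, so
            # pairs differing at the core contribute nothing on either side
            for h in range(n):
                cls[h] = H[h, k]
            d = 0 if side == 0 else 1
            while True:
                site = k + d if side == 0 else k - d
                if site < 0 or site >= S:
                    break
                ncls = _refine(cls, H[:, site], remap)
                for c in range(ncls):
                    size_all[c] = 0
                    size_p1[c] = 0
                for h in range(n):
                    size_all[cls[h]] += 1
                    if h < n1:
                        size_p1[cls[h]] += 1
                e1 = 0.0
                e2 = 0.0
                ep = 0.0
                for c in range(ncls):
                    a = size_p1[c]
                    b = size_all[c] - a
                    sz = size_all[c]
                    e1 += a * (a - 1) / 2.0
                    e2 += b * (b - 1) / 2.0
                    ep += sz * (sz - 1) / 2.0
                if cutoff > 0.0 and ep / pairs_pool < cutoff:
                    break
                sl1[k] += e1 / pairs1
                sl2[k] += e2 / pairs2
                d += 1
                if max_extend > 0 and d > max_extend:
                    break
    return sl1, sl2


@njit(cache=True)
def ehh_sums_nsl(H, cutoff, max_extend):
    """Within-population mean-tract sums split by core allele.

    For each core site the haplotypes are partitioned into carriers of the
    0 (ancestral) and 1 (derived) allele; each partition's homozygosity is
    summed outward with its own cutoff.  Returns ``(sl_anc, sl_der)``:
    mean pairwise tract lengths per class, NaN where a class has fewer
    than two haplotypes.
    """
    n, S = H.shape
    sl_a = np.full(S, np.nan)
    sl_d = np.full(S, np.nan)
    cls = np.empty(n, dtype=np.int64)
    remap = np.empty(4 * n + 4, dtype=np.int64)
    sizes = np.empty(n, dtype=np.int64)
    members = np.empty(n, dtype=np.int64)
    buf = np.empty(n, dtype=np.uint8)
    for k in range(S):
        for allele in range(2):
            m = 0
            for h in range(n):
                if H[h, k] == allele:
                    members[m] = h
                    m += 1
            if m < 2:
                continue
            pairs = m * (m - 1) / 2.0
            total = 0.0
            for side in range(2):
                for i in range(m):
                    cls[i] = 0
                d = 0 if side == 0 else 1
                while True:
                    site = k + d if side == 0 else k - d
                    if site < 0 or site >= S:
                        break
                    for i in range(m):
                        buf[i] = H[members[i], site]
                    ncls = _refine(cls[:m], buf[:m], remap)
                    for c in range(ncls):
                        sizes[c] = 0
                    for i in range(m):
                        sizes[cls[i]] += 1
                    e = 0.0
                    for c in range(ncls):
                        e += sizes[c] * (sizes[c] - 1) / 2.0
                    e /= pairs
                    if cutoff > 0.0 and e < cutoff:
                        break
                    total += e
                    d += 1
                    if max_extend > 0 and d > max_extend:
                        break
            if allele == 0:
                sl_a[k] = total
            else:
                sl_d[k] = total
    return sl_a, sl_d
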