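"""Independent brute-force reference implementations for oracle tests.

Deliberately naive: per-site, per-pair left/right scans with explicit loops.
Kept free of any code shared with the package kernels.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def tract_length(hap_i, hap_j, k0: int, max_extend: int | None = None) -> int:
    """IBS run containing 0-based site k0 (0 if the pair differs there)."""
    S = len(hap_i)
    if hap_i[k0] != hap_j[k0]:
        return 0
    left = k0
    while left > 0 and hap_i[left - 1] == hap_j[left - 1]:
        left -= 1
    right = k0
    while right < S - 1 and hap_i[right + 1] == hap_j[right + 1]:
        right += 1
    if max_extend is not None:
        left = max(left, k0 - max_extend)
        right = min(right, k0 + max_extend)
    return right - left + 1


def sl_mean(H, members, k0, max_extend=None) -> float:
    pairs = list(itertools.combinations(members, 2))
    if not pairs:
        return math.nan
    return sum(tract_length(H[i], H[j], k0, max_extend) for i, j in pairs) / len(pairs)


def xpnsl_brute(H1, H2, max_extend=None):
    """Per-site (sl1, sl2, raw) for two haplotype matrices."""
    S = H1.shape[1]
    sl1 = np.empty(S)
    sl2 = np.empty(S)
    raw = np.empty(S)
    for k in range(S):
        sl1[k] = sl_mean(H1, range(H1.shape[0]), k, max_extend)
        sl2[k] = sl_mean(H2, range(H2.shape[0]), k, max_extend)
        raw[k] = (
            math.log(sl1[k] / sl2[k]) if sl1[k] > 0 and sl2[k] > 0 else math.nan
        )
    return sl1, sl2, raw


def nsl_brute(H, max_extend=None):
    """Per-site (sl_anc, sl_der, raw) within one matrix."""
    n, S = H.shape
    sl_a = np.empty(S)
    sl_d = np.empty(S)
    raw = np.empty(S)
    for k in range(S):
        anc = [h for h in range(n) if H[h, k] == 0]
        der = [h for h in range(n) if H[h, k] == 1]
        sl_a[k] = sl_mean(H, anc, k, max_extend) if len(anc) >= 2 else math.nan
        sl_d[k] = sl_mean(H, der, k, max_extend) if len(der) >= 2 else math.nan
        ok = (
            len(anc) >= 2 and len(der) >= 2
            and sl_a[k] > 0 and sl_d[k] > 0
        )
        raw[k] = math.log(sl_a[k] / sl_d[k]) if ok else math.nan
    return sl_a, sl_d, raw


def random_matrix(rng, max_haps=8, max_sites=30, min_haps=2, min_sites=1):
    n = rng.integers(min_haps, max_haps + 1)
    S = rng.integers(min_sites, max_sites + 1)
    return rng.integers(0, 2, size=(n, S)).astype(np.uint8)
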