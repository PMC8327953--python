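"""Raw nSL and XP-nSL score computation.

Both statistics summarise haplotype diversity around a test site k through
the mean pairwise identical-by-state (IBS) tract length: for haplotypes i, j
let ``L_ij(k)`` be the number of consecutive sites at which i and j are IBS
in the maximal interval containing k (counted including k; 0 if they differ
at k).  With ``SL(k)`` the mean of ``L_ij(k)`` over all unordered pairs in a
haplotype set,

* nSL(k)    = ln( SL_A(k) / SL_D(k) ), comparing carriers of the ancestral
  (A) and derived (D) allele within one population, and
* XP-nSL(k) = ln( SL_P1(k) / SL_P2(k) ), comparing two populations on a
  shared site list.

Positive XP-nSL indicates longer haplotype homozygosity tracts (a candidate
sweep) in population 1.  Distances are measured in numbers of segregating
sites, so no recombination map is needed.

Scores are returned as a "score table" DataFrame with one row per site and
columns ``chrom, pos, freq_pop1, sl1, freq_pop2, sl2, raw`` (for nSL the
frequency columns both hold the derived-allele frequency and sl1/sl2 hold
SL_A/SL_D).  Undefined scores are NaN and are ignored downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import _kernels
from .hapio import HaplotypeMatrix

SCORE_COLUMNS = ["chrom", "pos", "freq_pop1", "sl1", "freq_pop2", "sl2", "raw"]


def ibs_tract_length(hap_i: np.ndarray, hap_j: np.ndarray, k: int) -> int:
    """Length of the maximal IBS run containing site ``k`` (1-based).

    Returns 0 when the haplotypes differ at k; runs truncate at the ends of
    the haplotypes with no penalty.
    """
    hap_i = np.asarray(hap_i)
    hap_j = np.asarray(hap_j)
    if hap_i.shape != hap_j.shape:
        raise ValueError("haplotypes must have equal length")
    S = hap_i.shape[0]
    if not 1 <= k <= S:
        raise ValueError(f"site index {k} outside 1..{S}")
    idx = k - 1
    if hap_i[idx] != hap_j[idx]:
        return 0
    left = idx
    while left > 0 and hap_i[left - 1] == hap_j[left - 1]:
        left -= 1
    right = idx
    while right < S - 1 and hap_i[right + 1] == hap_j[right + 1]:
        right += 1
    return right - left + 1


def _check_truncation(ehh_cutoff: float | None, max_extend: int | None):
    cutoff = 0.0 if ehh_cutoff is None else float(ehh_cutoff)
    cap = 0 if max_extend is None else int(max_extend)
    if cutoff < 0 or cutoff >= 1:
        raise ValueError("ehh_cutoff must be in [0, 1)")
    if cap < 0:
        raise ValueError("max_extend must be >= 0")
    return cutoff, cap


def xpnsl_raw(
    pop1: HaplotypeMatrix,
    pop2: HaplotypeMatrix,
    ehh_cutoff: float | None = None,
    max_extend: int | None = None,
    min_maf_core: float = 0.0,
) -> pd.DataFrame:
    """Raw XP-nSL scores for every shared site of two populations.

    Parameters
    ----------
    pop1, pop2
        Haplotype matrices with identical site lists; population 1 is the
        putatively selected population (positive scores).
    ehh_cutoff
        If set, stop the tract extension once the pooled haplotype
        homozygosity decays below this fraction (the reference scan tool
        uses 0.05).  None computes the untruncated definition.
    max_extend
        If set, cap the extension at this many sites either side of the
        core (the reference tool uses 100).  None means no cap.
    min_maf_core
        Leave ``raw`` undefined (NaN) at core sites whose minor allele
        frequency is below this threshold in *both* populations.  All sites
        still contribute to tract lengths.

    Notes
    -----
    ``sl1``/``sl2`` are mean pairwise tract lengths in sites; ``raw`` is
    their natural log-ratio, NaN where either mean is zero (possible only
    for two-haplotype populations).  Swapping the populations negates every
    defined score.
    """
    if not np.array_equal(pop1.positions, pop2.positions):
        raise ValueError("population matrices must share the same site list")
    if pop1.chrom != pop2.chrom:
        raise ValueError("population matrices must be on the same chromosome")
    if pop1.n_haplotypes < 2 or pop2.n_haplotypes < 2:
        raise ValueError("each population needs at least 2 haplotypes")
    cutoff, cap = _check_truncation(ehh_cutoff, max_extend)

    n1, n2 = pop1.n_haplotypes, pop2.n_haplotypes
    if cutoff > 0.0:
        sl1, sl2 = _kernels.ehh_sums_xp(pop1.alleles, pop2.alleles, cutoff, cap)
    else:
        s1, _ = _kernels.pair_run_sums(pop1.alleles, cap)
        s2, _ = _kernels.pair_run_sums(pop2.alleles, cap)
        sl1 = s1 / (n1 * (n1 - 1) / 2.0)
        sl2 = s2 / (n2 * (n2 - 1) / 2.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where((sl1 > 0) & (sl2 > 0), np.log(sl1 / sl2), np.nan)
    f1 = pop1.derived_freq()
    f2 = pop2.derived_freq()
    if min_maf_core > 0:
        low = (np.minimum(f1, 1 - f1) < min_maf_core) & (
            np.minimum(f2, 1 - f2) < min_maf_core
        )
        raw = np.where(low, np.nan, raw)
    return pd.DataFrame(
        {
            "chrom": pop1.chrom,
            "pos": pop1.positions,
            "freq_pop1": f1,
            "sl1": sl1,
            "freq_pop2": f2,
            "sl2": sl2,
            "raw": raw,
        }
    )


def nsl_raw(
    pop: HaplotypeMatrix,
    ehh_cutoff: float | None = None,
    max_extend: int | None = None,
    min_maf_core: float = 0.0,
) -> pd.DataFrame:
    """Raw nSL scores within one population (allele 0 = ancestral).

    ``raw`` is NaN wherever either carrier class has fewer than two
    haplotypes (monomorphic sites, singletons) or the core minor allele
    frequency is below ``min_maf_core``.
    """
    if pop.n_haplotypes < 2:
        raise ValueError("need at least 2 haplotypes")
    cutoff, cap = _check_truncation(ehh_cutoff, max_extend)
    n = pop.n_haplotypes
    freq = pop.derived_freq()
    n_der = pop.alleles.sum(axis=0).astype(np.int64)
    n_anc = n - n_der

    if cutoff > 0.0:
        sl_a, sl_d = _kernels.ehh_sums_nsl(pop.alleles, cutoff, cap)
    else:
        s_all, s_der = _kernels.pair_run_sums(pop.alleles, cap)
        s_anc = s_all - s_der
        with np.errstate(divide="ignore", invalid="ignore"):
            sl_a = np.where(n_anc >= 2, s_anc / (n_anc * (n_anc - 1) / 2.0), np.nan)
            sl_d = np.where(n_der >= 2, s_der / (n_der * (n_der - 1) / 2.0), np.nan)

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(
            (n_anc >= 2) & (n_der >= 2) & (sl_a > 0) & (sl_d > 0),
            np.log(sl_a / sl_d),
            np.nan,
        )
    if min_maf_core > 0:
        raw = np.where(np.minimum(freq, 1 - freq) < min_maf_core, np.nan, raw)
    return pd.DataFrame(
        {
            "chrom": pop.chrom,
            "pos": pop.positions,
            "freq_pop1": freq,
            "sl1": sl_a,
            "freq_pop2": freq,
            "sl2": sl_d,
            "raw": raw,
        }
    )


def write_scores(table: pd.DataFrame, path) -> None:
    """Write a score table as TSV (NaN rendered as ``nan``)."""
    table.to_csv(path, sep="\t", index=False, na_rep="nan")


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["nan"])
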