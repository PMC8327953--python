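"""Window-based outlier detection, region merging and gene annotation.

Because consecutive scores are correlated through linkage disequilibrium, a
true sweep produces a *cluster* of extreme scores rather than one outlier.
The scan therefore tiles each chromosome with fixed-width windows (100 kb in
the reference analysis), computes per-window summaries of the normalized
scores, and flags the top fraction of windows with the highest proportion of
extreme scores.  Windows with few sites are noisier, so windows are first
stratified into site-count quantile bins and the threshold is taken within
each bin.  Flagged windows that are genomically adjacent are merged into
candidate regions; genes are assigned the maximum score of any window they
overlap; and a permutation test checks whether the number of distinct genes
hit by the flagged regions is unusual.

All coordinates are 1-based inclusive.  Windows tile from coordinate 1, so
window i covers ``[(i-1)*winsize + 1, i*winsize]``; a trailing partial
window is kept and subject to the same site-count filter as any other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

WINDOW_COLUMNS = [
    "chrom", "start", "end", "n_sites", "frac_extreme", "max_score",
    "bin_id", "flagged",
]


def window_summaries(
    table: pd.DataFrame, winsize: int, two_tailed: bool = False
) -> pd.DataFrame:
    """Summarize normalized scores in non-overlapping fixed-width windows.

    Every window from coordinate 1 up to the last scored site of each
    chromosome is emitted, including empty ones (``n_sites = 0``,
    ``frac_extreme = 0``, ``max_score = NaN``).  ``frac_extreme`` is the
    fraction of defined scores flagged ``crit == +1`` (``|crit| == 1``
    when *two_tailed*); ``max_score`` is the maximum normalized score.
    """
    if winsize <= 0:
        raise ValueError("winsize must be positive")
    if "norm" not in table.columns:
        raise ValueError("table must be normalized first (missing 'norm' column)")
    rows = []
    for chrom, sub in table.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(dtype=np.int64)
        norm = sub["norm"].to_numpy(dtype=float)
        crit = sub["crit"].to_numpy(dtype=np.int64)
        ok = np.isfinite(norm)
        n_win = int(np.ceil(pos.max() / winsize)) if len(pos) else 0
        widx = (pos - 1) // winsize
        for w in range(n_win):
            in_w = ok & (widx == w)
            n = int(in_w.sum())
            if n:
                hits = (crit[in_w] != 0) if two_tailed else (crit[in_w] == 1)
                frac = hits.mean()
                mx = norm[in_w].max()
            else:
                frac, mx = 0.0, np.nan
            rows.append((chrom, w * winsize + 1, (w + 1) * winsize, n, frac, mx))
    out = pd.DataFrame(rows, columns=WINDOW_COLUMNS[:6])
    out["bin_id"] = -1
    out["flagged"] = False
    return out


@dataclass
class BinThresholds:
    """Site-count quantile bins and per-bin extreme-fraction thresholds."""

    bins: pd.DataFrame  # bin_id, n_windows, min_sites, max_sites, threshold
    min_snps: int
    top_frac: float

    def assign_bin(self, n_sites: np.ndarray) -> np.ndarray:
        """Bin index by site count (clamped to the fitted range); -1 where
        the window fails the site-count filter."""
        n_sites = np.atleast_1d(np.asarray(n_sites, dtype=np.int64))
        uppers = self.bins["max_sites"].to_numpy()
        idx = np.searchsorted(uppers, n_sites, side="left")
        idx = np.minimum(idx, len(uppers) - 1)
        idx[n_sites <= self.min_snps] = -1
        return idx

    def detect(self, n_sites: np.ndarray, frac_extreme: np.ndarray) -> np.ndarray:
        """Top-window test for windows summarised elsewhere (e.g. sweep
        replicates judged against neutral thresholds)."""
        frac_extreme = np.atleast_1d(np.asarray(frac_extreme, dtype=float))
        idx = self.assign_bin(n_sites)
        thr = np.full(len(idx), np.inf)
        valid = idx >= 0
        thr[valid] = self.bins["threshold"].to_numpy()[idx[valid]]
        return frac_extreme > thr


def flag_top_windows(
    windows: pd.DataFrame,
    qbins: int = 10,
    min_snps: int = 10,
    top_frac: float = 0.01,
) -> tuple[pd.DataFrame, BinThresholds]:
    """Flag the top windows by extreme-score fraction within site-count bins.

    Windows with ``n_sites <= min_snps`` are excluded (the site filter is
    exclusive: "more than min_snps sites").  Eligible windows are ranked by
    site count (ties broken by genomic order) and divided into ``qbins``
    near-equal-occupancy bins; within each bin, windows whose
    ``frac_extreme`` lies strictly above the ``1 - top_frac`` quantile are
    flagged.  Returns the window table with ``bin_id``/``flagged`` filled
    plus the per-bin boundaries and thresholds.
    """
    if qbins < 1:
        raise ValueError("qbins must be >= 1")
    out = windows.copy().reset_index(drop=True)
    out["bin_id"] = -1
    out["flagged"] = False
    elig = np.flatnonzero(out["n_sites"].to_numpy() > min_snps)
    if len(elig) < qbins:
        raise ValueError(
            f"only {len(elig)} windows pass the site filter; need >= {qbins}"
        )
    order = elig[np.argsort(out["n_sites"].to_numpy()[elig], kind="stable")]
    ranks = np.arange(len(order))
    bin_ids = (ranks * qbins) // len(order)
    out.loc[order, "bin_id"] = bin_ids

    recs = []
    frac = out["frac_extreme"].to_numpy(dtype=float)
    nsit = out["n_sites"].to_numpy()
    for b in range(qbins):
        members = order[bin_ids == b]
        thr = np.quantile(frac[members], 1.0 - top_frac)
        hit = members[frac[members] > thr]
        out.loc[hit, "flagged"] = True
        recs.append(
            (b, len(members), int(nsit[members].min()), int(nsit[members].max()),
             float(thr))
        )
    bins = pd.DataFrame(
        recs, columns=["bin_id", "n_windows", "min_sites", "max_sites", "threshold"]
    )
    return out, BinThresholds(bins=bins, min_snps=min_snps, top_frac=top_frac)


def concatenate_adjacent(windows: pd.DataFrame) -> pd.DataFrame:
    """Merge runs of genomically adjacent flagged windows into regions.

    Returns one row per region: ``chrom, start, end, n_windows, max_score``
    where ``max_score`` is the maximum window max-score within the merged
    span.  Regions are disjoint and each contains at least one flagged
    window.
    """
    flagged = windows[windows["flagged"]].sort_values(["chrom", "start"])
    regions = []
    for chrom, sub in flagged.groupby("chrom", sort=False):
        start = None
        prev_end = None
        members: list[float] = []
        count = 0
        for _, row in sub.iterrows():
            if start is None:
                start, prev_end, members, count = row["start"], row["end"], [row["max_score"]], 1
            elif row["start"] == prev_end + 1:
                prev_end = row["end"]
                members.append(row["max_score"])
                count += 1
            else:
                regions.append((chrom, start, prev_end, count, np.nanmax(members)))
                start, prev_end, members, count = row["start"], row["end"], [row["max_score"]], 1
        if start is not None:
            regions.append((chrom, start, prev_end, count, np.nanmax(members)))
    return pd.DataFrame(
        regions, columns=["chrom", "start", "end", "n_windows", "max_score"]
    )


def top_window_report(
    windows: pd.DataFrame, regions: pd.DataFrame, top_n: int = 10
) -> pd.DataFrame:
    """Per-flagged-window report in the style of a "top regions" table.

    Each flagged window is listed with its extreme-score fraction, the
    number of flanking flagged windows merged with it, and the span and
    max score of its concatenated region; sorted by ``frac_extreme``.
    """
    flagged = windows[windows["flagged"]].copy()
    rows = []
    for _, w in flagged.iterrows():
        reg = regions[
            (regions["chrom"] == w["chrom"])
            & (regions["start"] <= w["start"])
            & (regions["end"] >= w["end"])
        ].iloc[0]
        rows.append(
            (
                w["chrom"], w["start"], w["end"], w["frac_extreme"],
                int(reg["n_windows"] - 1),
                reg["start"], reg["end"], reg["max_score"],
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "frac_extreme", "n_flanking",
            "region_start", "region_end", "region_max_score",
        ],
    )
    return out.sort_values("frac_extreme", ascending=False).head(top_n).reset_index(drop=True)


# ---------------------------------------------------------------------------
# gene annotation

def read_bed(path) -> pd.DataFrame:
    """Gene intervals from BED (0-based half-open -> 1-based inclusive)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "id"], usecols=[0, 1, 2, 3],
        dtype={"chrom": str},
    )
    out = pd.DataFrame(
        {
            "id": df["id"].astype(str),
            "chrom": df["chrom"],
            "start": df["start"].astype(np.int64) + 1,
            "end": df["end"].astype(np.int64),
        }
    )
    _validate_genes(out)
    return out


def read_gff3(path, feature_type: str = "gene") -> pd.DataFrame:
    """Gene intervals from GFF3 (already 1-based inclusive)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != feature_type:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID") or attrs.get("Name") or f"{f[0]}:{f[3]}-{f[4]}"
            rows.append((gid, f[0], int(f[3]), int(f[4])))
    out = pd.DataFrame(rows, columns=["id", "chrom", "start", "end"])
    _validate_genes(out)
    return out


def _validate_genes(genes: pd.DataFrame) -> None:
    if np.any(genes["start"].to_numpy() > genes["end"].to_numpy()):
        bad = genes[genes["start"] > genes["end"]].iloc[0]
        raise ValueError(f"gene {bad['id']} has start > end")


def gene_max_scores(windows: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Assign each gene the best window max-score among windows it overlaps.

    Overlap means any shared base pair (1-based inclusive intervals).  Genes
    overlapping only windows without a defined max score are omitted.
    """
    out_ids = []
    out_scores = []
    for chrom, gsub in genes.groupby("chrom", sort=False):
        wsub = windows[windows["chrom"] == chrom].sort_values("start")
        if wsub.empty:
            continue
        wstart = wsub["start"].to_numpy()
        wend = wsub["end"].to_numpy()
        wmax = wsub["max_score"].to_numpy(dtype=float)
        for _, g in gsub.iterrows():
            lo = np.searchsorted(wend, g["start"], side="left")
            hi = np.searchsorted(wstart, g["end"], side="right")
            if lo >= hi:
                continue
            scores = wmax[lo:hi]
            scores = scores[np.isfinite(scores)]
            if len(scores):
                out_ids.append(g["id"])
                out_scores.append(scores.max())
    return pd.DataFrame({"id": out_ids, "max_score": out_scores})


def permutation_gene_count(
    n_regions: int,
    region_size: int,
    genome: dict[str, int],
    genes: pd.DataFrame,
    n_reps: int,
    observed: int,
    seed: int,
) -> tuple[float, np.ndarray]:
    """Permutation test for the number of distinct genes hit by regions.

    Each replicate drops ``n_regions`` non-overlapping intervals of
    ``region_size`` bp uniformly across the genome (chromosome chosen
    proportional to length) and counts the unique genes overlapping any
    interval.  Returns ``(p, counts)`` with
    ``p = #{replicates with count <= observed} / n_reps`` — the one-sided
    probability of seeing so *few* genes by chance.
    """
    chroms = [c for c in genome if genome[c] >= region_size]
    if not chroms:
        raise ValueError("no chromosome can hold a region of this size")
    capacity = sum(genome[c] // region_size for c in chroms)
    if capacity < n_regions:
        raise ValueError(
            f"genome too small for {n_regions} non-overlapping regions"
        )
    lengths = np.array([genome[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    rng = np.random.default_rng(seed)

    by_chrom = {}
    for i, c in enumerate(chroms):
        sub = genes[genes["chrom"] == c]
        order = np.argsort(sub["start"].to_numpy())
        by_chrom[i] = (
            sub["start"].to_numpy()[order],
            sub["end"].to_numpy()[order],
            sub["id"].to_numpy()[order],
        )

    counts = np.empty(n_reps, dtype=np.int64)
    for rep in range(n_reps):
        placed: dict[int, list[tuple[int, int]]] = {}
        attempts = 0
        k = 0
        while k < n_regions:
            attempts += 1
            if attempts > 1000 * n_regions:
                raise RuntimeError("could not place non-overlapping regions")
            ci = rng.choice(len(chroms), p=probs)
            start = int(rng.integers(1, genome[chroms[ci]] - region_size + 2))
            end = start + region_size - 1
            ok = all(
                not (start <= e and end >= s) for s, e in placed.get(ci, [])
            )
            if not ok:
                continue
            placed.setdefault(ci, []).append((start, end))
            k += 1
        hit: set = set()
        for ci, ivals in placed.items():
            gstart, gend, gid = by_chrom[ci]
            if not len(gid):
                continue
            ivals.sort()
            rstart = np.array([s for s, _ in ivals])
            rend = np.array([e for _, e in ivals])
            idx = np.searchsorted(rstart, gend, side="right") - 1
            valid = idx >= 0
            overlap = np.zeros(len(gid), dtype=bool)
            overlap[valid] = rend[idx[valid]] >= gstart[valid]
            hit.update(gid[overlap])
        counts[rep] = len(hit)
    p = float(np.sum(counts <= observed)) / n_reps
    return p, counts
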