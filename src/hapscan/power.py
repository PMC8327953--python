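"""Calibration and power evaluation on simulated replicates.

Reproduces the simulation study that calibrates the cross-population scan:

* the neutral distribution of the maximum normalized score in the central
  window of each replicate, whose 99th percentile ("neutral99") is the
  max-score detection threshold;
* max-score power: the fraction of sweep replicates whose central-window
  maximum exceeds neutral99;
* window-based power: the fraction of sweep replicates whose central
  window exceeds the top-1% extreme-fraction threshold of the matching
  neutral site-count bin;
* false-positive rates: the same detection rules applied back to neutral
  replicates, optionally normalized against a mismatched demographic
  history.

Two interfaces are provided: table-level functions operating on normalized
score tables, and a streaming "batch" layer that keeps only per-replicate
sufficient statistics (pooled score moments plus the central-window raw
scores), which allows one set of simulations to be re-normalized under
several baselines without storing full tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .hapio import HaplotypeMatrix
from .normalize import NormStats
from .simulate import DemographicModel, SimConfig, SweepParams, simulate_neutral, simulate_sweep
from .winscan import BinThresholds, flag_top_windows
from .xpnsl import xpnsl_raw


@dataclass
class PowerResult:
    """Detection rate for one parameter cell and method."""

    cell: str
    method: str  # "max-score" or "window"
    power: float
    n_replicates: int
    threshold: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.power <= 1:
            raise ValueError("power must be in [0, 1]")


def central_window(length: int, winsize: int) -> tuple[int, int]:
    """The winsize-bp window centred on the segment midpoint (1-based)."""
    half = length // 2
    return half - winsize // 2 + 1, half + winsize // 2


def _central_max(table: pd.DataFrame, length: int, winsize: int) -> float:
    lo, hi = central_window(length, winsize)
    pos = table["pos"].to_numpy()
    norm = table["norm"].to_numpy(dtype=float)
    sel = (pos >= lo) & (pos <= hi) & np.isfinite(norm)
    return float(norm[sel].max()) if sel.any() else np.nan


def neutral_max_distribution(
    tables: Iterable[pd.DataFrame], length: int, winsize: int = 100_000
) -> dict:
    """Quantiles of the per-replicate central-window maximum score.

    Replicates without any defined score in the central window are skipped
    with a warning.  Returns median, the central 95% interval, the 99th
    percentile (the "neutral99" threshold) and the raw maxima.
    """
    maxima = []
    skipped = 0
    for t in tables:
        m = _central_max(t, length, winsize)
        if np.isnan(m):
            skipped += 1
        else:
            maxima.append(m)
    if skipped:
        warnings.warn(f"skipped {skipped} replicates with empty central window")
    maxima = np.asarray(maxima)
    q = np.quantile(maxima, [0.5, 0.025, 0.975, 0.99])
    return {
        "median": q[0], "q025": q[1], "q975": q[2], "q99": q[3],
        "n": len(maxima), "maxima": maxima,
    }


def power_max_score(
    tables: Iterable[pd.DataFrame],
    threshold: float,
    length: int,
    winsize: int = 100_000,
    cell: str = "",
) -> PowerResult:
    """Fraction of replicates whose central-window max exceeds *threshold*."""
    maxima = np.array([_central_max(t, length, winsize) for t in tables])
    detected = np.nansum(maxima > threshold)
    return PowerResult(
        cell=cell, method="max-score", power=float(detected) / len(maxima),
        n_replicates=len(maxima), threshold=threshold,
    )


def central_window_table(
    tables: Iterable[pd.DataFrame], length: int, winsize: int = 100_000
) -> pd.DataFrame:
    """One window-table row per replicate: its central window summary."""
    lo, hi = central_window(length, winsize)
    rows = []
    for i, t in enumerate(tables):
        pos = t["pos"].to_numpy()
        norm = t["norm"].to_numpy(dtype=float)
        crit = t["crit"].to_numpy()
        sel = (pos >= lo) & (pos <= hi) & np.isfinite(norm)
        n = int(sel.sum())
        frac = float((crit[sel] == 1).mean()) if n else 0.0
        mx = float(norm[sel].max()) if n else np.nan
        rows.append((f"rep{i}", lo, hi, n, frac, mx))
    out = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_sites", "frac_extreme", "max_score"]
    )
    out["bin_id"] = -1
    out["flagged"] = False
    return out


def power_window(
    sweep_tables: Iterable[pd.DataFrame],
    thresholds: BinThresholds,
    length: int,
    winsize: int = 100_000,
    cell: str = "",
) -> PowerResult:
    """Window-method power against thresholds fitted on neutral windows.

    A replicate is detected when its central window passes the site-count
    filter and its extreme-score fraction lies strictly above the threshold
    of the neutral bin matching its site count.  Central windows failing
    the site filter count as undetected.
    """
    wins = central_window_table(sweep_tables, length, winsize)
    hits = thresholds.detect(
        wins["n_sites"].to_numpy(), wins["frac_extreme"].to_numpy()
    )
    return PowerResult(
        cell=cell, method="window", power=float(hits.mean()),
        n_replicates=len(wins),
    )


def fpr_estimate(
    neutral_tables: Iterable[pd.DataFrame],
    method: str,
    length: int,
    winsize: int = 100_000,
    threshold: float | None = None,
    thresholds: BinThresholds | None = None,
    qbins: int = 10,
    min_snps: int = 10,
    top_frac: float = 0.01,
    cell: str = "neutral",
) -> PowerResult:
    """Proportion of neutral replicates identified as under selection.

    ``method="max"`` uses the neutral99-style threshold; ``method="window"``
    uses per-bin extreme-fraction thresholds.  If no thresholds are given
    for the window method they are fitted on these replicates themselves
    (the self-consistent construction that pins the rate near *top_frac*).
    """
    tables = list(neutral_tables)
    if method == "max":
        if threshold is None:
            raise ValueError("max method needs a threshold")
        res = power_max_score(tables, threshold, length, winsize, cell=cell)
        return PowerResult(cell, "max-score", res.power, res.n_replicates, threshold)
    if method != "window":
        raise ValueError("method must be 'max' or 'window'")
    wins = central_window_table(tables, length, winsize)
    if thresholds is None:
        flagged, thresholds = flag_top_windows(wins, qbins, min_snps, top_frac)
        rate = float(flagged["flagged"].mean())
    else:
        hits = thresholds.detect(
            wins["n_sites"].to_numpy(), wins["frac_extreme"].to_numpy()
        )
        rate = float(hits.mean())
    return PowerResult(cell, "window", rate, len(wins))


# ---------------------------------------------------------------------------
# streaming batch layer

@dataclass
class ScoreOpts:
    """Scan-statistic options for the simulation study.

    Defaults mirror the reference scan tool's settings: stop tract
    extension when pooled haplotype homozygosity decays below 0.05, cap the
    extension at 100 sites either side of the core, and leave scores
    undefined at cores below 5% minor allele frequency in both populations.
    """

    ehh_cutoff: float | None = 0.05
    max_extend: int | None = 100
    min_maf_core: float = 0.05
    crit_threshold: float = 2.0


@dataclass
class ReplicateScores:
    """Sufficient statistics of one scored replicate."""

    raw_central: np.ndarray  # defined raw scores in the central window
    n: int                   # defined raw scores genome-wide
    total: float
    total_sq: float


def score_replicate(
    pair: tuple[HaplotypeMatrix, HaplotypeMatrix],
    length: int,
    winsize: int = 100_000,
    opts: ScoreOpts = ScoreOpts(),
) -> ReplicateScores:
    table = xpnsl_raw(
        pair[0], pair[1],
        ehh_cutoff=opts.ehh_cutoff,
        max_extend=opts.max_extend,
        min_maf_core=opts.min_maf_core,
    )
    raw = table["raw"].to_numpy(dtype=float)
    pos = table["pos"].to_numpy()
    ok = np.isfinite(raw)
    lo, hi = central_window(length, winsize)
    cen = ok & (pos >= lo) & (pos <= hi)
    return ReplicateScores(
        raw_central=raw[cen],
        n=int(ok.sum()),
        total=float(raw[ok].sum()),
        total_sq=float((raw[ok] ** 2).sum()),
    )


def batch_neutral(
    model: DemographicModel | Callable[[int], DemographicModel],
    cfg: SimConfig,
    n_reps: int,
    seed: int,
    winsize: int = 100_000,
    opts: ScoreOpts = ScoreOpts(),
) -> list[ReplicateScores]:
    """Simulate and score neutral replicates (replicate i uses seed+i).

    *model* may be a callable mapping the replicate seed to a model, for
    per-replicate randomized histories.
    """
    out = []
    for i in range(n_reps):
        m = model(seed + i) if callable(model) else model
        pair = simulate_neutral(m, cfg, seed + i)
        out.append(score_replicate(pair, cfg.length, winsize, opts))
    return out


def batch_sweep(
    model: DemographicModel,
    cfg: SimConfig,
    params: SweepParams,
    n_reps: int,
    seed: int,
    winsize: int = 100_000,
    opts: ScoreOpts = ScoreOpts(),
) -> list[ReplicateScores]:
    out = []
    for i in range(n_reps):
        pair = simulate_sweep(model, cfg, params, seed + i)
        out.append(score_replicate(pair, cfg.length, winsize, opts))
    return out


def baseline_from_batch(
    batch: Sequence[ReplicateScores], source: str = "neutral-sims"
) -> NormStats:
    """Pooled genome-wide mean/sd over a batch of scored replicates."""
    n = sum(b.n for b in batch)
    total = sum(b.total for b in batch)
    total_sq = sum(b.total_sq for b in batch)
    return NormStats.from_moments(n, total, total_sq, source=source)


def central_summaries(
    batch: Sequence[ReplicateScores],
    stats: NormStats,
    length: int,
    winsize: int = 100_000,
    crit_threshold: float = 2.0,
) -> pd.DataFrame:
    """Central-window table of a batch normalized under a given baseline."""
    lo, hi = central_window(length, winsize)
    m, sd = stats.mean[0], stats.sd[0]
    rows = []
    for i, b in enumerate(batch):
        norm = (b.raw_central - m) / sd
        n = len(norm)
        frac = float((norm > crit_threshold).mean()) if n else 0.0
        mx = float(norm.max()) if n else np.nan
        rows.append((f"rep{i}", lo, hi, n, frac, mx))
    out = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_sites", "frac_extreme", "max_score"]
    )
    out["bin_id"] = -1
    out["flagged"] = False
    return out
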