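"""Score normalization against a neutral or empirical baseline.

Raw log-ratio scores have an arbitrary location and scale that depend on
the joint demography of the two populations, so they are standardized
("normalized") before any thresholding: subtract the baseline mean and
divide by the baseline standard deviation.  The baseline is either the
genome-wide empirical score distribution or scores computed on neutral
coalescent simulations of a matching demographic history.

Cross-population scores use a single genome-wide baseline; within-population
(nSL-style) scores are standardized within derived-allele-frequency bins
because their raw distribution shifts with frequency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd


@dataclass
class NormStats:
    """Baseline means/standard deviations, optionally per frequency bin.

    ``bin_edges`` is None for a single genome-wide bin; otherwise it holds
    ``n_bins + 1`` equal-width edges on [0, 1] and ``mean``/``sd`` have one
    entry per bin.  Standard deviations use the n denominator.
    """

    mean: np.ndarray
    sd: np.ndarray
    bin_edges: np.ndarray | None = None
    n_scores: int = 0
    source: str = "empirical"

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.sd = np.atleast_1d(np.asarray(self.sd, dtype=float))
        if self.bin_edges is not None:
            self.bin_edges = np.asarray(self.bin_edges, dtype=float)
            if len(self.mean) != len(self.bin_edges) - 1:
                raise ValueError("one mean/sd required per frequency bin")
        elif len(self.mean) != 1:
            raise ValueError("unbinned stats must have exactly one mean/sd")
        if np.any(self.sd <= 0):
            raise ValueError("standard deviation must be positive in every bin")

    @property
    def n_bins(self) -> int:
        return len(self.mean)

    def bin_of(self, freq: np.ndarray) -> np.ndarray:
        """Bin index for each frequency (clipping 1.0 into the top bin)."""
        if self.bin_edges is None:
            return np.zeros(len(freq), dtype=np.int64)
        freq = np.asarray(freq, dtype=float)
        if np.any((freq < 0) | (freq > 1) | ~np.isfinite(freq)):
            bad = freq[(freq < 0) | (freq > 1) | ~np.isfinite(freq)][0]
            raise ValueError(f"site frequency {bad} outside all bins")
        nb = self.n_bins
        return np.minimum((freq * nb).astype(np.int64), nb - 1)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "bin_edges": None if self.bin_edges is None else self.bin_edges.tolist(),
            "n_scores": int(self.n_scores),
            "source": self.source,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormStats":
        d = json.loads(Path(path).read_text())
        edges = None if d["bin_edges"] is None else np.asarray(d["bin_edges"])
        return cls(
            mean=np.asarray(d["mean"]),
            sd=np.asarray(d["sd"]),
            bin_edges=edges,
            n_scores=d.get("n_scores", 0),
            source=d.get("source", "empirical"),
        )

    @classmethod
    def from_moments(
        cls, n: int, total: float, total_sq: float, source: str = "empirical"
    ) -> "NormStats":
        """Single-bin stats from streaming moments (n-denominator sd)."""
        if n < 2:
            raise ValueError("need at least 2 scores")
        mean = total / n
        var = total_sq / n - mean * mean
        if var <= 0:
            raise ValueError("zero variance in baseline scores")
        return cls(mean=np.array([mean]), sd=np.array([np.sqrt(var)]),
                   n_scores=n, source=source)


def fit_baseline(
    tables: pd.DataFrame | Iterable[pd.DataFrame],
    n_freq_bins: int | None = None,
    source: str = "empirical",
) -> NormStats:
    """Fit baseline mean/sd from the defined raw scores of score tables.

    Scores from all tables are pooled (normalization is genome-wide, not
    per chromosome or per replicate).  With ``n_freq_bins``, sites are
    binned by the ``freq_pop1`` column (derived-allele frequency for nSL
    tables) into equal-width bins; every bin must contain at least two
    defined scores with positive variance.
    """
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    raws = []
    freqs = []
    for t in tables:
        ok = np.isfinite(t["raw"].to_numpy(dtype=float))
        raws.append(t["raw"].to_numpy(dtype=float)[ok])
        freqs.append(t["freq_pop1"].to_numpy(dtype=float)[ok])
    raw = np.concatenate(raws) if raws else np.empty(0)
    freq = np.concatenate(freqs) if freqs else np.empty(0)

    if n_freq_bins is None:
        if len(raw) < 2:
            raise ValueError("need at least 2 defined raw scores")
        sd = raw.std()
        if sd == 0:
            raise ValueError("zero variance in baseline scores")
        return NormStats(mean=np.array([raw.mean()]), sd=np.array([sd]),
                         n_scores=len(raw), source=source)

    edges = np.linspace(0.0, 1.0, n_freq_bins + 1)
    idx = np.minimum((freq * n_freq_bins).astype(np.int64), n_freq_bins - 1)
    means = np.empty(n_freq_bins)
    sds = np.empty(n_freq_bins)
    for b in range(n_freq_bins):
        vals = raw[idx == b]
        if len(vals) < 2:
            raise ValueError(f"fewer than 2 defined scores in frequency bin {b}")
        means[b] = vals.mean()
        sds[b] = vals.std()
        if sds[b] == 0:
            raise ValueError(f"zero variance in frequency bin {b}")
    return NormStats(mean=means, sd=sds, bin_edges=edges,
                     n_scores=len(raw), source=source)


def apply_normalization(
    table: pd.DataFrame, stats: NormStats, crit_threshold: float = 2.0
) -> pd.DataFrame:
    """Standardize a score table and flag extreme scores.

    Appends ``norm = (raw - mean) / sd`` (per frequency bin when the stats
    are binned) and ``crit`` (+1 above ``crit_threshold``, -1 below its
    negative, 0 otherwise; undefined scores stay NaN with crit 0).
    """
    out = table.copy()
    raw = out["raw"].to_numpy(dtype=float)
    ok = np.isfinite(raw)
    idx = np.zeros(len(out), dtype=np.int64)
    if stats.bin_edges is not None:
        idx[ok] = stats.bin_of(out["freq_pop1"].to_numpy(dtype=float)[ok])
    norm = np.full(len(out), np.nan)
    norm[ok] = (raw[ok] - stats.mean[idx[ok]]) / stats.sd[idx[ok]]
    crit = np.zeros(len(out), dtype=np.int64)
    crit[ok & (norm > crit_threshold)] = 1
    crit[ok & (norm < -crit_threshold)] = -1
    out["norm"] = norm
    out["crit"] = crit
    return out
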