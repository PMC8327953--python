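"""Two-population coalescent simulation of neutral and sweep replicates.

The demographic model is a clean two-population divergence: an ancestral
population of diploid size N5 splits T3 generations ago into population 1
(the putatively locally adapted population, constant size N1) and
population 2, whose size changes from N4 to N3 at T2 and to the present-day
N2 at T1 (all times in generations before present; no migration after the
split).  Defaults reproduce the rhesus-macaque high/low-altitude divergence
model used to calibrate the scan: 500-kb segments, mu = 2.5e-8 and
r = 5.126e-9 per bp per generation, 46 + 44 sampled haplotypes.

Sweep replicates place a single beneficial allele (additive per-copy
selection coefficient s; genotype fitnesses 1 : 1+s : 1+2s) at the segment
midpoint of population 1.  Hard sweeps arise de novo; soft sweeps arise
neutral and turn beneficial at an establishment frequency e.  Replicates
are conditioned either on the allele sitting at frequency f at sampling
time or on fixation g generations before sampling.

Engine: the sweep phase is a structured coalescent conditioned on a
per-generation allele-frequency trajectory sampled by
:func:`sample_trajectory` (see :mod:`hapscan._sweepengine`); for soft
sweeps the trajectory includes the neutral standing-variation phase, so
carriers coalesce all the way to the single mutational origin.  Each
replicate is simulated in two stages that exploit the absence of
post-split migration: both daughter populations are simulated
independently back to the split (population 1 through the sweep engine
plus a neutral msprime continuation), the partial tree sequences are
joined, and coalescence finishes in the ancestral population.  Neutral
replicates use a single msprime call with the full demography; the two
paths are statistically identical under neutrality.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import msprime
import numpy as np
import tskit
from numba import njit

from .hapio import HaplotypeMatrix, write_phased_vcf


@dataclass
class DemographicModel:
    """Piecewise-constant two-population divergence history.

    Sizes are diploid effective sizes; times are generations before present
    with ``t1 < t2 < t3``.  ``n_ref`` is the reference size for coalescent
    scaling (defaults to ``n1``).
    """

    n1: float  # population 1, present back to the split
    n2: float  # population 2, present..t1
    n3: float  # population 2, t1..t2
    n4: float  # population 2, t2..t3 (split)
    n5: float  # ancestral population, before t3
    t1: float
    t2: float
    t3: float
    n_ref: float | None = None

    def __post_init__(self) -> None:
        for name in ("n1", "n2", "n3", "n4", "n5"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.t1 < self.t2 < self.t3:
            raise ValueError("times must satisfy t1 < t2 < t3")
        if self.n_ref is None:
            self.n_ref = self.n1


# Point estimates and 95% CIs of the macaque high/low-altitude divergence
# model (diploid sizes; times in generations).
MACAQUE_MODEL = DemographicModel(
    n1=16188, n2=3730, n3=4506, n4=20768, n5=66210,
    t1=4660, t2=5605, t3=9468,
)
MACAQUE_CI = {
    "t1": (651, 5034),
    "t2": (3962, 10468),
    "t3": (4563, 14047),
    "n1": (8255, 26825),
    "n2": (660, 5006),
    "n3": (572, 124135),
    "n4": (1710, 88242),
    "n5": (20581, 301430),
}
# The reference size implied by the published simulation command
# (2*N_ref = 32,377); differs from the rounded table value by ~0.003%.
COMMAND_N_REF = 16188.5


@dataclass
class SimConfig:
    """Sequence and sampling configuration for one replicate set."""

    length: int = 500_000
    mu: float = 2.5e-8
    rec: float = 5.126e-9
    n_hap: tuple[int, int] = (46, 44)

    def __post_init__(self) -> None:
        if self.length <= 0 or self.mu < 0 or self.rec < 0:
            raise ValueError("length must be positive; rates non-negative")
        if min(self.n_hap) < 2:
            raise ValueError("need at least 2 haplotypes per population")


@dataclass
class SweepParams:
    """Selection parameters for a sweep in population 1.

    Exactly one of ``f`` (allele frequency at sampling) or ``g``
    (generations since fixation at sampling) must be set.  ``e`` is the
    establishment frequency: 0 for a hard sweep (de novo beneficial
    mutation), > 0 for a soft sweep from standing variation.
    """

    s: float
    e: float = 0.0
    f: float | None = None
    g: float | None = None
    sweep_pos: float = 0.5
    hide_selected: bool = True

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("selection coefficient s must be positive")
        if not 0 <= self.e < 1:
            raise ValueError("establishment frequency e must be in [0, 1)")
        if (self.f is None) == (self.g is None):
            raise ValueError("exactly one of f or g must be set")
        if self.f is not None and not 0 < self.f <= 1:
            raise ValueError("sampling frequency f must be in (0, 1]")
        if self.f is not None and self.f <= self.e:
            raise ValueError("sampling frequency f must exceed establishment e")
        if self.g is not None and self.g < 0:
            raise ValueError("generations post fixation g must be >= 0")
        if not 0 < self.sweep_pos < 1:
            raise ValueError("sweep_pos is a relative position in (0, 1)")


def scale_parameters(
    model: DemographicModel, cfg: SimConfig, s: float | None = None
) -> dict:
    """Coalescent-scaled (discoal-style) encoding of a model and config.

    theta = 4*N_ref*mu*L, rho = 4*N_ref*r*L, alpha = 2*N_ref*s, times in
    units of 4*N_ref generations and sizes as ratios to N_ref.
    """
    nref = model.n_ref
    four_n = 4.0 * nref
    out = {
        "theta": four_n * cfg.mu * cfg.length,
        "rho": four_n * cfg.rec * cfg.length,
        "size_changes": [
            # (scaled time, population index, size ratio): population 2
            # history plus the ancestral size after the merge.
            (0.0, 1, model.n2 / nref),
            (model.t1 / four_n, 1, model.n3 / nref),
            (model.t2 / four_n, 1, model.n4 / nref),
            (model.t3 / four_n, 0, model.n5 / nref),
        ],
        "split_time": model.t3 / four_n,
    }
    if s is not None:
        out["alpha"] = 2.0 * nref * s
    return out


def to_discoal_args(
    model: DemographicModel, cfg: SimConfig, p: SweepParams | None = None
) -> str:
    """Render the scaled model as a discoal-vocabulary argument string."""
    sc = scale_parameters(model, cfg, None if p is None else p.s)
    parts = [
        f"-p 2 {cfg.n_hap[0]} {cfg.n_hap[1]}",
        f"-t {sc['theta']:.6g}",
        f"-r {sc['rho']:.6g}",
    ]
    for t, pop, ratio in sc["size_changes"][:3]:
        parts.append(f"-en {t:.15g} {pop} {ratio:.15g}")
    parts.append(f"-ed {sc['split_time']:.15g} 1 0")
    t3, pop0, ratio5 = sc["size_changes"][3]
    parts.append(f"-en {t3:.15g} {pop0} {ratio5:.15g}")
    if p is not None:
        parts.append(f"-a {sc['alpha']:.6g}")
        parts.append(f"-x {p.sweep_pos:g}")
        if p.e > 0:
            parts.append(f"-f {p.e:g}")
        if p.f is not None:
            parts.append(f"-c {p.f:g}")
        else:
            parts.append(f"-ws {p.g / (2.0 * model.n_ref):.6g}")
        if p.hide_selected:
            parts.append("-h")
    return " ".join(parts)


# ---------------------------------------------------------------------------
# tree-sequence plumbing

def _full_demography(model: DemographicModel) -> msprime.Demography:
    d = msprime.Demography()
    d.add_population(name="pop1", initial_size=model.n1)
    d.add_population(name="pop2", initial_size=model.n2)
    d.add_population(name="anc", initial_size=model.n5)
    d.add_population_parameters_change(
        time=model.t1, population="pop2", initial_size=model.n3
    )
    d.add_population_parameters_change(
        time=model.t2, population="pop2", initial_size=model.n4
    )
    d.add_population_split(time=model.t3, derived=["pop1", "pop2"], ancestral="anc")
    return d


def _derive_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(x) for x in rng.integers(1, 2**31 - 1, size=n)]


def _ts_to_matrices(
    ts: tskit.TreeSequence,
    cols1: np.ndarray,
    cols2: np.ndarray,
    length: int,
    chrom: str,
) -> tuple[HaplotypeMatrix, HaplotypeMatrix]:
    """Split a mutated tree sequence into per-population matrices.

    Continuous (infinite-sites) mutation positions are converted to 1-based
    integer bp; collisions are resolved by shifting subsequent sites +1 and
    any site pushed past the segment end is dropped.
    """
    G = ts.genotype_matrix()  # sites x samples
    pos = np.floor(ts.sites_position).astype(np.int64) + 1
    for i in range(1, len(pos)):
        if pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1
    keep = pos <= length
    G = G[keep].astype(np.uint8)
    pos = pos[keep]
    m1 = HaplotypeMatrix(chrom=chrom, positions=pos, alleles=G[:, cols1].T)
    m2 = HaplotypeMatrix(chrom=chrom, positions=pos, alleles=G[:, cols2].T)
    return m1, m2


def simulate_neutral(
    model: DemographicModel, cfg: SimConfig, seed: int, chrom: str = "1"
) -> tuple[HaplotypeMatrix, HaplotypeMatrix]:
    """One neutral replicate; the seed fully determines the output."""
    anc_seed, mut_seed = _derive_seeds(seed, 2)
    n1, n2 = cfg.n_hap
    ts = msprime.sim_ancestry(
        samples={"pop1": math.ceil(n1 / 2), "pop2": math.ceil(n2 / 2)},
        demography=_full_demography(model),
        sequence_length=cfg.length,
        recombination_rate=cfg.rec,
        random_seed=anc_seed,
    )
    ts = msprime.sim_mutations(
        ts, rate=cfg.mu, random_seed=mut_seed, discrete_genome=False,
        model=msprime.BinaryMutationModel(),
    )
    samples = np.asarray(ts.samples())
    pops = np.array([ts.node(u).population for u in samples])
    cols1 = np.flatnonzero(pops == 0)[:n1]
    cols2 = np.flatnonzero(pops == 1)[:n2]
    return _ts_to_matrices(ts, cols1, cols2, cfg.length, chrom)


def simulate_sweep(
    model: DemographicModel,
    cfg: SimConfig,
    p: SweepParams,
    seed: int,
    chrom: str = "1",
) -> tuple[HaplotypeMatrix, HaplotypeMatrix]:
    """One sweep replicate (selection in population 1 only).

    Stage 1 samples an allele-frequency trajectory and runs the
    trajectory-conditioned structured coalescent for population 1 (see
    :mod:`hapscan._sweepengine`), finishing population 1's neutral
    coalescence back to the split; population 2 is simulated independently
    over the same period (valid because the model has no post-split
    migration).  Stage 2 joins the partial genealogies and finishes
    coalescence in the ancestral population.
    """
    from ._sweepengine import SweepGenealogy

    s_traj, s_eng, s1, s2, s3, mut_seed = _derive_seeds(seed, 6)
    n1, n2 = cfg.n_hap

    trajectory = sample_trajectory(p, model, s_traj)
    engine = SweepGenealogy(
        n_samples=n1,
        sequence_length=cfg.length,
        recombination_rate=cfg.rec,
        n_diploid=model.n1,
        sweep_position=p.sweep_pos * cfg.length,
        rng=np.random.default_rng(s_eng),
    )
    tables, carriers, t_end = engine.run(trajectory, max_time=model.t3 - 1)

    ts_stage = tables.tree_sequence()
    if max(t.num_roots for t in ts_stage.trees()) > 1:
        d1 = msprime.Demography()
        d1.add_population(name="stage", initial_size=model.n1)
        ts_sel = msprime.sim_ancestry(
            initial_state=ts_stage,
            demography=d1,
            recombination_rate=cfg.rec,
            end_time=model.t3,
            random_seed=s1,
        )
    else:
        ts_sel = ts_stage  # sample fully coalesced during the sweep phase
    d2 = msprime.Demography()
    d2.add_population(name="stage", initial_size=model.n2)
    d2.add_population_parameters_change(
        time=model.t1, population="stage", initial_size=model.n3
    )
    d2.add_population_parameters_change(
        time=model.t2, population="stage", initial_size=model.n4
    )
    ts_ref = msprime.sim_ancestry(
        samples={"stage": math.ceil(n2 / 2)},
        demography=d2,
        sequence_length=cfg.length,
        recombination_rate=cfg.rec,
        end_time=model.t3,
        random_seed=s2,
    )

    joined = ts_sel.union(
        ts_ref,
        node_mapping=np.full(ts_ref.num_nodes, tskit.NULL),
        check_shared_equality=False,
        add_populations=False,
    )
    tables = joined.dump_tables()
    tables.nodes.population = np.zeros(len(tables.nodes), dtype=np.int32)
    joined = tables.tree_sequence()

    d3 = msprime.Demography()
    d3.add_population(name="stage", initial_size=model.n5)
    ts = msprime.sim_ancestry(
        initial_state=joined,
        demography=d3,
        recombination_rate=cfg.rec,
        random_seed=s3,
    )
    ts = msprime.sim_mutations(
        ts, rate=cfg.mu, random_seed=mut_seed, discrete_genome=False,
        model=msprime.BinaryMutationModel(),
    )
    samples = np.asarray(ts.samples())
    first = samples[samples < ts_sel.num_nodes]
    second = samples[samples >= ts_sel.num_nodes]
    sample_list = list(ts.samples())
    cols1 = np.array([sample_list.index(u) for u in first[:n1]])
    cols2 = np.array([sample_list.index(u) for u in second[:n2]])
    m1, m2 = _ts_to_matrices(ts, cols1, cols2, cfg.length, chrom)
    if not p.hide_selected:
        m1, m2 = _insert_selected_site(m1, m2, carriers, p, cfg)
    return m1, m2


def _insert_selected_site(m1, m2, carriers, p: SweepParams, cfg: SimConfig):
    pos = int(round(p.sweep_pos * cfg.length))
    while pos in m1.positions:
        pos += 1
    at = int(np.searchsorted(m1.positions, pos))
    cols = (carriers[: m1.n_haplotypes].astype(np.uint8),
            np.zeros(m2.n_haplotypes, dtype=np.uint8))
    out = []
    for m, col in ((m1, cols[0]), (m2, cols[1])):
        alleles = np.insert(m.alleles, at, col, axis=1)
        positions = np.insert(m.positions, at, pos)
        out.append(
            HaplotypeMatrix(m.chrom, positions, alleles, list(m.sample_ids))
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# allele-frequency trajectories (forward Wright-Fisher, for analysis and
# cross-checks of sweep timing; the coalescent engine generates its own
# internal trajectory with the same selection model)

@njit(cache=True)
def _selected_phase(two_n, s, x0, f_target, need_fix, seed, max_attempts):
    np.random.seed(seed)
    for _ in range(max_attempts):
        path = np.empty(8 * two_n + 1000, dtype=np.float64)
        x = x0
        path[0] = x / two_n
        m = 1
        ok = False
        while True:
            pfreq = x / two_n
            pstar = pfreq * (1.0 + s + s * pfreq) / (1.0 + 2.0 * s * pfreq)
            x = np.random.binomial(two_n, pstar)
            if m >= path.shape[0]:
                tmp = np.empty(path.shape[0] * 2, dtype=np.float64)
                tmp[: path.shape[0]] = path
                path = tmp
            path[m] = x / two_n
            m += 1
            if x == 0:
                break
            if need_fix:
                if x == two_n:
                    ok = True
                    break
            elif x >= f_target * two_n:
                ok = True
                break
        if ok:
            return path[:m]
    return np.empty(0, dtype=np.float64)


@njit(cache=True)
def _neutral_phase_reversed(two_n, e_count, seed, max_attempts):
    # Neutral drift from frequency e conditioned on eventual loss; the
    # reversed path is the standing-variation history from origin up to
    # establishment.
    np.random.seed(seed)
    for _ in range(max_attempts):
        path = np.empty(32 * two_n, dtype=np.float64)
        x = e_count
        path[0] = x / two_n
        m = 1
        lost = False
        while m < path.shape[0]:
            x = np.random.binomial(two_n, x / two_n)
            path[m] = x / two_n
            m += 1
            if x == 0:
                lost = True
                break
            if x == two_n:
                break
        if lost:
            # drop the absorbed 0 state; reversed, the path runs from the
            # allele's origin near 1/(2N) up to the establishment frequency
            return path[: m - 1][::-1].copy()
    return np.empty(0, dtype=np.float64)


def sample_trajectory(
    p: SweepParams,
    model: DemographicModel,
    seed: int,
    max_attempts: int = 100_000,
) -> np.ndarray:
    """Sample a per-generation allele-frequency path in population 1.

    The path runs forward in time from the allele's origin at frequency
    1/(2*N1) to the sampling generation.  Soft sweeps (e > 0) drift
    neutrally up to the establishment frequency (simulated as a reversed
    loss-conditioned walk) and then sweep under additive selection; hard
    sweeps are under selection from origination.  Conditioning on f stops
    the path at the first generation the frequency reaches f; conditioning
    on g appends g generations at frequency 1 after fixation.  Rejection
    sampling is used for the selected phase; an unattainable condition
    raises after ``max_attempts`` rejected paths.
    """
    two_n = int(round(2 * model.n1))
    s_neut, s_sel = _derive_seeds(seed, 2)
    segments = []
    if p.e > 0:
        e_count = max(1, int(round(p.e * two_n)))
        neut = _neutral_phase_reversed(two_n, e_count, s_neut, max_attempts)
        if len(neut) == 0:
            raise RuntimeError(
                f"standing-variation phase not attained in {max_attempts} attempts"
            )
        segments.append(neut[:-1])  # establishment generation opens the next phase
        x0 = e_count
    else:
        x0 = 1
    if p.f is not None:
        f_target, need_fix = p.f, p.f >= 1.0
    else:
        f_target, need_fix = 1.0, True
    sel = _selected_phase(two_n, p.s, x0, f_target, need_fix, s_sel, max_attempts)
    if len(sel) == 0:
        raise RuntimeError(
            f"sweep condition not attained in {max_attempts} attempts"
        )
    segments.append(sel)
    path = np.concatenate(segments)
    if p.g is not None and p.g > 0:
        path = np.concatenate([path, np.ones(int(p.g))])
    return path


# ---------------------------------------------------------------------------
# mismatched histories

def mismatched_history(
    kind: str,
    seed: int | None = None,
    base: DemographicModel = MACAQUE_MODEL,
    ci: dict[str, tuple[float, float]] = MACAQUE_CI,
) -> DemographicModel:
    """Deliberately misspecified histories for normalization experiments.

    ``under``/``over`` replace only the present-day sizes with the CI
    endpoints that under- or over-state the size difference between the
    populations; ``rand`` draws every parameter uniformly within its 95%
    CI, resampling until the times are ordered (seed required).
    """
    kind = kind.lower()
    if kind == "under":
        return replace(base, n1=8255, n2=5006, n_ref=None)
    if kind == "over":
        return replace(base, n1=26825, n2=660, n_ref=None)
    if kind != "rand":
        raise ValueError("kind must be one of 'rand', 'under', 'over'")
    if seed is None:
        raise ValueError("kind='rand' needs a seed")
    rng = np.random.default_rng(seed)
    for _ in range(10_000):
        draw = {k: rng.uniform(*ci[k]) for k in ci}
        if draw["t1"] < draw["t2"] < draw["t3"]:
            return DemographicModel(
                n1=draw["n1"], n2=draw["n2"], n3=draw["n3"], n4=draw["n4"],
                n5=draw["n5"], t1=draw["t1"], t2=draw["t2"], t3=draw["t3"],
            )
    raise RuntimeError("could not draw ordered times from the CI table")


# ---------------------------------------------------------------------------
# replicate output

def write_replicate(
    pair: tuple[HaplotypeMatrix, HaplotypeMatrix],
    out_dir: str | Path,
    name: str,
    meta: dict | None = None,
) -> Path:
    """Write one replicate as a phased-VCF pair plus a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    m1, m2 = pair
    write_phased_vcf(m1, out_dir / f"{name}.pop1.vcf")
    write_phased_vcf(m2, out_dir / f"{name}.pop2.vcf")
    sidecar = {"name": name, "engine": "two-stage structured coalescent"}
    if meta:
        sidecar.update(meta)
    (out_dir / f"{name}.json").write_text(json.dumps(sidecar, indent=1))
    return out_dir
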