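"""Coalescent simulator: scaling, determinism, demography, sweeps,
trajectories and mismatched histories."""

import numpy as np
import pytest

from hapscan import (
    COMMAND_N_REF,
    MACAQUE_CI,
    MACAQUE_MODEL,
    DemographicModel,
    SimConfig,
    SweepParams,
    mismatched_history,
    sample_trajectory,
    scale_parameters,
    simulate_neutral,
    simulate_sweep,
    to_discoal_args,
)
from hapscan.simulate import write_replicate
from hapscan.hapio import read_phased_vcf

from dataclasses import replace


def command_model():
    """The macaque model with the reference size implied by the published
    simulation command (2*N_ref = 32,377)."""
    return replace(MACAQUE_MODEL, n1=COMMAND_N_REF, n_ref=None)


SMALL = SimConfig(length=60_000, n_hap=(12, 10))


class TestScaleParameters:
    def test_published_scaled_mutation_and_recombination(self):
        sc = scale_parameters(command_model(), SimConfig())
        assert sc["theta"] == pytest.approx(809.425, abs=1e-3)
        # the published command rounds the scaled recombination rate; the
        # stated per-bp rate gives 165.9645
        assert sc["rho"] == pytest.approx(165.967, rel=2e-5)

    def test_published_scaled_split_time(self):
        sc = scale_parameters(command_model(), SimConfig())
        assert sc["split_time"] == pytest.approx(0.146214905642895, rel=1e-12)

    def test_published_size_ratios(self):
        sc = scale_parameters(command_model(), SimConfig())
        ratios = {(t, p): r for t, p, r in sc["size_changes"]}
        assert ratios[(0.0, 1)] == pytest.approx(0.230410476572876, rel=1e-12)
        t1 = MACAQUE_MODEL.t1 / (4 * COMMAND_N_REF)
        assert t1 == pytest.approx(0.071964666275442, rel=1e-9)
        assert ratios[(t1, 1)] == pytest.approx(0.278345739259351, rel=1e-9)

    def test_published_selection_scaling(self):
        for s, alpha in [(0.01, 323.77), (0.02, 647.54), (0.05, 1618.85)]:
            sc = scale_parameters(command_model(), SimConfig(), s=s)
            assert sc["alpha"] == pytest.approx(alpha, abs=1e-6)

    def test_zero_mutation_rate(self):
        sc = scale_parameters(MACAQUE_MODEL, SimConfig(mu=0.0))
        assert sc["theta"] == 0.0

    def test_discoal_vocabulary(self):
        args = to_discoal_args(
            command_model(), SimConfig(),
            SweepParams(s=0.01, e=0.05, g=50),
        )
        assert args.startswith("-p 2 46 44 ")
        assert "-t 809.425" in args
        assert "-ed 0.146214905642895 1 0" in args
        assert "-a 323.77" in args
        # g = 50 generations in units of 2*N_ref
        assert "-ws 0.00154431" in args
        assert "-h" in args


class TestNeutralSimulation:
    def test_seed_determinism(self):
        a1, b1 = simulate_neutral(MACAQUE_MODEL, SMALL, seed=11)
        a2, b2 = simulate_neutral(MACAQUE_MODEL, SMALL, seed=11)
        np.testing.assert_array_equal(a1.alleles, a2.alleles)
        np.testing.assert_array_equal(a1.positions, a2.positions)
        a3, _ = simulate_neutral(MACAQUE_MODEL, SMALL, seed=12)
        assert a3.n_sites != a1.n_sites or not np.array_equal(a3.alleles, a1.alleles)

    def test_sample_sizes_and_shared_sites(self):
        cfg = SimConfig(length=100_000)
        m1, m2 = simulate_neutral(MACAQUE_MODEL, cfg, seed=5)
        assert m1.n_haplotypes == 46 and m2.n_haplotypes == 44
        np.testing.assert_array_equal(m1.positions, m2.positions)
        assert np.all(np.diff(m1.positions) > 0)
        assert m1.positions.max() <= cfg.length

    def test_watterson_segregating_sites(self):
        """Near-panmictic constant-N model matches the Watterson expectation."""
        N = 5000.0
        model = DemographicModel(
            n1=N, n2=N, n3=N, n4=N, n5=N, t1=1, t2=2, t3=3
        )
        cfg = SimConfig(length=50_000, n_hap=(10, 10))
        n = 20
        theta = 4 * N * cfg.mu * cfg.length
        expected = theta * sum(1 / i for i in range(1, n))
        counts = [
            simulate_neutral(model, cfg, seed=1000 + i)[0].n_sites
            for i in range(200)
        ]
        assert np.mean(counts) == pytest.approx(expected, rel=0.05)

    def test_replicate_written_as_vcf_pair(self, tmp_path):
        pair = simulate_neutral(MACAQUE_MODEL, SMALL, seed=3)
        write_replicate(pair, tmp_path, "rep0", meta={"seed": 3})
        back = read_phased_vcf(tmp_path / "rep0.pop1.vcf")
        np.testing.assert_array_equal(back.alleles, pair[0].alleles)
        assert (tmp_path / "rep0.json").exists()


class TestSweepSimulation:
    def test_seed_determinism_and_shapes(self):
        p = SweepParams(s=0.05, f=1.0)
        a1, b1 = simulate_sweep(MACAQUE_MODEL, SMALL, p, seed=21)
        a2, b2 = simulate_sweep(MACAQUE_MODEL, SMALL, p, seed=21)
        np.testing.assert_array_equal(a1.alleles, a2.alleles)
        assert a1.n_haplotypes == 12 and b1.n_haplotypes == 10
        np.testing.assert_array_equal(a1.positions, b1.positions)

    def test_selected_site_hidden_by_default(self):
        # a completed sweep leaves no fixed-difference column for the
        # selected site itself when hide_selected is on
        p = SweepParams(s=0.05, f=1.0, hide_selected=False)
        m1, m2 = simulate_sweep(MACAQUE_MODEL, SMALL, p, seed=22)
        pos = int(round(0.5 * SMALL.length))
        assert pos in m1.positions
        j = list(m1.positions).index(pos)
        assert m1.alleles[:, j].min() == 1  # fixed derived in population 1
        assert m2.alleles[:, j].max() == 0  # absent in population 2

    def test_diversity_reduction_in_selected_population(self):
        """Strong completed sweeps collapse diversity around the selected
        site in population 1 while leaving population 2 untouched."""
        from scipy.stats import mannwhitneyu

        cfg = SimConfig(length=200_000, n_hap=(20, 20))
        p = SweepParams(s=0.05, f=1.0)
        lo, hi = 75_000, 125_000

        def central_pi(m):
            sel = (m.positions >= lo) & (m.positions <= hi)
            H = m.alleles[:, sel]
            n = H.shape[0]
            tot = 0
            npairs = 0
            for i in range(n):
                for j in range(i + 1, n):
                    tot += np.sum(H[i] != H[j])
                    npairs += 1
            return tot / npairs

        n_reps = 100
        pi_sweep1, pi_sweep2, pi_neut1, pi_neut2 = [], [], [], []
        for i in range(n_reps):
            s1, s2 = simulate_sweep(MACAQUE_MODEL, cfg, p, seed=40_000 + i)
            n1, n2 = simulate_neutral(MACAQUE_MODEL, cfg, seed=60_000 + i)
            pi_sweep1.append(central_pi(s1))
            pi_sweep2.append(central_pi(s2))
            pi_neut1.append(central_pi(n1))
            pi_neut2.append(central_pi(n2))
        assert np.mean(pi_sweep1) < 0.5 * np.mean(pi_neut1)
        # non-selected population indistinguishable from neutral runs
        stat = mannwhitneyu(pi_sweep2, pi_neut2)
        assert stat.pvalue > 0.01


class TestTrajectories:
    def test_condition_f_one_reaches_fixation(self):
        p = SweepParams(s=0.05, f=1.0)
        path = sample_trajectory(p, MACAQUE_MODEL, seed=1)
        assert path[-1] == 1.0
        assert np.all((path >= 0) & (path <= 1))

    def test_hard_sweep_starts_at_single_copy(self):
        p = SweepParams(s=0.05, f=1.0)
        path = sample_trajectory(p, MACAQUE_MODEL, seed=2)
        assert path[0] == pytest.approx(1 / (2 * MACAQUE_MODEL.n1), rel=1e-6)

    def test_partial_sweep_stops_at_first_crossing(self):
        p = SweepParams(s=0.05, f=0.7)
        path = sample_trajectory(p, MACAQUE_MODEL, seed=3)
        assert path[-1] >= 0.7
        assert np.all(path[:-1] < 1.0)

    def test_post_fixation_generations_appended(self):
        p = SweepParams(s=0.05, g=50)
        path = sample_trajectory(p, MACAQUE_MODEL, seed=4)
        assert np.all(path[-50:] == 1.0)
        assert path[-51] == 1.0  # fixation generation itself

    def test_soft_sweep_standing_phase(self):
        small = DemographicModel(
            n1=500, n2=500, n3=500, n4=500, n5=500, t1=1, t2=2, t3=3
        )
        p = SweepParams(s=0.1, e=0.1, f=1.0)
        path = sample_trajectory(p, small, seed=5)
        # the standing phase originates near a single copy and must pass
        # through the establishment frequency on its way up
        assert 0 < path[0] <= 5 / 1000
        assert np.any(path >= 0.1)
        assert path[-1] == 1.0

    def test_sojourn_matches_wright_fisher_oracle(self):
        """Conditional fixation time agrees with an independent plain
        Wright-Fisher forward simulation (within 15%)."""
        N, s = 400, 0.1
        model = DemographicModel(
            n1=N, n2=N, n3=N, n4=N, n5=N, t1=1, t2=2, t3=3
        )
        times = [
            len(sample_trajectory(SweepParams(s=s, f=1.0), model, seed=100 + i))
            for i in range(100)
        ]
        # oracle: unconditioned forward WF, keep fixed paths
        rng = np.random.default_rng(987)
        two_n = 2 * N
        oracle = []
        while len(oracle) < 100:
            x, t = 1, 0
            while 0 < x < two_n:
                pfreq = x / two_n
                pstar = pfreq * (1 + s + s * pfreq) / (1 + 2 * s * pfreq)
                x = rng.binomial(two_n, pstar)
                t += 1
            if x == two_n:
                oracle.append(t + 1)  # include origination generation
        assert np.mean(times) == pytest.approx(np.mean(oracle), rel=0.15)

    def test_unattainable_condition_reports_attempts(self):
        p = SweepParams(s=1e-6, f=1.0)
        small = DemographicModel(
            n1=2000, n2=10, n3=10, n4=10, n5=10, t1=1, t2=2, t3=3
        )
        with pytest.raises(RuntimeError, match="attempts"):
            sample_trajectory(p, small, seed=6, max_attempts=3)


class TestSweepParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(s=-0.1, f=1.0),
            dict(s=0.1),                 # neither f nor g
            dict(s=0.1, f=0.5, g=10),    # both
            dict(s=0.1, f=1.5),
            dict(s=0.1, e=0.5, f=0.3),   # f below establishment
            dict(s=0.1, e=1.0, f=1.0),
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SweepParams(**kwargs)


class TestMismatchedHistories:
    def test_under_uses_ci_endpoints(self):
        m = mismatched_history("under")
        assert (m.n1, m.n2) == (8255, 5006)
        assert (m.n3, m.t3) == (MACAQUE_MODEL.n3, MACAQUE_MODEL.t3)

    def test_over_uses_ci_endpoints(self):
        m = mismatched_history("over")
        assert (m.n1, m.n2) == (26825, 660)

    def test_rand_within_ci_and_ordered(self):
        for seed in range(25):
            m = mismatched_history("rand", seed=seed)
            for name in ("t1", "t2", "t3", "n1", "n2", "n3", "n4", "n5"):
                lo, hi = MACAQUE_CI[name]
                assert lo <= getattr(m, name) <= hi
            assert m.t1 < m.t2 < m.t3

    def test_rand_requires_seed(self):
        with pytest.raises(ValueError, match="seed"):
            mismatched_history("rand")


class TestSweepEngine:
    """Direct checks of the trajectory-conditioned structured coalescent."""

    def _run(self, n=12, e=0.0, f=1.0, seed=5, s=0.1, N=1000):
        from hapscan._sweepengine import SweepGenealogy

        model = DemographicModel(n1=N, n2=N, n3=N, n4=N, n5=N,
                                 t1=1, t2=2, t3=3)
        traj = sample_trajectory(SweepParams(s=s, e=e, f=f), model, seed)
        eng = SweepGenealogy(
            n_samples=n, sequence_length=50_000, recombination_rate=1e-8,
            n_diploid=N, sweep_position=25_000,
            rng=np.random.default_rng(seed + 1),
        )
        tables, carriers, t_end = eng.run(traj)
        return tables.tree_sequence(), carriers, t_end, traj

    def test_tables_are_valid_and_bounded_in_time(self):
        ts, carriers, t_end, traj = self._run()
        assert t_end <= len(traj) + 1
        assert ts.num_samples == 12
        assert max(ts.tables.nodes.time) <= len(traj) + 1

    def test_completed_sweep_coalesces_carriers_at_sweep_site(self):
        # with f = 1 all samples carry the allele; at the selected site the
        # whole sample must share one ancestor no later than the origin
        ts, carriers, t_end, traj = self._run(f=1.0)
        assert carriers.all()
        tree = ts.at(25_000)
        assert tree.num_roots == 1
        assert tree.time(tree.root) <= len(traj) + 1

    def test_partial_sweep_draws_carriers_at_sampling_frequency(self):
        counts = []
        for seed in range(30):
            _, carriers, _, _ = self._run(f=0.6, seed=100 + seed, n=20)
            counts.append(carriers.mean())
        assert 0.45 < np.mean(counts) < 0.75
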