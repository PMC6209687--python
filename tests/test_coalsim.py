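import numpy as np
import pytest
from scipy import stats as sps

from glacialdemog import coalsim
from glacialdemog.coalsim import (
    PRIOR,
    SCENARIOS,
    DemographicParams,
    Genealogy,
    LocusSpec,
    drop_mutations,
    hky_model,
    mutate_hky,
    sample_prior,
    simulate_dataset,
    simulate_genealogy,
    study_design,
)

CONST = DemographicParams(5e3, 5e3, 5e3, 2.5e4, 1e3, 6e-8, 2e-7)


class TestPriors:
    def test_bounds_s1(self):
        rng = np.random.default_rng(0)
        draws = [sample_prior("S1", rng) for _ in range(2000)]
        ne = np.array([d.Ne for d in draws])
        assert ne.min() >= PRIOR["Ne"][0] and ne.max() <= PRIOR["Ne"][1]

    def test_determinism(self):
        a = [sample_prior("S4", np.random.default_rng(7)) for _ in range(5)]
        b = [sample_prior("S4", np.random.default_rng(7)) for _ in range(5)]
        assert a == b

    @pytest.mark.parametrize("sid,check", [
        ("S2", lambda p: p.Na > p.Ne),
        ("S3", lambda p: p.Na < p.Ne),
        ("S4", lambda p: p.Ndb > max(p.Ne, p.Na) and p.Tdb < p.Ta),
        ("S6", lambda p: p.Ndb < min(p.Ne, p.Na)),
    ])
    def test_ordering_constraints(self, sid, check):
        rng = np.random.default_rng(1)
        assert all(check(sample_prior(sid, rng)) for _ in range(2000))

    def test_tdb_windows(self):
        rng = np.random.default_rng(2)
        for sid, (lo, hi) in (("S4", (250, 1500)), ("S5", (75, 275))):
            t = [sample_prior(sid, rng).Tdb for _ in range(500)]
            assert lo <= min(t) and max(t) <= hi


class TestGenealogy:
    def test_single_leaf(self):
        tree = simulate_genealogy(
            CONST, "S1", LocusSpec("x", "nuclear", 10, 1), np.random.default_rng(0)
        )
        assert tree.n_leaves == 1 and tree.tmrca == 0.0

    def test_empty(self):
        tree = simulate_genealogy(
            CONST, "S1", LocusSpec("x", "nuclear", 10, 0), np.random.default_rng(0)
        )
        assert tree.n_nodes == 0

    def test_pair_tmrca_nuclear_and_plastid_scaling(self):
        rng = np.random.default_rng(3)
        reps = 3000
        for mult, expect in ((1.0, 2 * 5e3), (0.5, 5e3)):
            spec = LocusSpec("x", "nuclear", 10, 2, mult)
            t = np.array(
                [simulate_genealogy(CONST, "S1", spec, rng).tmrca
                 for _ in range(reps)]
            )
            se = t.std() / np.sqrt(reps)
            assert abs(t.mean() - expect) < 3 * se

    def test_parent_index_exceeds_child(self):
        rng = np.random.default_rng(4)
        tree = simulate_genealogy(CONST, "S4", LocusSpec("x", "nuclear", 10, 30), rng)
        nonroot = np.arange(tree.n_nodes - 1)
        assert np.all(tree.parent[nonroot] > nonroot)
        assert np.all(np.diff(tree.node_times[tree.n_leaves:]) >= 0)

    def test_tmrca_distribution_matches_msprime(self):
        """Independent oracle: the same three-epoch exponential demography
        simulated with msprime must give the same TMRCA distribution."""
        import msprime

        p = DemographicParams(2e4, 5e3, 8e4, 2.5e4, 1e3, 6e-8, 2e-7)
        scen = SCENARIOS["S4"]
        spec = LocusSpec("x", "nuclear", 10, 10)
        rng = np.random.default_rng(5)
        reps = 1200
        mine = np.array(
            [simulate_genealogy(p, scen, spec, rng).tmrca for _ in range(reps)]
        )
        at, asz = scen.anchors(p)
        # chromosome counts 2N; msprime ploidy=1 population size = 2N
        g0 = np.log((2 * p.Ne) / (2 * p.Ndb)) / p.Tdb
        g1 = np.log((2 * p.Ndb) / (2 * p.Na)) / (p.Ta - p.Tdb)
        dem = msprime.Demography()
        dem.add_population(initial_size=2 * p.Ne, growth_rate=g0)
        dem.add_population_parameters_change(
            time=p.Tdb, initial_size=2 * p.Ndb, growth_rate=g1
        )
        dem.add_population_parameters_change(
            time=p.Ta, initial_size=2 * p.Na, growth_rate=0
        )
        theirs = np.array([
            ts.max_root_time
            for ts in msprime.sim_ancestry(
                samples=10, ploidy=1, demography=dem,
                num_replicates=reps, random_seed=11,
            )
        ])
        assert sps.ks_2samp(mine, theirs).pvalue > 0.01

    def test_exponential_epoch_limit_matches_two_phase_model(self):
        """A very steep exponential transition behaves like an
        instantaneous size change."""
        rng = np.random.default_rng(6)
        steep = DemographicParams(1e3, 5e4, 5e4, 2.5e4, 20.0, 6e-8, 2e-7)
        stepped = []
        spec = LocusSpec("x", "nuclear", 10, 2)
        reps = 3000
        mine = np.array(
            [simulate_genealogy(steep, "S4", spec, rng).tmrca
             for _ in range(reps)]
        )
        # oracle: exact two-phase inversion (constant 2Ne then constant 2Ndb)
        u = np.random.default_rng(7).random(reps)
        nc0, nc1, t0 = 2e3, 1e5, 20.0
        t_oracle = np.where(
            u < 1 - np.exp(-t0 / nc0),
            -nc0 * np.log(1 - u),
            t0 - nc1 * np.log((1 - u) / np.exp(-t0 / nc0)),
        )
        assert sps.ks_2samp(mine, t_oracle).pvalue > 0.01


class TestMutation:
    def test_zero_rate(self):
        rng = np.random.default_rng(0)
        spec = LocusSpec("x", "nuclear", 100, 8)
        tree = simulate_genealogy(CONST, "S1", spec, rng)
        sd = drop_mutations(tree, 0.0, spec, rng)
        assert sd.genotypes.shape[0] == 0

    def test_jc69_divergence_closed_form(self):
        # two tips at divergence t: p_diff = (3/4)(1 - exp(-4 mu t / 3))
        t_div = 4e4
        mu = 1e-5
        L = 200_000
        spec = LocusSpec("x", "nuclear", L, 2, kappa=1.0)
        tree = Genealogy(
            np.array([2, 2, -1], dtype=np.int64),
            np.array([0.0, 0.0, t_div / 2]),
            2,
        )
        sd = drop_mutations(tree, mu, spec, np.random.default_rng(8))
        p_obs = np.mean(sd.genotypes[:, 0] != sd.genotypes[:, 1]) * (
            sd.genotypes.shape[0] / L
        )
        p_exp = 0.75 * (1 - np.exp(-4 * mu * t_div / 3))
        se = np.sqrt(p_exp * (1 - p_exp) / L)
        assert abs(p_obs - p_exp) < 3 * se

    def test_tip_composition_matches_stationary_frequencies(self):
        freqs = (0.1, 0.2, 0.3, 0.4)
        L = 50_000
        spec = LocusSpec("x", "nuclear", L, 2, kappa=3.0, base_frequencies=freqs)
        tree = Genealogy(
            np.array([2, 2, -1], dtype=np.int64),
            np.array([0.0, 0.0, 5e4]),
            2,
        )
        aln, anc = mutate_hky(tree, 2e-5, spec, np.random.default_rng(9))
        counts = np.array([aln.sequences[0].count(b) for b in "ACGT"])
        assert sps.chisquare(counts, np.array(freqs) * L).pvalue > 0.01

    def test_hky_normalization(self):
        # realized substitution rate equals mu on a long branch
        mu = 1e-5
        t_div = 2e3  # short enough that back-mutation is negligible
        L = 500_000
        spec = LocusSpec("x", "nuclear", L, 2, kappa=4.0,
                         base_frequencies=(0.4, 0.1, 0.1, 0.4))
        tree = Genealogy(
            np.array([2, 2, -1], dtype=np.int64),
            np.array([0.0, 0.0, t_div / 2]),
            2,
        )
        sd = drop_mutations(tree, mu, spec, np.random.default_rng(10))
        n_diff = int(np.sum(sd.genotypes[:, 0] != sd.genotypes[:, 1]))
        expect = mu * t_div * L
        assert abs(n_diff - expect) < 4 * np.sqrt(expect)


class TestDataset:
    def test_sample_size_one_everywhere(self):
        design = [LocusSpec("a", "nuclear", 50, 1), LocusSpec("c", "plastid", 50, 1, 0.5)]
        rng = np.random.default_rng(0)
        sds = coalsim.simulate_site_data("S1", CONST, design, rng)
        assert all(sd.genotypes.shape[0] == 0 for sd in sds)

    def test_watterson_expectation(self):
        rng = np.random.default_rng(12)
        spec = LocusSpec("x", "nuclear", 336, 210)
        mu = 2e-7
        reps = 400
        S = np.empty(reps)
        for i in range(reps):
            tree = simulate_genealogy(CONST, "S1", spec, rng)
            S[i] = drop_mutations(tree, mu, spec, rng).genotypes.shape[0]
        theta_locus = 4 * CONST.Ne * mu * 336
        a_n = np.sum(1.0 / np.arange(1, 210))
        se = S.std() / np.sqrt(reps)
        assert abs(S.mean() - theta_locus * a_n) < 3 * se

    def test_plastid_nuclear_diversity_ratio(self):
        # pi = 2 mu E[T2]; E[T2] = N chromosomes (2N x multiplier)
        rng = np.random.default_rng(13)
        reps = 400
        cp = LocusSpec("c", "plastid", 1000, 20, 0.5)
        nr = LocusSpec("n", "nuclear", 1000, 20, 1.0)
        k_cp = np.empty(reps)
        k_nr = np.empty(reps)
        for i in range(reps):
            t1 = simulate_genealogy(CONST, "S1", cp, rng)
            sd = drop_mutations(t1, CONST.mu_cp, cp, rng)
            k_cp[i] = _mean_pairdiff(sd)
            t2 = simulate_genealogy(CONST, "S1", nr, rng)
            sd = drop_mutations(t2, CONST.mu_nr, nr, rng)
            k_nr[i] = _mean_pairdiff(sd)
        # theta per site: plastid 2 (2N x 0.5) mu_cp, nuclear 2 (2N) mu_nr
        expect = CONST.mu_cp / (2 * CONST.mu_nr)
        ratio = k_cp.mean() / k_nr.mean()
        assert ratio == pytest.approx(expect, rel=0.15)

    def test_full_dataset_dimensions_and_determinism(self):
        ds1 = simulate_dataset("S4", CONST, rng=np.random.default_rng(14))
        ds2 = simulate_dataset("S4", CONST, rng=np.random.default_rng(14))
        shapes = {a.locus_name: (a.n, a.length) for a in ds1.loci}
        assert shapes == {"RPc": (210, 336), "SAP": (210, 434), "cpDNA": (105, 1814)}
        for a, b in zip(ds1.loci, ds2.loci):
            assert a.sequences == b.sequences

    def test_tajima_sign_tracks_demography(self):
        """Recent decline pushes D positive, recent growth negative."""
        from glacialdemog.diversity import tajimas_d

        rng = np.random.default_rng(15)
        spec = LocusSpec("x", "nuclear", 800, 30)
        decline = DemographicParams(2e3, 6e4, 5e3, 3e3, 1e3, 6e-8, 2e-7)
        growth = DemographicParams(6e4, 2e3, 5e3, 3e3, 1e3, 6e-8, 2e-7)
        means = {}
        for name, scen, p in (("decline", "S2", decline), ("growth", "S3", growth)):
            vals = []
            for _ in range(600):
                tree = simulate_genealogy(p, scen, spec, rng)
                sd = drop_mutations(tree, 2e-7, spec, rng)
                S = sd.genotypes.shape[0]
                if S == 0:
                    continue
                vals.append(tajimas_d(30, S, _mean_pairdiff(sd)))
            means[name] = np.mean(vals)
        assert means["decline"] > 0.1
        assert means["growth"] < -0.1


def _mean_pairdiff(sd):
    G = sd.genotypes
    if G.shape[0] == 0:
        return 0.0
    n = G.shape[1]
    iu = np.triu_indices(n, 1)
    D = (G[:, :, None] != G[:, None, :]).sum(axis=0)
    return float(D[iu].mean())


def test_hky_model_mean_rate():
    for kappa, freqs in ((2.0, (0.25,) * 4), (5.0, (0.4, 0.1, 0.2, 0.3))):
        q_event, cum = hky_model(kappa, freqs, mu=1e-7)
        P = np.diff(np.concatenate([np.zeros((4, 1)), cum], axis=1), axis=1)
        leave = q_event * (1 - np.diag(P))
        assert np.asarray(freqs) @ leave == pytest.approx(1e-7)
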