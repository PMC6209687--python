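import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from glacialdemog import abcinfer
from glacialdemog.abcinfer import (
    STAT_COLUMNS,
    ReferenceTable,
    ToleranceError,
    build_reference_table,
    choose_scenario,
    estimate_params,
    rmae,
    stats_from_site_data,
    summary_stats,
)
from glacialdemog.coalsim import DemographicParams, LocusSpec, study_design
from glacialdemog.seqdata import StudyDataset

from conftest import make_alignment

TOY_SEQS = ["ACGTACGTAC", "ACGTACGTAT", "ACGAACGTAT", "ACGAACGTAT"]
# exhaustively enumerated for the toy: pair differences {1,2,2,1,1,0},
# rarest-nucleotide counts per segregating site {2, 1}
TOY_STATS = dict(VPD=0.56667, TajD=0.5916, PSS=1.0, MNS=1.5, VNS=0.5)


def toy_dataset():
    nuc = make_alignment(TOY_SEQS, locus="nuc")
    pla = make_alignment(TOY_SEQS, locus="pla", ploidy_tag="plastid")
    return StudyDataset(
        loci=[nuc, pla], locus_groups={"nuclear": ["nuc"], "plastid": ["pla"]}
    )


class TestSummaryStats:
    def test_monomorphic_gives_zero_vector(self):
        nuc = make_alignment(["ACGT"] * 4, locus="nuc")
        pla = make_alignment(["ACGT"] * 4, locus="pla")
        ds = StudyDataset(
            loci=[nuc, pla],
            locus_groups={"nuclear": ["nuc"], "plastid": ["pla"]},
        )
        assert np.allclose(summary_stats(ds), 0.0)

    def test_toy_enumeration_values(self):
        v = dict(zip(STAT_COLUMNS, summary_stats(toy_dataset())))
        for grp in ("plastid", "nuclear"):
            for name, expect in TOY_STATS.items():
                assert v[f"{grp}_{name}"] == pytest.approx(expect, abs=2e-4)

    def test_duplication_doubles_rarest_counts_and_kills_singletons(self):
        doubled = StudyDataset(
            loci=[
                make_alignment(TOY_SEQS * 2, locus="nuc"),
                make_alignment(TOY_SEQS * 2, locus="pla"),
            ],
            locus_groups={"nuclear": ["nuc"], "plastid": ["pla"]},
        )
        v = dict(zip(STAT_COLUMNS, summary_stats(doubled)))
        assert v["nuclear_PSS"] == 0.0
        assert v["nuclear_MNS"] == pytest.approx(2 * TOY_STATS["MNS"])

    def test_gap_columns_discarded(self):
        with_gap = [s[:3] + "-" + s[4:] if i == 0 else s
                    for i, s in enumerate(TOY_SEQS)]
        ds = StudyDataset(
            loci=[
                make_alignment(with_gap, locus="nuc"),
                make_alignment(TOY_SEQS, locus="pla"),
            ],
            locus_groups={"nuclear": ["nuc"], "plastid": ["pla"]},
        )
        v = dict(zip(STAT_COLUMNS, summary_stats(ds)))
        # dropping column 4 removes one segregating site from the nuclear locus
        assert v["nuclear_PSS"] == 1.0
        assert v["plastid_PSS"] == 1.0


TINY_DESIGN = [
    LocusSpec("nuc", "nuclear", 300, 20),
    LocusSpec("cp", "plastid", 600, 10, 0.5),
]


class TestReferenceTable:
    def test_equal_allocation(self):
        t = build_reference_table(700, design=TINY_DESIGN, seed=1)
        labels, counts = np.unique(t.scenario_labels(), return_counts=True)
        assert len(labels) == 7 and set(counts) == {100}

    def test_seed_reproducibility(self):
        a = build_reference_table(70, design=TINY_DESIGN, seed=9)
        b = build_reference_table(70, design=TINY_DESIGN, seed=9)
        assert np.array_equal(a.stats, b.stats)
        assert np.array_equal(a.params, b.params)

    def test_frame_roundtrip(self):
        t = build_reference_table(35, design=TINY_DESIGN, seed=3)
        back = ReferenceTable.from_frame(t.to_frame())
        assert np.allclose(back.stats, t.stats)
        assert list(back.scenario_labels()) == list(t.scenario_labels())

    def test_scenarios_are_statistically_separable(self):
        t = build_reference_table(
            1000, scenarios=("S1", "S4"), design=TINY_DESIGN, seed=5
        )
        lab = t.scenario_labels()
        pvals = [
            sps.ks_2samp(t.stats[lab == "S1", j], t.stats[lab == "S4", j]).pvalue
            for j in range(10)
        ]
        assert min(pvals) < 0.05


def synthetic_table(n_per=300, K=7, sep=4.0, seed=0, n_stats=10):
    """Reference table with Gaussian stat clusters per scenario."""
    rng = np.random.default_rng(seed)
    centers = rng.normal(0, sep, size=(K, n_stats))
    stats, labels = [], []
    for k in range(K):
        stats.append(centers[k] + rng.normal(0, 1, size=(n_per, n_stats)))
        labels += [k] * n_per
    params = rng.uniform(1e3, 1e5, size=(K * n_per, 7))
    return ReferenceTable(
        scenario_ids=tuple(f"S{k + 1}" for k in range(K)),
        scenario_index=np.array(labels),
        params=params,
        stats=np.vstack(stats),
    )


class TestChooseScenario:
    def test_acceptance_set_size_exact(self):
        t = synthetic_table()
        for tol in (0.01, 0.0137, 0.5):
            c = choose_scenario(t.stats[0], t, tolerance=tol)
            assert c.n_accepted == int(np.ceil(tol * t.n_rows))

    def test_single_scenario_acceptance_gives_point_mass(self):
        t = synthetic_table(sep=30.0)
        obs = t.stats[t.scenario_index == 2].mean(axis=0)
        for method in ("direct", "logistic"):
            c = choose_scenario(obs, t, tolerance=0.01, method=method)
            pp = dict(zip(c.posterior["scenario"], c.posterior["pp"]))
            assert pp["S3"] == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("method", ["direct", "logistic"])
    def test_probabilities_sum_to_one(self, method):
        t = synthetic_table(sep=1.0)
        c = choose_scenario(t.stats.mean(axis=0), t, 0.05, method)
        assert c.posterior["pp"].sum() == pytest.approx(1.0, abs=1e-6)
        assert ((c.posterior["ci_low"] >= 0) & (c.posterior["ci_high"] <= 1)).all()

    def test_exchangeable_scenarios_give_uniform_pp(self):
        # identical generating process for every label
        rng = np.random.default_rng(3)
        stats = rng.normal(size=(7 * 400, 10))
        t = ReferenceTable(
            scenario_ids=tuple(f"S{k}" for k in range(1, 8)),
            scenario_index=np.tile(np.arange(7), 400),
            params=np.ones((2800, 7)),
            stats=stats,
        )
        c = choose_scenario(rng.normal(size=10) * 0.1, t, tolerance=0.25)
        m = c.n_accepted
        se = np.sqrt((1 / 7) * (6 / 7) / m)
        assert np.all(np.abs(c.posterior["pp"] - 1 / 7) < 3 * se)

    def test_affine_invariance_of_acceptance(self):
        t = synthetic_table(seed=4)
        obs = t.stats[5]
        c1 = choose_scenario(obs, t, 0.02)
        scaled = ReferenceTable(
            scenario_ids=t.scenario_ids,
            scenario_index=t.scenario_index,
            params=t.params,
            stats=t.stats * 7.5 - 3.0,
        )
        c2 = choose_scenario(obs * 7.5 - 3.0, scaled, 0.02)
        assert np.allclose(c1.posterior["pp"], c2.posterior["pp"])

    def test_direct_and_logistic_agree_when_separated(self):
        t = synthetic_table(sep=6.0, seed=6)
        rng = np.random.default_rng(7)
        agree = 0
        for _ in range(40):
            k = rng.integers(7)
            obs = t.stats[t.scenario_index == k][rng.integers(100)]
            b1 = choose_scenario(obs, t, 0.02, "direct").best
            b2 = choose_scenario(obs, t, 0.02, "logistic").best
            agree += b1 == b2
        assert agree >= 38

    def test_tolerance_too_small_raises(self):
        t = synthetic_table(n_per=10)
        with pytest.raises(ToleranceError):
            choose_scenario(t.stats[0], t, tolerance=1e-5)


class TestEstimateParams:
    def test_zero_adjustment_when_stats_identical(self):
        rng = np.random.default_rng(0)
        n = 500
        stats = np.tile(np.linspace(0, 1, 10), (n, 1))
        params = np.column_stack([
            rng.uniform(1e3, 1e5, n) if i < 5 else rng.uniform(1e-8, 1e-7, n)
            for i in range(7)
        ])
        t = ReferenceTable(("S1",), np.zeros(n, int), params, stats)
        post = estimate_params(stats[0], t, "S1", tolerance=0.5)
        # with zero spread in stats the regression has nothing to correct:
        # every adjusted draw must coincide with a raw prior draw
        raw = np.sort(params[:, 0])
        pos = np.clip(np.searchsorted(raw, post.draws["Ne"]), 0, len(raw) - 1)
        near = np.minimum(
            np.abs(raw[pos] - post.draws["Ne"]),
            np.abs(raw[np.maximum(pos - 1, 0)] - post.draws["Ne"]),
        )
        assert np.all(near < 1e-6 * raw.mean())

    def test_linear_toy_recovers_parameter(self):
        # theta ~ U(0,1) carried by mu_cp (raw scale); stat0 = theta + noise
        rng = np.random.default_rng(1)
        n = 4000
        theta = rng.uniform(0, 1, n)
        stats = np.column_stack(
            [theta + rng.normal(0, 0.01, n)]
            + [rng.normal(0, 1, n) for _ in range(9)]
        )
        params = np.ones((n, 7))
        params[:, 5] = theta  # mu_cp column
        t = ReferenceTable(("S1",), np.zeros(n, int), params, stats)
        obs = np.array([0.5] + [0.0] * 9)
        post = estimate_params(obs, t, "S1", 0.05, parameters=("mu_cp",))
        assert post.point("mu_cp") == pytest.approx(0.5, abs=0.02)
        assert post.summary.loc["mu_cp", "q2_5"] <= 0.5 <= post.summary.loc["mu_cp", "q97_5"]

    def test_quantile_ordering(self):
        t = synthetic_table(seed=8)
        post = estimate_params(t.stats[0], t.subset("S2"), "S2", 0.2)
        s = post.summary
        assert (s["q2_5"] <= s["median"]).all() and (s["median"] <= s["q97_5"]).all()


class TestRmae:
    def test_oracle_estimator(self):
        truths = np.array([2.0, 5.0, 9.0])
        assert rmae(truths, truths) == 0.0

    def test_double_estimator(self):
        truths = np.array([2.0, 5.0, 9.0])
        assert rmae(2 * truths, truths) == 1.0

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            rmae(np.ones(2), np.array([1.0, 0.0]))


class TestGoodnessOfFit:
    def test_displaced_observation_flagged(self):
        from glacialdemog.abcinfer import PosteriorSummary, goodness_of_fit

        rng = np.random.default_rng(5)
        table = build_reference_table(
            140, scenarios=("S1",), design=TINY_DESIGN, seed=11
        )
        draws = pd.DataFrame(
            dict(
                Ne=rng.uniform(5e3, 2e4, 50),
                mu_cp=rng.uniform(*(5e-8, 7e-8), 50),
                mu_nr=rng.uniform(*(1e-7, 3e-7), 50),
            )
        )
        post = PosteriorSummary(
            scenario="S1", adjustment="rejection-only", n_accepted=50,
            draws=draws, summary=pd.DataFrame(),
        )
        obs = table.stats.mean(axis=0)
        obs[0] += 50 * table.sds[0]  # displaced far outside the POD cloud
        gof = goodness_of_fit(
            obs, post, table, n_pods=150, design=TINY_DESIGN, rng=rng
        )
        assert gof.tail_p.iloc[0] < 0.05
        assert gof.pca_pods.shape == (150, 2)
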