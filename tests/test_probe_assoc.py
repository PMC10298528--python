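import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnvclim import probe_assoc as pa
from conftest import make_calls, random_calls


def make_probes(rows):
    """Probe map from (probe, chrom, pos) tuples."""
    return pd.DataFrame(rows, columns=["probe", "chrom", "pos"])


GRID_PROBES = make_probes([(f"p{i}", "chr1", 100 * i) for i in range(1, 11)])


def triple_loop_matrix(calls, probes, polarity, samples):
    classes = {"del": (0, 1), "dup": (3, 4)}[polarity]
    mat = pd.DataFrame(0, index=samples, columns=probes["probe"])
    for c in calls.itertuples(index=False):
        if c.cn not in classes:
            continue
        for p in probes.itertuples(index=False):
            if p.chrom == c.chrom and c.start <= p.pos <= c.end:
                mat.loc[c.sample, p.probe] = 1
    return mat


class TestBuildProbeMatrix:
    def test_deletion_call_marks_spanned_probes_only(self):
        calls = make_calls([("s1", "chr1", 150, 450, 1, 5)])
        M = pa.build_probe_matrix(calls, GRID_PROBES, "del", samples=["s1", "s2"])
        assert M.loc["s1"].tolist() == [0, 1, 1, 1] + [0] * 6
        assert M.loc["s2"].sum() == 0
        assert pa.build_probe_matrix(calls, GRID_PROBES, "dup",
                                     samples=["s1", "s2"]).to_numpy().sum() == 0

    def test_boundary_probes_included(self):
        calls = make_calls([("s1", "chr1", 200, 400, 3, 5)])
        M = pa.build_probe_matrix(calls, GRID_PROBES, "dup", samples=["s1"])
        assert M.loc["s1", "p2"] == 1 and M.loc["s1", "p4"] == 1
        assert M.loc["s1", "p1"] == 0 and M.loc["s1", "p5"] == 0

    def test_matches_triple_loop_oracle(self, rng):
        probes = make_probes(
            [(f"c{c}_p{i}", f"chr{c}", int(pos)) for c in (1, 2)
             for i, pos in enumerate(np.sort(rng.choice(np.arange(1, 6000), 25,
                                                        replace=False)))])
        for _ in range(10):
            calls = random_calls(rng, 30)
            samples = sorted(set(calls["sample"]))
            for pol in ("del", "dup"):
                got = pa.build_probe_matrix(calls, probes, pol, samples=samples)
                want = triple_loop_matrix(calls, probes, pol, samples)
                np.testing.assert_array_equal(got.to_numpy(), want.to_numpy())

    def test_empty_probe_map_rejected(self):
        calls = make_calls([("s1", "chr1", 1, 100, 1, 5)])
        with pytest.raises(ValueError):
            pa.build_probe_matrix(calls, make_probes([]), "del")


class TestBnKinship:
    def test_two_sample_hand_value(self):
        M = pd.DataFrame({"p1": [0, 1]}, index=["a", "b"])
        K = pa.bn_kinship(M)
        np.testing.assert_allclose(K, [[1, -1], [-1, 1]])

    def test_duplicated_samples_identical_rows(self, rng):
        X = rng.integers(0, 2, (5, 40))
        X[1] = X[0]
        K = pa.bn_kinship(pd.DataFrame(X)).to_numpy()
        np.testing.assert_allclose(K[0], K[1])
        np.testing.assert_allclose(K[:, 0], K[:, 1])

    def test_probe_order_invariance(self, rng):
        X = pd.DataFrame(rng.integers(0, 2, (8, 30)))
        perm = rng.permutation(30)
        pd.testing.assert_frame_equal(pa.bn_kinship(X), pa.bn_kinship(X.iloc[:, perm]))

    def test_diagonal_mean_near_one_many_probes(self, rng):
        # under independent binomial probes E[K_ii] = 1
        p = rng.uniform(0.1, 0.9, 3000)
        X = (rng.random((40, 3000)) < p).astype(int)
        K = pa.bn_kinship(pd.DataFrame(X))
        assert np.diag(K).mean() == pytest.approx(1.0, abs=0.05)

    def test_monomorphic_only_rejected(self):
        M = pd.DataFrame({"p1": [1, 1], "p2": [0, 0]})
        with pytest.raises(ValueError):
            pa.bn_kinship(M)


def random_structured(rng, n=60, n_probes=80, noise=1.0):
    cluster = rng.integers(0, 3, n)
    p = rng.uniform(0.2, 0.8, n_probes)
    off = rng.normal(0, 1.0, (3, n_probes))
    logit = np.log(p / (1 - p))[None, :] + off[cluster]
    M = pd.DataFrame((rng.random((n, n_probes)) < 1 / (1 + np.exp(-logit))).astype(int))
    keep = M.std() > 0
    M = M.loc[:, keep]
    K = pa.bn_kinship(M)
    g = rng.normal(size=n)
    u = np.linalg.cholesky(K + 1e-6 * np.eye(n)) @ g
    y = u + noise * rng.normal(size=n)
    return y, M, K


class TestEmmaReml:
    def test_delta_matches_dense_grid_oracle(self, rng):
        y, M, K = random_structured(rng, noise=0.5)
        fit = pa.emma_reml_fit(y, K)
        grid = np.linspace(-10, 10, 1001)
        vals = [pa.reml_loglik(g, fit.reml_eigvals, fit.reml_eta2) for g in grid]
        best = grid[int(np.argmax(vals))]
        assert abs(np.log(fit.delta) - best) <= (grid[1] - grid[0]) + 1e-9

    def test_block_structure_gives_small_delta(self):
        rng = np.random.default_rng(2)
        n = 60
        cluster = np.repeat(np.arange(3), n // 3)
        K = pd.DataFrame((cluster[:, None] == cluster[None, :]).astype(float)
                         + 0.05 * np.eye(n))
        y = np.array([0.0, 3.0, -2.5])[cluster] + 0.05 * rng.normal(size=n)
        fit = pa.emma_reml_fit(y, K)
        assert fit.delta < 0.1  # genetic variance dominates

    def test_variance_components_positive(self, rng):
        y, M, K = random_structured(rng)
        fit = pa.emma_reml_fit(y, K)
        assert fit.sigma_g2 > 0 and fit.sigma_e2 >= 0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pa.emma_reml_fit(np.zeros(4), np.eye(3))


class TestMlmScan:
    def test_identity_kinship_equals_ols(self, rng):
        n = 50
        M = pd.DataFrame(rng.integers(0, 2, (n, 20)),
                         columns=[f"p{j}" for j in range(20)])
        M = M.loc[:, M.std() > 0]
        y = rng.normal(size=n)
        res = pa.mlm_scan(y, M, K=np.eye(n))
        for j, probe in enumerate(M.columns):
            ols = stats.linregress(M[probe].to_numpy(dtype=float), y)
            assert res.loc[res["probe"] == probe, "p"].iloc[0] == pytest.approx(
                ols.pvalue, abs=1e-8)

    def test_constant_probe_skipped(self, rng):
        n = 30
        M = pd.DataFrame({"const": np.ones(n, dtype=int),
                          "var": rng.integers(0, 2, n)})
        res = pa.mlm_scan(rng.normal(size=n), M, K=np.eye(n))
        assert res.set_index("probe").loc["const", "status"] == "skipped"
        assert res.set_index("probe").loc["var", "status"] == "ok"

    def test_permuted_response_p_uniform(self, rng):
        y, M, K = random_structured(rng, n=80, n_probes=300, noise=2.0)
        yp = rng.permutation(y)
        res = pa.mlm_scan(yp, M, K=K)
        ks = stats.kstest(res.loc[res["status"] == "ok", "p"], "uniform")
        assert ks.pvalue > 0.01

    def test_planted_probe_has_smallest_p(self, rng):
        y, M, K = random_structured(rng, n=80, n_probes=100, noise=1.0)
        target = M.columns[5]
        y = y + 3.0 * M[target].to_numpy()
        res = pa.mlm_scan(y, M, K=K)
        assert res.loc[res["p"].idxmin(), "probe"] == target

    def test_covariates_consume_df(self, rng):
        y, M, K = random_structured(rng, n=40, n_probes=30)
        cov = rng.normal(size=(40, 2))
        res = pa.mlm_scan(y, M, K=K, covariates=cov)
        assert res["p"].notna().any()


class TestLogisticScan:
    def test_matches_probewise_logistic_wald(self, rng):
        from cnvclim import gea
        n = 60
        M = pd.DataFrame(rng.integers(0, 2, (n, 5)),
                         columns=[f"p{j}" for j in range(5)])
        rad = rng.normal(size=n)
        res = pa.logistic_scan(M, rad).set_index("probe")
        for probe in M.columns:
            y = M[probe].to_numpy(dtype=float)
            if len(np.unique(y)) < 2:
                assert res.loc[probe, "status"] == "skipped"
                continue
            fit = gea.logistic_wald(y, rad)
            if fit.usable:
                assert res.loc[probe, "p"] == pytest.approx(fit.p, rel=1e-12)

    def test_constant_probe_skipped(self, rng):
        M = pd.DataFrame({"c": np.ones(20, dtype=int)})
        res = pa.logistic_scan(M, rng.normal(size=20))
        assert (res["status"] == "skipped").all()


class TestConsensusProbes:
    def setup_method(self):
        self.a = pd.DataFrame({"probe": ["p1", "p2", "p3"],
                               "p": [1e-5, 1e-3, 1e-6]})
        self.b = pd.DataFrame({"probe": ["p1", "p2", "p3"],
                               "p": [1e-6, 1e-6, 0.5]})

    def test_intersection(self):
        assert pa.consensus_probes(self.a, self.b) == {"p1"}

    def test_identical_tables(self):
        both = pa.consensus_probes(self.a, self.a, thr_a=5e-4, thr_b=5e-4)
        assert both == {"p1", "p3"}

    def test_disjoint_empty(self):
        b = pd.DataFrame({"probe": ["p9"], "p": [1e-9]})
        assert pa.consensus_probes(self.a, b) == set()


class TestMergeProbesToRegions:
    def test_three_consecutive_probes_form_region(self):
        pvals = pd.Series([0.5, 1e-5, 1e-6, 1e-5, 0.5],
                          index=[f"p{i}" for i in range(1, 6)])
        probes = make_probes([(f"p{i}", "chr1", 1000 * i) for i in range(1, 6)])
        out = pa.merge_probes_to_regions(pvals, probes, p_thr=5e-4)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["start"], row["end"], row["n_probes"]) == (2000, 4000, 3)
        assert row["p_min"] == 1e-6

    def test_two_probes_below_minimum(self):
        pvals = pd.Series([1e-6, 1e-6, 0.5], index=["p1", "p2", "p3"])
        probes = make_probes([("p1", "chr1", 100), ("p2", "chr1", 200),
                              ("p3", "chr1", 300)])
        assert len(pa.merge_probes_to_regions(pvals, probes, p_thr=5e-4)) == 0

    def test_chromosomes_never_merge(self):
        pvals = pd.Series([1e-6] * 6, index=[f"p{i}" for i in range(6)])
        probes = make_probes([(f"p{i}", f"chr{1 + i // 3}", 100 * (i % 3 + 1))
                              for i in range(6)])
        out = pa.merge_probes_to_regions(pvals, probes, p_thr=5e-4)
        assert len(out) == 2 and set(out["chrom"]) == {"chr1", "chr2"}

    def test_gap_splits_runs(self):
        pvals = pd.Series([1e-6] * 6, index=[f"p{i}" for i in range(6)])
        probes = make_probes([(f"p{i}", "chr1", pos) for i, pos in
                              enumerate([1, 2, 3, 5_000_000, 5_000_001, 5_000_002])])
        out = pa.merge_probes_to_regions(pvals, probes, p_thr=5e-4, max_gap_bp=1e6)
        assert len(out) == 2


@pytest.fixture(scope="module")
def scan_setup():
    rng = np.random.default_rng(31)
    y, M, K = random_structured(rng, n=60, n_probes=120, noise=1.0)
    y = y + 2.5 * M[M.columns[10]].to_numpy()
    probes = make_probes([(p, "chr1", 1000 * (j + 1))
                          for j, p in enumerate(M.columns)])
    scan = pa.mlm_scan(y, M, K=K)
    regions = pa.merge_probes_to_regions(scan.set_index("probe")["p"],
                                         probes, p_thr=0.01, min_probes=1)
    return y, M, K, regions


class TestMaxtAdjust:
    def test_adjusted_p_floor_and_monotonicity(self, scan_setup):
        y, M, K, regions = scan_setup
        out = pa.maxt_adjust(regions, y, M, K=K, B=200, seed=1)
        assert (out["p_adj"] >= 1 / 201 - 1e-12).all()
        ordered = out.sort_values("max_stat")
        assert (ordered["p_adj"].diff().dropna() <= 1e-12).all()

    def test_seeded_reproducibility(self, scan_setup):
        y, M, K, regions = scan_setup
        a = pa.maxt_adjust(regions, y, M, K=K, B=150, seed=7)
        b = pa.maxt_adjust(regions, y, M, K=K, B=150, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_region_table_passthrough(self, scan_setup):
        y, M, K, _ = scan_setup
        empty = pa.merge_probes_to_regions(
            pd.Series(1.0, index=M.columns),
            make_probes([(p, "chr1", 1000 * (j + 1)) for j, p in enumerate(M.columns)]),
            p_thr=1e-10)
        out = pa.maxt_adjust(empty, y, M, K=K, B=10, seed=0)
        assert len(out) == 0 and "p_adj" in out.columns

    def test_b_must_be_positive(self, scan_setup):
        y, M, K, regions = scan_setup
        with pytest.raises(ValueError):
            pa.maxt_adjust(regions, y, M, K=K, B=0, seed=0)
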