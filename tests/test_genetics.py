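import numpy as np
import pandas as pd
import pytest
from scipy import stats

from optimet.cgm import DEFAULT_BOUNDS
from optimet.genetics import (
    GenotypeData,
    assign_qtl,
    detection_power,
    gblup_predict,
    mlm_scan,
    simulate_genotypes,
    vanraden_kinship,
)


@pytest.fixture(scope="module")
def panel_500():
    return simulate_genotypes(500, n_chrom=2, markers_per_chrom=100, chrom_length_cM=200.0, seed=0)


def _r2(a, b):
    return np.corrcoef(a, b)[0, 1] ** 2


class TestSimulateGenotypes:
    def test_deterministic_and_binary(self):
        a = simulate_genotypes(50, 2, 30, 100.0, seed=7)
        b = simulate_genotypes(50, 2, 30, 100.0, seed=7)
        assert np.array_equal(a.matrix, b.matrix)
        assert set(np.unique(a.matrix)) <= {0, 1}

    def test_no_monomorphic_markers(self, panel_500):
        freq = panel_500.matrix.mean(axis=0)
        assert np.all((freq > 0) & (freq < 1))

    def test_zero_distance_markers_in_complete_ld(self):
        genos = simulate_genotypes(200, 1, 6, 1e-9, seed=1)
        for m in range(1, genos.n_markers):
            assert _r2(genos.matrix[:, 0], genos.matrix[:, m]) == pytest.approx(1.0)

    def test_ld_decays_with_map_distance(self, panel_500):
        g = panel_500
        chrom1 = g.map.chrom == 1
        pos = g.map.pos_cM[chrom1].to_numpy()
        X = g.matrix[:, chrom1.to_numpy()]
        near, far = [], []
        rng = np.random.default_rng(3)
        for _ in range(800):
            i, j = rng.integers(len(pos), size=2)
            if i == j:
                continue
            d = abs(pos[i] - pos[j])
            r2 = _r2(X[:, i], X[:, j])
            if d < 5:
                near.append(r2)
            elif d >= 50:
                far.append(r2)
        assert np.mean(far) < 0.05
        assert np.mean(near) > 0.3

    def test_allele_frequencies_cover_a_spectrum(self, panel_500):
        maf = np.minimum(panel_500.matrix.mean(axis=0), 1 - panel_500.matrix.mean(axis=0))
        assert maf.min() >= 0.01
        assert maf.max() > 0.3
        assert np.std(maf) > 0.05


class TestAssignQtl:
    def test_geometric_effect_ratio(self, panel_500):
        arch, _ = assign_qtl(panel_500, DEFAULT_BOUNDS, ratio=0.9, seed=2)
        for name in DEFAULT_BOUNDS.names:
            eff = np.abs(arch.qtl[name].effect.to_numpy())
            assert np.allclose(eff[:-1] / eff[1:], 1 / 0.9)

    def test_equal_effects_when_ratio_is_one(self, panel_500):
        arch, _ = assign_qtl(panel_500, DEFAULT_BOUNDS, ratio=1.0, seed=3)
        eff = np.abs(arch.qtl["VAI"].effect.to_numpy())
        assert np.allclose(eff, eff[0])

    def test_values_span_the_margin_trimmed_bounds(self, panel_500):
        arch, _ = assign_qtl(panel_500, DEFAULT_BOUNDS, seed=4)
        for s, name in enumerate(DEFAULT_BOUNDS.names):
            lo = DEFAULT_BOUNDS.lower[s] + 0.05 * DEFAULT_BOUNDS.ranges[s]
            hi = DEFAULT_BOUNDS.upper[s] - 0.05 * DEFAULT_BOUNDS.ranges[s]
            vals = arch.true_values[name]
            assert vals.min() == pytest.approx(lo, abs=1e-12)
            assert vals.max() == pytest.approx(hi, abs=1e-12)

    def test_qtl_markers_removed_and_disjoint(self, panel_500):
        arch, pruned = assign_qtl(panel_500, DEFAULT_BOUNDS, n_qtl=25, seed=5)
        all_qtl = [m for name in DEFAULT_BOUNDS.names for m in arch.qtl[name].marker_id]
        assert len(all_qtl) == len(set(all_qtl)) == 75
        assert pruned.n_markers == panel_500.n_markers - 75
        assert not set(all_qtl) & set(pruned.marker_ids)

    def test_too_few_markers_rejected(self):
        small = simulate_genotypes(30, 1, 60, 100.0, seed=6)
        with pytest.raises(ValueError):
            assign_qtl(small, DEFAULT_BOUNDS, n_qtl=25, seed=0)


class TestVanRadenKinship:
    def test_hand_example_three_lines_four_markers(self):
        m = np.array([[0, 1, 1, 0], [1, 1, 0, 0], [0, 0, 1, 1]], dtype=np.int8)
        G = vanraden_kinship(m)
        expected = np.array([[1.0, -0.5, -0.5], [-0.5, 2.5, -2.0], [-0.5, -2.0, 2.5]])
        assert np.allclose(G, expected)
        assert np.all(np.diag(G) >= G.max(axis=1) - 1e-12)

    def test_identical_lines_share_diagonal_value(self):
        m = np.array([[0, 1, 0, 1, 1], [0, 1, 0, 1, 1], [1, 0, 1, 0, 0]], dtype=np.int8)
        G = vanraden_kinship(m)
        assert G[0, 1] == pytest.approx(G[0, 0])

    def test_positive_semidefinite_and_inbred_scaled(self, panel_500):
        G = vanraden_kinship(panel_500)
        eigvals = np.linalg.eigvalsh(G)
        assert eigvals.min() > -1e-8
        # inbred lines: mean diagonal ~ 1 + f with f ~ 1
        assert 1.5 < np.mean(np.diag(G)) < 2.6

    def test_monomorphic_only_rejected(self):
        with pytest.raises(ValueError):
            vanraden_kinship(np.ones((4, 3), dtype=np.int8))


class TestGblup:
    def test_constant_phenotype_predicts_the_constant(self, panel_500):
        G = vanraden_kinship(panel_500)
        preds = gblup_predict(np.full(100, 5.5), G, np.arange(100), np.arange(100, 140))
        assert np.allclose(preds, 5.5)

    def test_noise_free_genetic_signal_recovered_in_training(self, panel_500):
        G = vanraden_kinship(panel_500)
        rng = np.random.default_rng(8)
        u = rng.normal(0, 1, 200)
        y = G[:200, :200] @ u
        preds = gblup_predict(y, G, np.arange(200), np.arange(200))
        assert np.corrcoef(preds, y)[0, 1] > 0.99

    def test_matches_direct_mixed_model_solve_on_ten_lines(self, panel_500):
        G = vanraden_kinship(panel_500)[:14, :14]
        rng = np.random.default_rng(9)
        y = rng.normal(100, 5, 10)
        train, test = np.arange(10), np.arange(10, 14)
        preds, lam = gblup_predict(y, G, train, test, return_variance_ratio=True)
        # independent GLS/BLUP oracle at the same fitted variance ratio
        Gtt = G[np.ix_(train, train)]
        V = Gtt + lam * np.eye(10)
        Vinv = np.linalg.inv(V)
        ones = np.ones(10)
        mu = (ones @ Vinv @ y) / (ones @ Vinv @ ones)
        expected = mu + G[np.ix_(test, train)] @ Vinv @ (y - mu)
        assert np.allclose(preds, expected, atol=1e-6)

    def test_accuracy_grows_with_training_size(self, panel_500):
        arch, pruned = assign_qtl(panel_500, DEFAULT_BOUNDS, seed=10)
        G = vanraden_kinship(pruned)
        y = arch.true_values["SLDL"].to_numpy()
        test = np.arange(300, 500)
        accs = []
        for n_train in (50, 100, 200):
            accs_n = []
            for rep in range(10):
                rng = np.random.default_rng(100 + rep)
                train = rng.choice(300, n_train, replace=False)
                preds = gblup_predict(y[train], G, train, test)
                accs_n.append(np.corrcoef(preds, y[test])[0, 1])
            accs.append(np.mean(accs_n))
        assert accs[0] < accs[1] < accs[2]


@pytest.fixture(scope="module")
def scan_setup(panel_500):
    arch, pruned = assign_qtl(panel_500, DEFAULT_BOUNDS, seed=11)
    sub = GenotypeData(
        matrix=pruned.matrix[:200],
        map=pruned.map,
        line_ids=pruned.line_ids[:200],
        marker_ids=pruned.marker_ids,
    )
    G = vanraden_kinship(sub)
    return arch, sub, G


class TestMlmScan:
    def test_null_rejection_rate_under_permutation(self, scan_setup):
        arch, sub, G = scan_setup
        rng = np.random.default_rng(12)
        y = rng.permutation(arch.true_values["VAI"].to_numpy()[:200])
        small = GenotypeData(
            matrix=sub.matrix[:, :200],
            map=sub.map.iloc[:200].reset_index(drop=True),
            line_ids=sub.line_ids,
            marker_ids=sub.marker_ids[:200],
        )
        out = mlm_scan(y, small, G)
        rate = float((out.pvalue < 0.05).mean())
        assert 0.02 <= rate <= 0.09

    def test_null_pvalues_approximately_uniform(self, panel_500):
        # effectively unlinked markers (~50 cM spacing) so the 1000
        # p-values are close to independent and the KS reference applies
        genos = simulate_genotypes(200, 10, 100, 5000.0, seed=13)
        G = vanraden_kinship(genos)
        rng = np.random.default_rng(14)
        # the model's own null: a polygenic signal but no marker fixed effect
        L = np.linalg.cholesky(0.5 * G + 0.5 * np.eye(200) + 1e-8 * np.eye(200))
        y = L @ rng.normal(0, 1, 200)
        out = mlm_scan(y, genos, G)
        ks = stats.kstest(out.pvalue.to_numpy()[:1000], "uniform")
        assert ks.pvalue > 0.01

    def test_strong_simulated_qtl_is_detected(self, scan_setup):
        # leave-one-chromosome-out kinship so the polygenic term cannot
        # absorb the tested QTL itself
        _, sub, _ = scan_setup
        chrom1 = (sub.map.chrom == 1).to_numpy()
        G_loco = vanraden_kinship(sub.matrix[:, ~chrom1])
        scan_set = sub.subset_markers(np.flatnonzero(chrom1))
        rng = np.random.default_rng(15)
        x = scan_set.matrix[:, 40].astype(float)
        beta = np.sqrt(0.3 / max(x.var(), 1e-9))
        y = beta * x + rng.normal(0, np.sqrt(0.7), 200)
        out = mlm_scan(y, scan_set, G_loco)
        assert out.pvalue.iloc[40] < 1e-6

    def test_reduces_to_ols_with_identity_kinship(self):
        rng = np.random.default_rng(16)
        n, M = 80, 30
        mat = (rng.random((n, M)) < 0.4).astype(np.int8)
        genos = GenotypeData(
            matrix=mat,
            map=pd.DataFrame(
                {"marker_id": [f"m{i}" for i in range(M)], "chrom": 1, "pos_cM": np.arange(M, dtype=float)}
            ),
            line_ids=tuple(f"l{i}" for i in range(n)),
            marker_ids=tuple(f"m{i}" for i in range(M)),
        )
        y = rng.normal(0, 1, n)
        out = mlm_scan(y, genos, np.eye(n))
        # closed-form OLS oracle with normal-approximation Wald p-values
        for m in (0, 7, 19):
            x = mat[:, m].astype(float)
            X = np.column_stack([np.ones(n), x])
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
            resid = y - X @ beta
            s2 = resid @ resid / (n - 2)
            se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
            p = 2 * stats.norm.sf(abs(beta[1] / se))
            assert out.pvalue.iloc[m] == pytest.approx(p, rel=1e-6)

    def test_constant_marker_flagged_with_p_one(self):
        n = 50
        mat = np.ones((n, 3), dtype=np.int8)
        mat[:, 1] = np.arange(n) % 2
        genos = GenotypeData(
            matrix=mat,
            map=pd.DataFrame({"marker_id": ["a", "b", "c"], "chrom": 1, "pos_cM": [0.0, 1.0, 2.0]}),
            line_ids=tuple(f"l{i}" for i in range(n)),
            marker_ids=("a", "b", "c"),
        )
        out = mlm_scan(np.random.default_rng(17).normal(size=n), genos, np.eye(n))
        assert out.pvalue.iloc[0] == 1.0
        assert bool(out.constant_marker.iloc[0])
        assert not bool(out.constant_marker.iloc[1])


class TestDetectionPower:
    def _scan_frame(self, pvals, positions, chrom=1):
        return pd.DataFrame(
            {
                "marker_id": [f"m{i}" for i in range(len(pvals))],
                "chrom": chrom,
                "pos_cM": positions,
                "pvalue": pvals,
            }
        )

    def test_zero_when_nothing_significant(self):
        scan = self._scan_frame([0.5, 0.9], [10.0, 20.0])
        qtl = pd.DataFrame({"chrom": [1], "pos_cM": [10.2]})
        assert detection_power(scan, qtl) == 0.0

    def test_one_when_all_colocated_and_significant(self):
        scan = self._scan_frame([1e-10, 1e-12], [10.0, 20.0])
        qtl = pd.DataFrame({"chrom": [1, 1], "pos_cM": [10.5, 19.8]})
        assert detection_power(scan, qtl) == 1.0

    def test_hand_built_half_detected(self):
        # 4 QTL: one near a significant marker, one near only a null marker,
        # one with no marker within 1 cM, one near a significant marker on
        # the wrong chromosome
        scan = pd.DataFrame(
            {
                "marker_id": ["a", "b", "c"],
                "chrom": [1, 1, 2],
                "pos_cM": [10.0, 30.0, 50.0],
                "pvalue": [1e-9, 0.5, 1e-9],
            }
        )
        qtl = pd.DataFrame({"chrom": [1, 1, 1, 1], "pos_cM": [10.4, 30.4, 70.0, 50.0]})
        assert detection_power(scan, qtl) == 0.25
        qtl2 = pd.DataFrame({"chrom": [1, 2], "pos_cM": [10.4, 50.0]})
        assert detection_power(scan, qtl2) == 1.0

    def test_window_is_strict(self):
        scan = self._scan_frame([1e-9], [10.0])
        exactly_one = pd.DataFrame({"chrom": [1], "pos_cM": [11.0]})
        assert detection_power(scan, exactly_one, window_cM=1.0) == 0.0

    def test_empty_qtl_rejected(self):
        scan = self._scan_frame([0.5], [1.0])
        with pytest.raises(ValueError):
            detection_power(scan, pd.DataFrame(columns=["chrom", "pos_cM"]))
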