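"""Eigenvalue-dispersion statistics, PCA and loading-vector clustering."""

import numpy as np
import pandas as pd
import pytest

from innomod import (
    CANONICAL_TRAITS,
    GeneratorConfig,
    INNOMINATE_PARTITION,
    TraitPartition,
    cluster_loadings,
    correlation_matrix,
    generate_table,
    integration_report,
    pca_loadings,
    sdrel_lambda,
    sdrel_null_expectation,
)
from innomod.integration import DegenerateDataError, InsufficientDataError
from innomod.io import TableValidationError
from conftest import build_table


def random_correlation(m, n, rng):
    """Sample correlation matrix of n draws of m independent normals."""
    x = rng.standard_normal((n, m))
    return np.corrcoef(x, rowvar=False)


def equicorrelation(m, rho):
    return np.full((m, m), rho) + (1 - rho) * np.eye(m)


class TestSdrelLambda:
    def test_identity_is_zero(self):
        for m in (2, 5, 8):
            assert sdrel_lambda(np.eye(m)) == 0.0

    def test_all_ones_is_one(self):
        # eigenvalues 3, 0, 0
        assert sdrel_lambda(np.ones((3, 3))) == pytest.approx(1.0, abs=1e-12)

    def test_equicorrelation_returns_rho(self):
        # closed form: eigenvalues 1+(M-1)rho and 1-rho (x M-1)
        for m in range(2, 9):
            for rho in (0.0, 0.3, 0.5, 0.9):
                assert sdrel_lambda(equicorrelation(m, rho)) == pytest.approx(
                    rho, abs=1e-12)

    def test_half_equicorrelation_closed_form(self):
        # M=3, rho=0.5: eigenvalues 2.0, 0.5, 0.5; sum (lam-1)^2 / 6 = 0.25
        r = equicorrelation(3, 0.5)
        lam = np.sort(np.linalg.eigvalsh(r))[::-1]
        assert np.allclose(lam, [2.0, 0.5, 0.5])
        assert sdrel_lambda(r) == pytest.approx(0.5, abs=1e-12)

    def test_equals_rms_offdiagonal(self):
        """Oracle identity: SDrel == RMS off-diagonal correlation."""
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            m = int(rng.integers(2, 9))
            r = random_correlation(m, int(rng.integers(m + 2, 40)), rng)
            off = r[~np.eye(m, dtype=bool)]
            assert sdrel_lambda(r) == pytest.approx(
                np.sqrt(np.mean(off ** 2)), abs=1e-10)

    def test_invalid_matrices_rejected(self):
        bad_diag = np.array([[1.0, 0.2], [0.2, 0.9]])
        with pytest.raises(TableValidationError):
            sdrel_lambda(bad_diag)
        asym = np.array([[1.0, 0.5], [0.1, 1.0]])
        with pytest.raises(TableValidationError):
            sdrel_lambda(asym)


class TestNullExpectation:
    @pytest.mark.parametrize("n,expected", [
        (1885, 0.0163), (1967, 0.0159), (1989, 0.0159)])
    def test_reference_sample_sizes(self, n, expected):
        assert round(sdrel_null_expectation(n), 4) == expected

    def test_closed_form_small_n(self):
        assert sdrel_null_expectation(50) == pytest.approx(0.1, abs=1e-15)

    def test_decreases_with_n(self):
        vals = [sdrel_null_expectation(n) for n in (10, 100, 1000, 10_000)]
        assert vals == sorted(vals, reverse=True)

    def test_tiny_n_rejected(self):
        with pytest.raises(TableValidationError):
            sdrel_null_expectation(1)


class TestCorrelationMatrix:
    def test_perfectly_linear_pair(self):
        sa = [60.0, 62.0, 64.0, 66.0]
        t = build_table(SA=sa, SS=[2 * v for v in sa])
        r, n = correlation_matrix(t, ["SA", "SS"])
        assert n == 4
        assert r.loc["SA", "SS"] == pytest.approx(1.0, abs=1e-12)

    def test_independent_traits_near_zero(self):
        rng = np.random.default_rng(0)
        cols = {t: 100 + rng.standard_normal(10_000) for t in CANONICAL_TRAITS}
        r, _ = correlation_matrix(build_table(**cols), CANONICAL_TRAITS)
        off = r.to_numpy()[~np.eye(8, dtype=bool)]
        assert np.max(np.abs(off)) < 0.05

    def test_subset_n_exceeds_full_n(self):
        from innomod import impose_missingness

        t = impose_missingness(build_table(n=30), {"PUM": 10}, seed=1)
        _, n_full = correlation_matrix(t, CANONICAL_TRAITS)
        _, n_sub = correlation_matrix(
            t, [x for x in CANONICAL_TRAITS if x != "PUM"])
        assert n_sub > n_full

    def test_too_few_cases(self):
        with pytest.raises(InsufficientDataError):
            correlation_matrix(build_table(n=2), ["SA", "SS"])

    def test_zero_variance_named(self):
        t = build_table(SA=[70.0] * 5)
        with pytest.raises(DegenerateDataError, match="SA"):
            correlation_matrix(t, ["SA", "SS"])


class TestIntegrationReport:
    def test_planted_module_sdrel(self):
        """A 3-trait module planted at rho=0.7 scores SDrel ~ 0.7 (the
        equicorrelation value) at large n; zero dimorphism keeps the pooled
        correlation equal to the planted one."""
        cfg = GeneratorConfig(n_female=5000, n_male=5000,
                              dimorphism={t: 0.0 for t in CANONICAL_TRAITS},
                              seed=17)
        rep = integration_report(generate_table(cfg), ["PUM", "SA", "SCOX"])
        assert rep.sdrel == pytest.approx(0.7, abs=0.02)
        assert rep.n == 10_000 and rep.m == 3

    def test_independent_traits_near_null(self):
        rng = np.random.default_rng(42)
        cols = {t: 100 + rng.standard_normal(1885) for t in CANONICAL_TRAITS}
        rep = integration_report(build_table(**cols), CANONICAL_TRAITS)
        assert rep.sdrel < 3 * rep.null_expectation
        assert rep.sdrel > rep.null_expectation / 3

    def test_eigenvalues_sum_to_m(self, reference_table):
        rep = integration_report(reference_table, CANONICAL_TRAITS)
        assert sum(rep.eigenvalues) == pytest.approx(8.0, abs=1e-9)
        assert min(rep.eigenvalues) >= 0

    def test_modules_more_integrated_than_whole(self, reference_table):
        """Within-module integration exceeds whole-set integration, which
        exceeds the no-integration expectation."""
        rep_all = integration_report(reference_table, CANONICAL_TRAITS)
        for module in INNOMINATE_PARTITION.modules:
            if len(module) < 2:
                continue
            rep_mod = integration_report(reference_table, sorted(module))
            assert rep_mod.sdrel > rep_all.sdrel > rep_all.null_expectation


class TestPcaLoadings:
    def test_identity_correlation_unit_variances(self):
        rng = np.random.default_rng(7)
        cols = {t: 100 + rng.standard_normal(20_000) for t in CANONICAL_TRAITS}
        pca = pca_loadings(build_table(**cols), CANONICAL_TRAITS)
        assert np.allclose(pca.explained_variance, 1.0, atol=0.05)

    def test_trace_conserved_and_orthonormal(self, reference_table):
        pca = pca_loadings(reference_table, CANONICAL_TRAITS)
        assert sum(pca.explained_variance) == pytest.approx(8.0, abs=1e-9)
        v = pca.loadings.to_numpy()
        assert np.allclose(v.T @ v, np.eye(8), atol=1e-10)
        # sign convention: dominant entry of each column positive
        for j in range(8):
            col = v[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_row_order_invariance(self, reference_table):
        pca = pca_loadings(reference_table, CANONICAL_TRAITS)
        shuffled = reference_table.data.sample(frac=1, random_state=3)
        from innomod import OsteometricTable

        pca2 = pca_loadings(OsteometricTable(shuffled), CANONICAL_TRAITS)
        assert np.allclose(pca.loadings.to_numpy(),
                           pca2.loadings.to_numpy(), atol=1e-10)

    def test_same_module_loadings_align(self):
        """In the leading 2-PC plane, same-module loading vectors are more
        parallel than cross-module pairs (zero dimorphism, so the pooled
        correlation equals the planted block structure)."""
        table = generate_table(GeneratorConfig(
            n_female=2000, n_male=2000,
            dimorphism={t: 0.0 for t in CANONICAL_TRAITS}, seed=23))
        pca = pca_loadings(table, CANONICAL_TRAITS)
        v = pca.loadings.to_numpy()[:, :2]
        v = v / np.linalg.norm(v, axis=1, keepdims=True)
        cos = v @ v.T
        idx = {t: i for i, t in enumerate(CANONICAL_TRAITS)}
        mods = INNOMINATE_PARTITION.modules
        same = [cos[idx[a], idx[b]]
                for mod in mods for a in mod for b in mod if a < b]
        cross = [cos[idx[a], idx[b]]
                 for i in range(len(mods)) for j in range(i + 1, len(mods))
                 for a in mods[i] for b in mods[j]]
        assert min(same) > max(cross)


class TestClusterLoadings:
    def test_k_equals_m_gives_singletons(self, reference_table):
        pca = pca_loadings(reference_table, CANONICAL_TRAITS)
        part = cluster_loadings(pca.loadings, k=8, n_pcs=2)
        assert all(len(m) == 1 for m in part.modules)

    def test_identical_rows_co_cluster(self):
        loadings = pd.DataFrame(
            [[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [-1.0, 0.2]],
            index=["SA", "SS", "PUM", "DCOX"], columns=["PC1", "PC2"])
        for k in (2, 3):
            part = cluster_loadings(loadings, k=k, n_pcs=2)
            module_of = {t: i for i, m in enumerate(part.modules) for t in m}
            assert module_of["SA"] == module_of["SS"]

    def test_invalid_k_rejected(self, reference_table):
        pca = pca_loadings(reference_table, CANONICAL_TRAITS)
        with pytest.raises(TableValidationError):
            cluster_loadings(pca.loadings, k=9)


class TestTraitPartition:
    def test_normalised_equality(self):
        a = TraitPartition(modules=(frozenset({"A"}), frozenset({"B", "C"})))
        b = TraitPartition(modules=(frozenset({"C", "B"}), frozenset({"A"})))
        assert a == b

    def test_overlap_rejected(self):
        with pytest.raises(TableValidationError):
            TraitPartition(modules=(frozenset({"A", "B"}), frozenset({"B"})))

    def test_empty_module_rejected(self):
        with pytest.raises(TableValidationError):
            TraitPartition(modules=(frozenset(), frozenset({"A"})))

    def test_round_trips_through_dict(self):
        d = INNOMINATE_PARTITION.to_dict()
        assert TraitPartition.from_dict(d) == INNOMINATE_PARTITION
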