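import numpy as np
import pytest

from hybridgp.kernels import (
    IncidenceMatrix,
    KernelSpec,
    arc_cosine_kernel,
    arc_cosine_scalar,
    build_kernel,
    ensure_psd,
    expand_kernel,
    gaussian_kernel,
    hybrid_kernel,
    interaction_kernel,
)
from hybridgp.markers import KernelMatrix, MarkerMatrix


def _std(rows, ids=None):
    rows = np.asarray(rows, float)
    ids = ids or [f"i{k}" for k in range(rows.shape[0])]
    return MarkerMatrix(ids=ids, dosages=rows, missing_mask=np.zeros_like(rows, bool),
                        state="standardized")


class TestGaussianKernel:
    def test_identical_rows_give_one(self):
        w = _std([[1.0, -1.0], [1.0, -1.0], [0.0, 2.0]])
        k = gaussian_kernel(w, gamma=1.0)
        assert k.values[0, 1] == pytest.approx(1.0)
        assert np.allclose(np.diag(k.values), 1.0)

    def test_small_gamma_limit_is_all_ones(self):
        w = _std(np.random.default_rng(0).standard_normal((4, 6)))
        k = gaussian_kernel(w, gamma=1e-12)
        assert np.allclose(k.values, 1.0, atol=1e-10)

    def test_hand_computed_three_point_case(self):
        # pairwise squared distances {2, 2, 8}; mean d^2 = 4
        w = _std([[0.0, 0.0], [1.0, 1.0], [-1.0, -1.0]])
        k = gaussian_kernel(w, gamma=1.0)
        assert k.values[0, 1] == pytest.approx(np.exp(-2 / 4))
        assert k.values[0, 2] == pytest.approx(np.exp(-2 / 4))
        assert k.values[1, 2] == pytest.approx(np.exp(-8 / 4))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        w = rng.standard_normal((6, 10))
        perm = rng.permutation(6)
        k1 = gaussian_kernel(_std(w)).values
        k2 = gaussian_kernel(_std(w[perm])).values
        assert np.allclose(k2, k1[np.ix_(perm, perm)])

    def test_identical_dataset_warns_to_ones(self):
        w = _std([[1.0, 0.0], [1.0, 0.0]])
        assert np.allclose(gaussian_kernel(w).values, 1.0)


class TestArcCosineKernel:
    def test_matches_scalar_closed_form(self):
        rng = np.random.default_rng(11)
        w = _std(rng.standard_normal((12, 9)))
        k = arc_cosine_kernel(w, layers=1, degree=1)
        # undo the mean-diagonal rescaling to compare raw values
        raw = np.array([[arc_cosine_scalar(a, b) for b in w.dosages] for a in w.dosages])
        scale = np.diag(raw).mean()
        assert np.allclose(k.values, raw / scale, atol=1e-10)

    def test_identical_unit_rows_any_depth(self):
        v = np.array([0.6, 0.8])
        w = _std([v, v])
        for layers in (1, 2, 3, 4):
            k = arc_cosine_kernel(w, layers=layers)
            assert k.values[0, 1] == pytest.approx(1.0)

    def test_orthogonal_unit_rows_single_layer(self):
        # J1(pi/2) = 1 -> raw kernel 1/pi; diagonals are 1 so rescaling is identity
        w = _std([[1.0, 0.0], [0.0, 1.0]])
        k = arc_cosine_kernel(w, layers=1)
        assert k.values[0, 1] == pytest.approx(1 / np.pi)

    def test_antiparallel_unit_rows(self):
        w = _std([[1.0, 0.0], [-1.0, 0.0]])
        assert arc_cosine_kernel(w, layers=1).values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_zero_norm_row_is_reported(self):
        w = _std([[0.0, 0.0], [1.0, 1.0]], ids=["bad", "ok"])
        with pytest.raises(ValueError, match="bad"):
            arc_cosine_kernel(w)

    def test_deeper_layers_stay_psd_with_unit_mean_diagonal(self):
        rng = np.random.default_rng(5)
        w = _std(rng.standard_normal((10, 20)))
        for layers in (1, 2, 3, 4):
            k = arc_cosine_kernel(w, layers=layers)
            assert np.diag(k.values).mean() == pytest.approx(1.0)
            assert np.linalg.eigvalsh(k.values)[0] >= -1e-8


class TestKernelSpecDispatch:
    def test_linear_is_gblup_g(self, small_sim):
        from hybridgp.markers import genomic_relationship, qc_pipeline

        w = qc_pipeline(small_sim.males)
        assert np.allclose(build_kernel(w, KernelSpec("linear")).values,
                           genomic_relationship(w).values)

    def test_ac_name_sets_layers(self):
        assert KernelSpec("AC_3").layers == 3

    def test_invalid_name_rejected(self):
        with pytest.raises(ValueError):
            KernelSpec("cubic")


class TestComposition:
    def test_expand_identity_kernel_marks_same_level(self):
        z = IncidenceMatrix.from_levels(["o1", "o2", "o3"], ["a", "b", "a"])
        k = KernelMatrix(ids=["a", "b"], values=np.eye(2))
        out = expand_kernel(z, k).values
        assert out[0, 2] == 1.0 and out[0, 1] == 0.0

    def test_expand_matches_per_entry_lookup(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((3, 4))
        k = KernelMatrix(ids=["a", "b", "c"], values=x @ x.T)
        levels = ["b", "a", "c", "a", "b"]
        z = IncidenceMatrix.from_levels([f"o{j}" for j in range(5)], levels)
        out = expand_kernel(z, k).values
        pos = {l: j for j, l in enumerate(k.ids)}
        for i in range(5):
            for j in range(5):
                assert out[i, j] == pytest.approx(k.values[pos[levels[i]], pos[levels[j]]])

    def test_hybrid_kernel_identity_parents(self):
        # same male, different females, identity parental kernels -> H entry 0
        z_m = IncidenceMatrix.from_levels(["h1", "h2"], ["m1", "m1"])
        z_f = IncidenceMatrix.from_levels(["h1", "h2"], ["f1", "f2"])
        g_i = KernelMatrix(ids=["m1"], values=np.eye(1))
        g_f = KernelMatrix(ids=["f1", "f2"], values=np.eye(2))
        h = hybrid_kernel(z_m, g_i, z_f, g_f)
        assert h.values[0, 1] == 0.0
        assert h.values[0, 0] == 1.0

    def test_hybrid_kernel_is_elementwise_product(self):
        rng = np.random.default_rng(9)
        xm, xf = rng.standard_normal((3, 5)), rng.standard_normal((4, 5))
        g_m = KernelMatrix(ids=["m0", "m1", "m2"], values=xm @ xm.T)
        g_f = KernelMatrix(ids=["f0", "f1", "f2", "f3"], values=xf @ xf.T)
        males = ["m0", "m2", "m1", "m0"]
        females = ["f1", "f1", "f3", "f2"]
        hybrids = [f"h{j}" for j in range(4)]
        h = hybrid_kernel(
            IncidenceMatrix.from_levels(hybrids, males, g_m.ids),
            g_m,
            IncidenceMatrix.from_levels(hybrids, females, g_f.ids),
            g_f,
        )
        km = expand_kernel(IncidenceMatrix.from_levels(hybrids, males, g_m.ids), g_m).values
        kf = expand_kernel(IncidenceMatrix.from_levels(hybrids, females, g_f.ids), g_f).values
        assert np.allclose(h.values, km * kf)

    def test_interaction_kernel_masks_across_years(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((4, 3))
        k = KernelMatrix(ids=[f"o{j}" for j in range(4)], values=x @ x.T)
        z_e = IncidenceMatrix.from_levels(k.ids, ["1", "1", "2", "2"])
        v = interaction_kernel(k, z_e).values
        assert v[0, 2] == 0.0 and v[0, 3] == 0.0
        assert v[0, 1] == pytest.approx(k.values[0, 1])
        one_year = IncidenceMatrix.from_levels(k.ids, ["1"] * 4)
        assert np.allclose(interaction_kernel(k, one_year).values, k.values)


class TestEnsurePsd:
    def test_psd_input_unchanged(self):
        k = KernelMatrix(ids=["a", "b"], values=np.eye(2))
        assert ensure_psd(k) is k

    def test_indefinite_matrix_inflated(self):
        k = KernelMatrix(ids=["a", "b"], values=np.array([[1.0, 1.2], [1.2, 1.0]]))
        out = ensure_psd(k)
        assert np.linalg.eigvalsh(out.values)[0] >= -1e-8
        assert np.allclose(out.values - k.values, np.diag(np.diag(out.values - k.values)))


def test_hadamard_products_of_psd_factors_are_psd():
    """Schur product theorem exercised over 200 random kernel pairs."""
    rng = np.random.default_rng(123)
    for _ in range(200):
        n = rng.integers(2, 7)
        a = rng.standard_normal((n, n + 1))
        b = rng.standard_normal((n, n + 2))
        had = (a @ a.T) * (b @ b.T)
        assert np.linalg.eigvalsh(had)[0] >= -1e-8
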