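"""Tensor assembly, Hadamard powers, normalizations, aa-level split."""

import numpy as np
import pytest

from protriform.metrics import get_duplex
from protriform.structure_io import ProteinGeometry
from protriform.tensor import (DegenerateTensorError, HadamardDomainError,
                               MissingMetricError, TDSM, TensorMeta,
                               aa_tensor, build_tdsm, dump_tsv, hadamard_power,
                               load_tsv, normalize_mp, normalize_ss)


def _tensor(values):
    return TDSM(values=np.asarray(values, dtype=float))


@pytest.fixture(scope="module")
def tri_geom():
    # right triangle with unit-spaced sequence positions
    pts = np.array([[0.0, 0, 0], [3.0, 0, 0], [0.0, 4, 0]])
    return ProteinGeometry(representation="CA", codes="AGS", points=pts,
                           mass_center=pts.mean(axis=0),
                           chain_ids=("A", "A", "A"),
                           residue_numbers=(1, 2, 3))


class TestBuild:
    def test_distinct_triple_is_perimeter(self, tri_geom):
        t = build_tdsm(tri_geom, "SUM", "euclidean")
        assert t.values[0, 1, 2] == pytest.approx(12.0)

    def test_repeated_pair_complete_uses_duplex(self, tri_geom):
        t = build_tdsm(tri_geom, "SUM", "euclidean")
        assert t.values[0, 0, 1] == pytest.approx(3.0)  # d(1,2)

    def test_repeated_pair_non_complete_zero(self, tri_geom):
        t = build_tdsm(tri_geom, "SUM", "euclidean",
                       completeness="non-complete")
        assert t.values[0, 0, 1] == 0.0
        assert t.values[0, 1, 2] == pytest.approx(12.0)

    def test_aa_mode_diagonal_zero(self, tri_geom):
        t = build_tdsm(tri_geom, "SUM", "euclidean")
        assert all(t.values[i, i, i] == 0.0 for i in range(3))

    def test_center_mode_diagonal_nonzero(self, tri_geom):
        t = build_tdsm(tri_geom, "SUM", "euclidean", reference_mode="center")
        for i in range(3):
            expected = np.linalg.norm(tri_geom.points[i]
                                      - tri_geom.mass_center)
            assert t.values[i, i, i] == pytest.approx(expected)
            assert t.values[i, i, i] > 0

    def test_complete_without_metric_errors(self, tri_geom):
        with pytest.raises(MissingMetricError):
            build_tdsm(tri_geom, "SUM", None)

    def test_bond_angle_exempt_from_metric(self, tri_geom):
        t = build_tdsm(tri_geom, "ANGLE", None)
        assert t.values[0, 1, 2] > 0
        assert t.values[0, 0, 1] == 0.0

    def test_symmetric_recipe_gives_permutation_invariant_tensor(self, geom5):
        t = build_tdsm(geom5, "SUM", "euclidean")
        v = t.values
        for perm in ((0, 2, 1), (1, 0, 2), (2, 1, 0), (1, 2, 0), (2, 0, 1)):
            np.testing.assert_allclose(v, np.transpose(v, perm), atol=1e-10)

    def test_metadata_recorded(self, tri_geom):
        t = build_tdsm(tri_geom, "M59", "M1", completeness="non-complete")
        assert t.meta.multi_metric == "SUM"
        assert t.meta.duplex_metric == "euclidean"
        assert t.meta.completeness == "non-complete"
        assert t.meta.power == 1.0
        assert t.meta.normalization == "NS"


class TestHadamard:
    def test_square(self):
        t = hadamard_power(_tensor(np.full((3, 3, 3), 3.0)), 2)
        assert t.values[0, 0, 0] == 9.0

    def test_reciprocal_and_zero_preservation(self):
        v = np.zeros((3, 3, 3))
        v[0, 0, 0] = 2.0
        t = hadamard_power(_tensor(v), -1)
        assert t.values[0, 0, 0] == 0.5
        assert t.values[1, 1, 1] == 0.0

    def test_power_zero(self):
        v = np.zeros((3, 3, 3))
        v[0, 1, 2] = 5.0
        t = hadamard_power(_tensor(v), 0)
        assert t.values[0, 1, 2] == 1.0
        assert t.values[0, 0, 0] == 0.0

    @pytest.mark.parametrize("k", range(-12, 13))
    def test_zero_support_fixed_for_every_power(self, k):
        rng = np.random.default_rng(3)
        v = rng.uniform(0.5, 2.0, size=(4, 4, 4))
        v[rng.random(v.shape) < 0.4] = 0.0
        t = hadamard_power(_tensor(v), k)
        np.testing.assert_array_equal(t.values == 0.0, v == 0.0)

    def test_reciprocal_product_identity(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(0.2, 4.0, size=(4, 4, 4))
        v[0, 0, 0] = 0.0
        for k in (1, 2, 3, 5):
            a = hadamard_power(_tensor(v), k).values
            b = hadamard_power(_tensor(v), -k).values
            prod = a * b
            nz = v != 0
            np.testing.assert_allclose(prod[nz], 1.0, atol=1e-9)
            assert np.all(prod[~nz] == 0.0)

    def test_non_integer_power_of_negative_entries(self):
        v = np.full((3, 3, 3), -2.0)
        with pytest.raises(HadamardDomainError):
            hadamard_power(_tensor(v), 0.5)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            hadamard_power(_tensor(np.ones((3, 3, 3))), 13)


class TestNormalize:
    def test_ss_slices_sum_to_one(self):
        rng = np.random.default_rng(1)
        t = normalize_ss(_tensor(rng.uniform(0.1, 2, size=(5, 5, 5))))
        np.testing.assert_allclose(t.values.sum(axis=(1, 2)), 1.0,
                                   atol=1e-12)
        assert t.meta.normalization == "SS"

    def test_ss_zero_slice_unchanged(self):
        v = np.zeros((2, 2, 2))
        v[1] = 0.25
        t = normalize_ss(_tensor(v))
        assert np.all(t.values[0] == 0.0)
        np.testing.assert_allclose(t.values[1].sum(), 1.0)

    def test_ss_uniform_slice(self):
        v = np.zeros((2, 2, 2))
        v[0] = 1.0
        t = normalize_ss(_tensor(v))
        np.testing.assert_allclose(t.values[0], 0.25)

    def test_mp_grand_total_one(self):
        rng = np.random.default_rng(2)
        t = normalize_mp(_tensor(rng.uniform(0, 3, size=(4, 4, 4))))
        assert t.values.sum() == pytest.approx(1.0, abs=1e-12)

    def test_mp_single_entry(self):
        v = np.zeros((3, 3, 3))
        v[1, 2, 0] = 7.5
        t = normalize_mp(_tensor(v))
        assert t.values[1, 2, 0] == 1.0

    def test_mp_uniform(self):
        t = normalize_mp(_tensor(np.full((3, 3, 3), 4.0)))
        np.testing.assert_allclose(t.values, 1.0 / 27.0)

    def test_mp_degenerate(self):
        with pytest.raises(DegenerateTensorError):
            normalize_mp(_tensor(np.zeros((3, 3, 3))))

    def test_normalization_rejects_normalized_input(self):
        t = normalize_mp(_tensor(np.ones((3, 3, 3))))
        with pytest.raises(ValueError):
            normalize_ss(t)
        with pytest.raises(ValueError):
            hadamard_power(t, 2)


class TestAaDecomposition:
    def test_weight_rules(self):
        v = np.ones((3, 3, 3))
        part = aa_tensor(_tensor(v), 2).values
        assert part[1, 1, 1] == 1.0              # all three indices match
        assert part[1, 1, 0] == pytest.approx(2 / 3)
        assert part[0, 1, 2] == pytest.approx(1 / 3)
        assert part[0, 0, 2] == 0.0              # no index matches

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            aa_tensor(_tensor(np.ones((3, 3, 3))), 4)

    @pytest.mark.parametrize("n", [3, 7, 20])
    def test_exact_decomposition_random_tensors(self, n):
        rng = np.random.default_rng(n)
        v = rng.normal(size=(n, n, n))
        t = _tensor(v)
        total = sum(aa_tensor(t, aa).values for aa in range(1, n + 1))
        np.testing.assert_allclose(total, v, atol=1e-12)


def test_order_of_operations_power_before_normalization(tri_geom=None):
    # SS(power(Z)) differs from power(SS(Z)); the pipeline uses the former
    rng = np.random.default_rng(9)
    v = rng.uniform(0.5, 2.0, size=(4, 4, 4))
    path_a = normalize_ss(hadamard_power(_tensor(v), 2)).values
    ss_first = _tensor(v).values / _tensor(v).values.sum(axis=(1, 2),
                                                         keepdims=True)
    path_b = ss_first ** 2
    assert not np.allclose(path_a, path_b)
    np.testing.assert_allclose(path_a.sum(axis=(1, 2)), 1.0, atol=1e-12)


def test_tsv_dump_roundtrip(tmp_path, geom5):
    t = build_tdsm(geom5, "AREA", "manhattan", reference_mode="center")
    path = tmp_path / "tensor.tsv"
    dump_tsv(t, path)
    t2 = load_tsv(path)
    np.testing.assert_array_equal(t2.values, t.values)
    assert t2.meta == t.meta
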