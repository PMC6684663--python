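"""Duplex metrics and ternary multi-metrics against closed forms."""

import math

import numpy as np
import pytest

from protriform.metrics import (UndefinedAngleError, UnknownMetricError,
                                duplex_distance, duplex_for_tensor,
                                get_duplex, get_multi, list_multi_metrics,
                                make_context, multi_metric)

P0 = np.zeros(3)
P345 = np.array([3.0, 4.0, 0.0])

RIGHT = (np.array([0.0, 0.0, 0.0]), np.array([3.0, 0.0, 0.0]),
         np.array([0.0, 4.0, 0.0]))  # sides 3 (XY), 5 (YZ), 4 (ZX)


class TestDuplex:
    @pytest.mark.parametrize("metric,expected", [
        ("euclidean", 5.0),
        ("manhattan", 7.0),
        ("chebyshev", 4.0),
    ])
    def test_345_triangle(self, metric, expected):
        assert duplex_distance(P0, P345, metric) == pytest.approx(expected)

    def test_minkowski_infinity_is_chebyshev(self):
        assert duplex_distance(P0, P345, "minkowski", math.inf) == \
            pytest.approx(4.0)

    def test_minkowski_order_interpolates(self):
        d3 = duplex_distance(P0, P345, "minkowski", 3.0)
        assert 4.0 < d3 < 5.0
        assert d3 == pytest.approx((3 ** 3 + 4 ** 3) ** (1 / 3))

    @pytest.mark.parametrize("metric", [
        "euclidean", "manhattan", "chebyshev", "minkowski", "canberra",
        "wave-edge", "soergel", "lance-williams"])
    def test_symmetric_nonnegative_and_identity(self, metric):
        rng = np.random.default_rng(42)
        for _ in range(20):
            u, v = rng.normal(size=(2, 3)) * 10
            d = duplex_distance(u, v, metric)
            assert d >= 0
            assert d == pytest.approx(duplex_distance(v, u, metric))
            assert duplex_distance(u, u, metric) == 0.0
            assert duplex_distance(u, v, metric) > 0  # distinct points

    def test_id_aliases(self):
        assert get_duplex("M1").name == "euclidean"
        assert get_duplex("M2").name == "euclidean"
        assert get_duplex("M15").name == "lance-williams"
        with pytest.raises(UnknownMetricError):
            get_duplex("M99")


class TestClosedForms:
    def ctx(self, pts=RIGHT, metric="euclidean"):
        return make_context(*pts, metric=metric)

    def test_triangle_area_345(self):
        assert multi_metric(self.ctx(), "AREA") == pytest.approx(6.0)

    def test_area_equals_cross_product_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            X, Y, Z = rng.normal(size=(3, 3)) * 5
            area = multi_metric(make_context(X, Y, Z), "AREA")
            oracle = np.linalg.norm(np.cross(X - Y, Z - Y)) / 2
            assert area == pytest.approx(oracle, abs=1e-9)

    def test_incircle_identity(self):
        ctx = self.ctx()
        area = multi_metric(ctx, "AREA")
        s = ctx.semiperimeter
        assert multi_metric(ctx, "INCIRCLE") == \
            pytest.approx(math.pi * (area / s) ** 2, abs=1e-9)

    def test_degenerate_triangle_zero_areas(self):
        collinear = (np.zeros(3), np.array([1.0, 0, 0]), np.array([2.0, 0, 0]))
        assert multi_metric(self.ctx(collinear), "AREA") == 0.0
        assert multi_metric(self.ctx(collinear), "INCIRCLE") == 0.0

    def test_sum_rule_perimeter(self):
        assert multi_metric(self.ctx(), "SUM") == pytest.approx(12.0)

    def test_summation_sides_two_sides_only(self):
        # d_XY + d_YZ = 3 + 5, as tabulated (not the full perimeter)
        assert multi_metric(self.ctx(), "SUMSIDES") == pytest.approx(8.0)

    def test_bond_angle_orthogonal(self):
        ctx = make_context(np.array([1.0, 0, 0]), np.zeros(3),
                           np.array([0.0, 1.0, 0]))
        assert multi_metric(ctx, "ANGLE") == pytest.approx(math.pi / 2)

    def test_bond_angle_zero_side_error(self):
        ctx = make_context(np.zeros(3), np.zeros(3), np.array([1.0, 0, 0]))
        with pytest.raises(UndefinedAngleError):
            multi_metric(ctx, "ANGLE")

    def test_ave_rule(self):
        # (d_XZ + d_YZ)/2 = (4 + 5)/2
        assert multi_metric(self.ctx(), "AVE") == pytest.approx(4.5)

    def test_min_max_rules_use_z_sides(self):
        assert multi_metric(self.ctx(), "MIN") == pytest.approx(4.0)
        assert multi_metric(self.ctx(), "MAX") == pytest.approx(5.0)

    def test_join_rule_middle_side(self):
        assert multi_metric(self.ctx(), "JOIN") == pytest.approx(4.0)

    def test_ran_rule(self):
        assert multi_metric(self.ctx(), "RAN") == pytest.approx(2.0)

    def equilateral(self, d=2.0):
        h = d * math.sqrt(3) / 2
        return (np.array([0.0, 0, 0]), np.array([d, 0, 0]),
                np.array([d / 2, h, 0]))

    def test_med_rule_equilateral(self):
        d = 3.7
        ctx = make_context(*self.equilateral(d))
        assert multi_metric(ctx, "MED") == pytest.approx(3 * d / 4, abs=1e-10)

    def test_adj_rule_equilateral_zero(self):
        ctx = make_context(*self.equilateral(1.9))
        assert multi_metric(ctx, "ADJ") == pytest.approx(0.0, abs=1e-10)

    def test_lc_rule_identical_points(self):
        p = np.array([1.0, 2.0, 3.0])
        ctx = make_context(p, p.copy(), p.copy())
        assert multi_metric(ctx, "LC") == pytest.approx(1.0)

    def test_add_rule_topology(self):
        ctx = make_context(*RIGHT, positions=[1, 2, 4], chains=list("AAA"))
        expected = (3.0 / 1 + 5.0 / 2 + 4.0 / 3) / 3
        assert multi_metric(ctx, "ADD") == pytest.approx(expected)

    def test_add_rule_chain_break_drops_pair(self):
        ctx = make_context(*RIGHT, positions=[1, 2, 3], chains=list("AAB"))
        expected = (3.0 / 1 + 0.0 + 0.0) / 3  # YZ and ZX cross the break
        assert multi_metric(ctx, "ADD") == pytest.approx(expected)

    def test_qua_geo_power_means(self):
        ctx = self.ctx()
        assert multi_metric(ctx, "QUA") == \
            pytest.approx(math.sqrt((9 + 16 + 25) / 3))
        assert multi_metric(ctx, "GEO") == \
            pytest.approx(((27 + 64 + 125) / 3) ** (1 / 3))
        assert multi_metric(ctx, "PRO") == pytest.approx(60.0)


class TestSymmetryContracts:
    @pytest.mark.parametrize("spec", [s for s in list_multi_metrics()
                                      if s.symmetry == "S"],
                             ids=lambda s: s.name)
    def test_s_flagged_invariant_under_all_permutations(self, spec):
        import itertools
        rng = np.random.default_rng(7)
        for _ in range(10):
            pts = rng.normal(size=(3, 3)) * 8
            pos = sorted(rng.choice(np.arange(1, 30), size=3, replace=False))
            vals = []
            for perm in itertools.permutations(range(3)):
                ctx = make_context(pts[perm[0]], pts[perm[1]], pts[perm[2]],
                                   positions=[pos[perm[0]], pos[perm[1]],
                                              pos[perm[2]]],
                                   chains=list("AAA"))
                vals.append(multi_metric(ctx, spec))
            assert max(vals) - min(vals) < 1e-10, spec.name

    @pytest.mark.parametrize("spec", [
        s for s in list_multi_metrics()
        if s.family in ("geometric", "cluster", "operator")],
        ids=lambda s: s.name)
    def test_rigid_motion_invariance(self, spec):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(13)
        for _ in range(5):
            pts = rng.normal(size=(3, 3)) * 6
            ref = multi_metric(make_context(*pts, positions=[1, 3, 6],
                                            chains=list("AAA")), spec)
            for _ in range(5):
                R = Rotation.random(random_state=rng.integers(2 ** 16)).as_matrix()
                t = rng.normal(size=3) * 20
                moved = pts @ R.T + t
                val = multi_metric(make_context(*moved, positions=[1, 3, 6],
                                                chains=list("AAA")), spec)
                assert val == pytest.approx(ref, abs=1e-9), spec.name


class TestDuplexForTensor:
    def test_aa_mode_diagonal_zero(self, geom5):
        m = get_duplex("euclidean")
        assert duplex_for_tensor(geom5.points, (1, 1, 1), m, "aa",
                                 geom5.mass_center) == 0.0

    def test_aa_mode_pair(self, geom5):
        m = get_duplex("euclidean")
        d = duplex_for_tensor(geom5.points, (0, 0, 3), m, "aa",
                              geom5.mass_center)
        assert d == pytest.approx(np.linalg.norm(geom5.points[0]
                                                 - geom5.points[3]))

    def test_center_mode_diagonal_measures_to_center(self, geom5):
        m = get_duplex("euclidean")
        d = duplex_for_tensor(geom5.points, (2, 2, 2), m, "center",
                              geom5.mass_center)
        assert d == pytest.approx(np.linalg.norm(geom5.points[2]
                                                 - geom5.mass_center))
        assert d > 0

    def test_center_mode_repeated_residue_to_center(self, geom5):
        m = get_duplex("euclidean")
        d = duplex_for_tensor(geom5.points, (4, 1, 4), m, "center",
                              geom5.mass_center)
        assert d == pytest.approx(np.linalg.norm(geom5.points[4]
                                                 - geom5.mass_center))

    def test_all_distinct_rejected(self, geom5):
        m = get_duplex("euclidean")
        with pytest.raises(ValueError):
            duplex_for_tensor(geom5.points, (0, 1, 2), m, "aa",
                              geom5.mass_center)


def test_registry_listing_covers_tabulated_ids():
    specs = list_multi_metrics()
    ids = {i for s in specs for i in s.ids}
    assert ids == {f"M{n}" for n in range(33, 77)}
    families = {s.family for s in specs}
    assert families == {"geometric", "cluster", "operator", "agreement"}
    assert not get_multi("ANGLE").needs_duplex
    assert all(s.needs_duplex for s in specs if s.name != "ANGLE")
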