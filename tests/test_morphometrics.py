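import math

import numpy as np
import pytest

import oracles
from rhizomorph.morphometrics import (
    bifurcation_angles,
    count_tips_bifurcations,
    cover_area,
    max_euclidean,
    rgu,
    summarize,
    surface_area,
    total_length,
)
from rhizomorph.swc import Node, RHIZOID, THALLUS, TracedTree


def _rotated(tree, angle_deg, axis="z"):
    a = math.radians(angle_deg)
    if axis == "z":
        R = np.array([[math.cos(a), -math.sin(a), 0], [math.sin(a), math.cos(a), 0], [0, 0, 1]])
    else:
        R = np.array([[1, 0, 0], [0, math.cos(a), -math.sin(a)], [0, math.sin(a), math.cos(a)]])
    coords = tree.coords @ R.T + np.array([3.0, -2.0, 1.0])
    return TracedTree.from_arrays(tree.ids, tree.labels, coords, tree.radii, tree.parent_ids)


def _scaled(tree, k):
    return TracedTree.from_arrays(
        tree.ids, tree.labels, tree.coords * k, tree.radii, tree.parent_ids
    )


class TestToyYHandValues:
    def test_total_length(self, toy_y):
        assert total_length(toy_y) == pytest.approx(30.0, abs=1e-12)

    def test_tips_and_bifurcations(self, toy_y):
        assert count_tips_bifurcations(toy_y) == (2, 1)

    def test_rgu_both_methods(self, toy_y):
        assert rgu(toy_y, "ratio") == pytest.approx(15.0)
        assert rgu(toy_y, "segment") == pytest.approx(10.0)

    def test_max_euclidean(self, toy_y):
        assert max_euclidean(toy_y) == pytest.approx(math.sqrt(360.0))

    def test_bifurcation_angle(self, toy_y):
        (angle,) = bifurcation_angles(toy_y)
        assert angle == pytest.approx(math.degrees(math.acos(0.28)), abs=1e-9)

    def test_cover_area(self, toy_y):
        assert cover_area(toy_y) == pytest.approx(108.0)

    def test_summary_is_consistent_and_deterministic(self, toy_y):
        rec = summarize(toy_y)
        assert rec.total_length == pytest.approx(30.0)
        assert (rec.n_tips, rec.n_bifurcations) == (2, 1)
        assert rec.rgu_ratio == pytest.approx(15.0)
        assert rec.cover_area == pytest.approx(108.0)
        assert summarize(toy_y) == rec


class TestClosedForms:
    def test_cylinder_lateral_area(self):
        tree = TracedTree(
            [
                Node(1, THALLUS, 0, 0, 0, 0.5, -1),
                Node(2, RHIZOID, 10, 0, 0, 0.5, 1),
            ]
        )
        assert surface_area(tree) == pytest.approx(10 * math.pi)

    def test_frustum_lateral_area(self):
        tree = TracedTree(
            [
                Node(1, THALLUS, 0, 0, 0, 2.0, -1),
                Node(2, RHIZOID, 10, 0, 0, 0.5, 1),
            ]
        )
        slant = math.sqrt(10**2 + 1.5**2)
        assert surface_area(tree) == pytest.approx(math.pi * 2.5 * slant)

    def test_zero_radii_zero_area(self, toy_y):
        zeroed = TracedTree.from_arrays(
            toy_y.ids, toy_y.labels, toy_y.coords, np.zeros(len(toy_y)), toy_y.parent_ids
        )
        assert surface_area(zeroed) == 0.0

    @pytest.mark.parametrize(
        "d1, d2, expected",
        [((0, 1, 0), (0, -1, 0), 180.0), ((1, 0, 0), (0, 1, 0), 90.0)],
        ids=["antiparallel", "perpendicular"],
    )
    def test_angle_limits(self, d1, d2, expected):
        tree = TracedTree(
            [
                Node(1, THALLUS, 0, 0, 0, 1.0, -1),
                Node(2, RHIZOID, 0, 0, 1, 0.5, 1),
                Node(3, RHIZOID, 0 + d1[0], 0 + d1[1], 1 + d1[2], 0.5, 2),
                Node(4, RHIZOID, 0 + d2[0], 0 + d2[1], 1 + d2[2], 0.5, 2),
            ]
        )
        (angle,) = bifurcation_angles(tree)
        assert angle == pytest.approx(expected, abs=1e-9)


class TestDegenerateInputs:
    def test_root_only_zeros(self):
        tree = TracedTree([Node(1, THALLUS, 0, 0, 0, 2.0, -1)])
        rec = summarize(tree)
        assert rec.total_length == 0.0
        assert rec.n_tips == 0 and rec.n_bifurcations == 0
        assert rec.max_euclidean == 0.0 and rec.cover_area == 0.0
        assert math.isnan(rec.rgu_segment) and math.isnan(rec.mean_bif_angle)

    def test_unbranched_filament(self):
        nodes = [Node(1, THALLUS, 0, 0, 0, 1.0, -1)] + [
            Node(i, RHIZOID, float(i - 1), 0, 0, 0.5, i - 1) for i in range(2, 11)
        ]
        tree = TracedTree(nodes)
        assert count_tips_bifurcations(tree) == (1, 0)
        assert math.isnan(rgu(tree, "segment"))
        assert cover_area(tree) == 0.0  # collinear hull degenerates

    def test_unknown_rgu_method_rejected(self, toy_y):
        with pytest.raises(ValueError):
            rgu(toy_y, "median")


class TestInvariances:
    @pytest.fixture(scope="class")
    def trees(self):
        from conftest import make_random_tree

        rng = np.random.default_rng(42)
        return [make_random_tree(rng, int(n)) for n in rng.integers(5, 120, size=10)]

    def test_isometry_invariance(self, trees):
        for tree in trees:
            rot = _rotated(tree, 73.5, axis="z")
            rec, rec2 = summarize(tree), summarize(rot)
            for name in (
                "total_length", "n_tips", "n_bifurcations", "rgu_ratio",
                "surface_area", "max_euclidean", "cover_area",
            ):
                np.testing.assert_allclose(
                    getattr(rec2, name), getattr(rec, name), rtol=1e-9, atol=1e-9
                )
            a1, a2 = bifurcation_angles(tree), bifurcation_angles(rot)
            np.testing.assert_allclose(sorted(a2), sorted(a1), rtol=1e-9, atol=1e-9)

    def test_scaling_covariance(self, trees):
        k = 2.0
        for tree in trees[:5]:
            a, b = summarize(tree), summarize(_scaled(tree, k))
            assert b.total_length == pytest.approx(k * a.total_length, rel=1e-9)
            assert b.cover_area == pytest.approx(k**2 * a.cover_area, rel=1e-9)
            assert b.max_euclidean == pytest.approx(k * a.max_euclidean, rel=1e-9)
            assert (b.n_tips, b.n_bifurcations) == (a.n_tips, a.n_bifurcations)

    def test_monotone_under_branch_addition(self, trees):
        rng = np.random.default_rng(0)
        for tree in trees[:5]:
            before = summarize(tree)
            nid = int(tree.ids.max()) + 1
            host = int(rng.choice(tree.ids))
            host_pos = tree.coords[tree.row_of(host)]
            new = Node(nid, RHIZOID, float(host_pos[0] + 30), float(host_pos[1] + 30),
                       float(host_pos[2]), 0.5, host)
            grown = TracedTree(tree.nodes + [new])
            after = summarize(grown)
            assert after.total_length >= before.total_length
            assert after.n_tips >= before.n_tips
            assert after.cover_area >= before.cover_area

    def test_binary_tree_tip_bifurcation_identity(self):
        # strictly binary random growth: tips = bifurcations + 1
        from rhizomorph.simulator import GrowthParams, simulate

        params = GrowthParams(
            branch_rate=20.0, lateral_prob=0.0, duration=2.0, dt=0.02, seed=5
        )
        series, _ = simulate(params)
        tips, bifs = count_tips_bifurcations(series.trees[-1])
        assert tips == bifs + 1


def test_oracle_equivalence_small_sample(random_tree_factory):
    """Spot-check against the brute-force oracle (full suite in acceptance)."""
    rng = np.random.default_rng(11)
    for _ in range(10):
        tree = random_tree_factory(rng, int(rng.integers(2, 150)))
        assert total_length(tree) == pytest.approx(oracles.naive_total_length(tree), rel=1e-9)
        assert count_tips_bifurcations(tree) == oracles.naive_tips_bifurcations(tree)
        assert surface_area(tree) == pytest.approx(oracles.naive_surface_area(tree), rel=1e-9)
        assert max_euclidean(tree) == pytest.approx(oracles.naive_max_euclidean(tree), rel=1e-9)
        assert cover_area(tree) == pytest.approx(oracles.naive_cover_area(tree), rel=1e-9)
        np.testing.assert_allclose(
            sorted(bifurcation_angles(tree)),
            sorted(oracles.naive_bifurcation_angles(tree)),
            rtol=1e-9,
            atol=1e-9,
        )
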