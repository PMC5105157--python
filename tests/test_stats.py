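"""Bray–Curtis, NMDS, Pearson and MNI-scaling behaviour."""

import math

import numpy as np
import pytest

from sedaprof.stats import (
    bray_curtis,
    correlate_profiles,
    dissimilarity_matrix,
    kruskal_stress,
    nmds,
    pearson,
    scale_mni,
)


class TestBrayCurtis:
    def test_identity(self):
        assert bray_curtis([3, 1, 2], [3, 1, 2]) == 0.0

    def test_disjoint_supports(self):
        assert bray_curtis([5, 0, 0], [0, 2, 7]) == 1.0

    def test_worked_formula(self):
        assert bray_curtis([6, 2, 0], [2, 2, 4]) == pytest.approx(
            1 - 2 * 4 / 16
        )

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            u = rng.integers(0, 20, size=6)
            v = rng.integers(0, 20, size=6)
            if u.sum() + v.sum() == 0:
                continue
            d = bray_curtis(u, v)
            assert d == pytest.approx(bray_curtis(v, u))
            assert 0 <= d <= 1

    def test_scale_sensitivity(self):
        # doubling one vector changes the dissimilarity (not a metric on
        # relative composition)
        assert bray_curtis([6, 2, 0], [2, 2, 4]) != pytest.approx(
            bray_curtis([12, 4, 0], [2, 2, 4])
        )

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])


class TestNMDS:
    def test_three_equidistant_layers_embed_exactly(self):
        d = np.full((3, 3), 0.6)
        np.fill_diagonal(d, 0.0)
        res = nmds(d, seed=1, restarts=5)
        assert res.stress < 1e-3

    def test_duplicated_profiles_coincide(self):
        base = np.array(
            [[0, 0.7, 0.7, 0.2], [0.7, 0, 0.3, 0.7], [0.7, 0.3, 0, 0.7],
             [0.2, 0.7, 0.7, 0]]
        )
        # layers 1 and 2 are duplicates (distance 0.0 after relabeling)
        d = base.copy()
        d[1, 2] = d[2, 1] = 0.0
        res = nmds(d, seed=2, restarts=10)
        gap = np.linalg.norm(res.coords[1] - res.coords[2])
        others = np.linalg.norm(res.coords[0] - res.coords[3])
        assert gap < 0.05 * max(others, 1e-9)

    def test_beats_random_layouts(self):
        rng = np.random.default_rng(7)
        vecs = rng.integers(0, 30, size=(6, 8)).astype(float)
        d = dissimilarity_matrix(vecs)
        res = nmds(d, seed=3, restarts=20)
        random_best = min(
            kruskal_stress(d, rng.normal(size=(6, 2))) for _ in range(100)
        )
        assert res.stress <= random_best

    def test_too_few_layers(self):
        with pytest.raises(ValueError):
            nmds(np.zeros((2, 2)), seed=0)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(1)
        vecs = rng.integers(0, 10, size=(5, 6)).astype(float)
        d = dissimilarity_matrix(vecs)
        a = nmds(d, seed=5, restarts=4)
        b = nmds(d, seed=5, restarts=4)
        assert a.stress == b.stress
        assert np.array_equal(a.coords, b.coords)


class TestPearson:
    def test_perfect_linearity(self):
        res = pearson([1, 2, 3, 4], [3, 5, 7, 9])
        assert res.rho == pytest.approx(1.0)
        assert res.p_two_sided == 0.0

    def test_permutation_decorrelates(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=2000)
        y = rng.permutation(x)
        res = pearson(x, y)
        assert abs(res.rho) < 3 / math.sqrt(2000)

    def test_small_table_against_exact_arithmetic(self):
        from fractions import Fraction as F

        x = [2, 3, 5, 7, 11]
        y = [1, 4, 4, 6, 9]
        fx = [F(v) for v in x]
        fy = [F(v) for v in y]
        mx, my = sum(fx) / 5, sum(fy) / 5
        num = sum((a - mx) * (b - my) for a, b in zip(fx, fy))
        den2 = sum((a - mx) ** 2 for a in fx) * sum((b - my) ** 2 for b in fy)
        exact_r = float(num) / math.sqrt(float(den2))
        res = pearson(x, y)
        assert res.rho == pytest.approx(exact_r, abs=1e-12)
        # p from the t transform on n-2 df
        from scipy import stats as sps

        t = exact_r * math.sqrt(3 / (1 - exact_r**2))
        assert res.p_two_sided == pytest.approx(2 * sps.t.sf(abs(t), 3))

    @pytest.mark.parametrize("x,y", [([1, 2], [3, 4]), ([1, 1, 1], [1, 2, 3])])
    def test_preconditions(self, x, y):
        with pytest.raises(ValueError):
            pearson(x, y)


class TestMNIScaling:
    def test_published_excavated_fraction(self):
        scaled, factor = scale_mni(1.0, 0.087)
        assert factor == 11.5

    def test_full_excavation_identity(self):
        scaled, factor = scale_mni({"seal": 12}, 1.0)
        assert factor == 1.0
        assert scaled == {"seal": 12}

    def test_quarter(self):
        _, factor = scale_mni(0, 0.25)
        assert factor == 4.0


class TestCorrelateProfiles:
    def test_proportional_counts(self):
        biomass = {"a": 10.0, "b": 20.0, "c": 40.0, "d": 5.0}
        counts = {k: 3 * v for k, v in biomass.items()}
        res = correlate_profiles(counts, biomass)
        assert res.rho == pytest.approx(1.0)
        assert res.p_two_sided == 0.0

    def test_too_few_shared_species(self):
        with pytest.raises(ValueError):
            correlate_profiles({"a": 1, "b": 2}, {"a": 3, "z": 4})

    def test_excluded_species_reported(self):
        counts = {"a": 1, "b": 2, "c": 3, "x": 9}
        ref = {"a": 2, "b": 1, "c": 5, "y": 7}
        res = correlate_profiles(counts, ref)
        assert set(res.excluded) == {"x", "y"}
        assert res.n == 3

    def test_noisy_generative_recovery(self):
        rng = np.random.default_rng(21)
        biomass = {f"sp{i}": float(v) for i, v in
                   enumerate([400, 150, 90, 30, 12, 5])}
        total = sum(biomass.values())
        draws = rng.multinomial(20_000, [v / total for v in biomass.values()])
        counts = {k: int(n) for k, n in zip(biomass, draws)}
        res = correlate_profiles(counts, biomass)
        assert res.rho > 0.99
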