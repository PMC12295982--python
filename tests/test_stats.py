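"""Wasserstein EE/EED statistics against independent transport oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import linprog

from rinse import (
    DEFAULT_EED_CUTOFFS,
    EEDDistribution,
    EEDistribution,
    HeatKernelEmbedding,
    ResidueIndexMap,
    eed,
    ee_distribution,
    embedding_error,
    max_ee_analysis,
    min_ee_analysis,
    regional_summary,
    wasserstein_1d,
)
from rinse.embedding import EmbeddingCloud


def sorted_oracle(a, b):
    """Equal-size first Wasserstein: mean |diff| of sorted samples."""
    return float(np.mean(np.abs(np.sort(a) - np.sort(b))))


def transport_lp_oracle(a, b):
    """Exhaustive optimal-transport linear program between empirical samples."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    cost = np.abs(a[:, None] - b[None, :]).ravel()
    A_eq = []
    b_eq = []
    for i in range(na):  # row marginals: uniform mass 1/na
        row = np.zeros(na * nb)
        row[i * nb : (i + 1) * nb] = 1.0
        A_eq.append(row)
        b_eq.append(1.0 / na)
    for j in range(nb):  # column marginals: uniform mass 1/nb
        col = np.zeros(na * nb)
        col[j::nb] = 1.0
        A_eq.append(col)
        b_eq.append(1.0 / nb)
    res = linprog(cost, A_eq=np.array(A_eq), b_eq=np.array(b_eq), method="highs")
    assert res.success
    return float(res.fun)


finite_floats = st.floats(-50, 50, allow_nan=False, allow_infinity=False)


class TestWasserstein:
    def test_identical_samples_zero(self, rng):
        a = rng.normal(size=20)
        assert wasserstein_1d(a, a) == 0.0

    def test_translation_property(self, rng):
        a = rng.normal(size=30)
        assert wasserstein_1d(a, a + 2.5) == pytest.approx(2.5, abs=1e-12)

    def test_sorted_pair_example(self):
        assert wasserstein_1d([0, 1], [1, 2]) == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wasserstein_1d([], [1.0])

    @given(
        st.lists(finite_floats, min_size=1, max_size=6),
        st.lists(finite_floats, min_size=1, max_size=6),
    )
    def test_matches_transport_lp(self, a, b):
        assert wasserstein_1d(a, b) == pytest.approx(
            transport_lp_oracle(a, b), abs=1e-9
        )

    @given(
        st.lists(finite_floats, min_size=4, max_size=4),
        st.lists(finite_floats, min_size=4, max_size=4),
    )
    def test_matches_sorted_oracle_equal_sizes(self, a, b):
        assert wasserstein_1d(a, b) == pytest.approx(sorted_oracle(a, b), abs=1e-12)


def make_cloud(coords, construct, basis_source="ref"):
    im = ResidueIndexMap(tuple(range(1, coords.shape[0] + 1)))
    return EmbeddingCloud(coords, construct, im, centered=True, basis_source=basis_source)


@pytest.fixture
def cloud_pair(rng):
    u = make_cloud(rng.normal(size=(6, 15, 3)), "U")
    v = make_cloud(rng.normal(size=(6, 15, 3)), "V")
    return u, v


class TestEmbeddingError:
    def test_self_comparison_zero(self, cloud_pair):
        u, _ = cloud_pair
        dist = ee_distribution(u, u)
        assert (dist.values == 0).all()
        assert len(dist.values) == u.index_map.size

    def test_translation_per_axis(self, cloud_pair):
        u, _ = cloud_pair
        shifted = make_cloud(u.coords + np.array([0.7, 0.0, 0.0]), "V")
        for res in u.index_map.labels:
            assert embedding_error(u, shifted, res) == pytest.approx(0.7, abs=1e-12)

    def test_symmetry(self, cloud_pair):
        u, v = cloud_pair
        for res in (1, 4, 6):
            assert embedding_error(u, v, res) == pytest.approx(
                embedding_error(v, u, res), abs=1e-12
            )

    def test_triangle_inequality(self, rng):
        u = make_cloud(rng.normal(size=(4, 10, 3)), "U")
        v = make_cloud(rng.normal(size=(4, 10, 3)), "V")
        w = make_cloud(rng.normal(size=(4, 10, 3)), "W")
        for res in u.index_map.labels:
            duv = embedding_error(u, v, res)
            dvw = embedding_error(v, w, res)
            duw = embedding_error(u, w, res)
            assert duw <= duv + dvw + 1e-12

    def test_mismatched_basis_rejected(self, rng):
        u = make_cloud(rng.normal(size=(4, 8, 3)), "U", basis_source="a")
        v = make_cloud(rng.normal(size=(4, 8, 3)), "V", basis_source="b")
        with pytest.raises(ValueError, match="bases"):
            embedding_error(u, v, 1)

    def test_aggregate_modes(self, cloud_pair):
        u, v = cloud_pair
        s = embedding_error(u, v, 1, aggregate="sum")
        m = embedding_error(u, v, 1, aggregate="mean")
        p = embedding_error(u, v, 1, aggregate="pc1")
        assert s == pytest.approx(3 * m)
        assert p <= s


class TestEED:
    def series(self, vals):
        return pd.Series(vals, index=range(1, len(vals) + 1))

    def test_arithmetic(self):
        a = EEDistribution(("MUT", "d"), self.series([0.5, 0.5]))
        b = EEDistribution(("WT", "d"), self.series([0.2, 0.7]))
        v = eed(a, b)
        assert v.values.tolist() == pytest.approx([0.3, -0.2])

    def test_equal_inputs_zero(self):
        a = EEDistribution(("MUT", "d"), self.series([0.4, 0.1]))
        assert (eed(a, a).values == 0).all()

    def test_swap_negates(self):
        a = EEDistribution(("MUT", "d"), self.series([0.5, 0.1]))
        b = EEDistribution(("WT", "d"), self.series([0.2, 0.3]))
        np.testing.assert_allclose(eed(a, b).values, -eed(b, a).values)

    def test_residue_mismatch_rejected(self):
        a = EEDistribution(("MUT", "d"), self.series([0.5, 0.1]))
        b = EEDistribution(("WT", "d"), pd.Series([0.2], index=[9]))
        with pytest.raises(ValueError):
            eed(a, b)


class TestMinMaxAnalysis:
    def dists(self, mat, names):
        idx = range(1, mat.shape[0] + 1)
        return [
            EEDistribution(("WT", nm), pd.Series(mat[:, k], index=idx))
            for k, nm in enumerate(names)
        ]

    def test_strict_dominance(self):
        mat = np.array([[0.1, 0.5], [0.2, 0.9], [0.3, 0.4]])
        _, src, prc = min_ee_analysis(self.dists(mat, ["a", "b"]))
        assert (src == "WT_a").all()
        assert prc.tolist() == [100.0, 0.0]

    def test_ties_go_to_earliest(self):
        mat = np.array([[0.5, 0.5], [0.5, 0.5]])
        _, src, _ = min_ee_analysis(self.dists(mat, ["a", "b"]))
        assert (src == "WT_a").all()
        _, src, _ = max_ee_analysis(self.dists(mat, ["a", "b"]))
        assert (src == "WT_a").all()

    def test_matches_brute_force_argmin_argmax(self, rng):
        mat = rng.random((30, 4))
        dists = self.dists(mat, list("abcd"))
        vmin, smin, prc_min = min_ee_analysis(dists)
        vmax, smax, prc_max = max_ee_analysis(dists)
        np.testing.assert_allclose(vmin, mat.min(axis=1))
        np.testing.assert_allclose(vmax, mat.max(axis=1))
        names = [d.name for d in dists]
        expect_min = [names[j] for j in mat.argmin(axis=1)]
        assert smin.tolist() == expect_min
        counts = pd.Series(expect_min).value_counts()
        for nm in names:
            assert prc_min[nm] == pytest.approx(counts.get(nm, 0) / 30 * 100)

    def test_prc_sums_to_100(self, rng):
        mat = rng.random((50, 5))
        _, _, prc_min = min_ee_analysis(self.dists(mat, list("abcde")))
        _, _, prc_max = max_ee_analysis(self.dists(mat, list("abcde")))
        assert prc_min.sum() == pytest.approx(100.0, abs=1e-9)
        assert prc_max.sum() == pytest.approx(100.0, abs=1e-9)

    def test_single_distribution_rejected(self, rng):
        with pytest.raises(ValueError):
            min_ee_analysis(self.dists(rng.random((5, 1)), ["a"]))


class TestRegionalSummary:
    def eedist(self, vals, idx, drug="d1"):
        return EEDDistribution(drug, pd.Series(vals, index=idx))

    def test_counting_oracle(self):
        idx = list(range(100, 110))
        vals = [0.001, 0.0001, 0.003, 0.0, 0.0025, 0.0004, 0.0, 0.0, 0.0005, 0.0]
        regions = {"A": (100, 104), "B": (105, 109)}
        pct, mean = regional_summary(
            [self.eedist(vals, idx)], regions, cutoffs=(0.0005, 0.002)
        )
        # region A: {0.001, 0.0001, 0.003, 0.0, 0.0025}: 3/5 >= 5e-4, 2/5 >= 2e-3
        assert pct.loc["A", 0.0005] == pytest.approx(60.0)
        assert pct.loc["A", 0.002] == pytest.approx(40.0)
        # region B: only 0.0005 clears the first cutoff
        assert pct.loc["B", 0.0005] == pytest.approx(20.0)
        assert pct.loc["B", 0.002] == pytest.approx(0.0)
        assert mean.loc["A", "d1"] == pytest.approx(np.mean(vals[:5]))

    def test_region_fully_above_cutoff(self):
        idx = [1, 2, 3]
        pct, _ = regional_summary(
            [self.eedist([0.01, 0.02, 0.03], idx)], {"R": (1, 3)}, cutoffs=(0.0002,)
        )
        assert pct.loc["R", 0.0002] == 100.0

    def test_default_cutoffs(self):
        assert DEFAULT_EED_CUTOFFS == (0.0002, 0.0003, 0.0004, 0.0005, 0.001, 0.002)

    def test_any_mode_uses_max_across_drugs(self):
        idx = [1, 2]
        d1 = self.eedist([0.0, 0.5], idx, "d1")
        d2 = self.eedist([0.5, 0.0], idx, "d2")
        pct, _ = regional_summary([d1, d2], {"R": (1, 2)}, cutoffs=(0.1,), mode="any")
        assert pct.loc["R", 0.1] == 100.0
        pct2, _ = regional_summary(
            [d1, d2], {"R": (1, 2)}, cutoffs=(0.1,), mode="per-drug"
        )
        assert pct2.loc[("R", "d1"), 0.1] == 50.0

    def test_region_outside_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            regional_summary(
                [self.eedist([0.1], [5])], {"R": (50, 60)}, cutoffs=(0.1,)
            )


class TestKnownAnswerPlantedPerturbation:
    def test_planted_residues_hold_largest_ee(self, tiny_spec):
        """Weakened residues dominate the EE distribution end to end."""
        from rinse import (
            PerturbationSpec,
            generate_ensemble,
            perturb_construct,
            planted_targets,
        )

        ref = generate_ensemble(tiny_spec, label="WT")
        targets = sorted(planted_targets(tiny_spec, n_targets=3))
        pert = perturb_construct(
            ref, PerturbationSpec(frozenset(targets), magnitude=0.1), label="MUT"
        )
        est = HeatKernelEmbedding().fit(ref)
        d = ee_distribution(est.transform_cloud(ref), est.transform_cloud(pert))
        top3 = set(d.values.sort_values(ascending=False).head(3).index)
        assert top3 == set(targets)
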