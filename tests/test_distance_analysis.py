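import numpy as np
import pytest

from spinscape.distance_analysis import (
    DistanceDistribution,
    default_grid,
    delta_mean,
    distribution_rmsd,
    global_rmsd,
    pairwise_distribution,
    read_distribution,
    stats,
    write_distribution,
)
from spinscape.ensemble import RotamerEnsemble

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


def _point_ensemble(centers, weights=None):
    """Minimal ensemble carrying only spin centers (coords unused here)."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    n = len(centers)
    return RotamerEnsemble(
        label="TEST", sites=(), atom_names=("X",), elements=("C",),
        dihedrals=np.zeros((n, 1)), coords=np.zeros((n, 1, 3)),
        spin_centers=centers, weights=weights,
    )


def _gaussian_distribution(mu, sigma, lo=10.0, hi=60.0, step=0.05):
    r = np.arange(lo, hi + 1e-9, step)
    p = np.exp(-0.5 * ((r - mu) / sigma) ** 2)
    return DistanceDistribution(r, p)


class TestPairwiseDistribution:
    def test_single_pair_gives_kernel_at_distance(self):
        a = _point_ensemble([[0.0, 0, 0]])
        b = _point_ensemble([[25.0, 0, 0]])
        dist = pairwise_distribution(a, b, grid=(10, 40, 0.05), smoothing=1.0)
        s = stats(dist)
        assert s.mean == pytest.approx(25.0, abs=0.05)
        assert s.fwhm == pytest.approx(FWHM_FACTOR * 1.0, rel=0.02)

    def test_two_deltas_give_equal_bimodal_peaks(self):
        a = _point_ensemble([[20.0, 0, 0], [30.0, 0, 0]])
        b = _point_ensemble([[0.0, 0, 0]])
        dist = pairwise_distribution(a, b, grid=(10, 40, 0.05), smoothing=0.5)
        s = stats(dist)
        assert s.multimodal
        i20 = np.argmin(np.abs(dist.r - 20.0))
        i30 = np.argmin(np.abs(dist.r - 30.0))
        assert dist.p[i20] == pytest.approx(dist.p[i30], rel=1e-6)
        assert s.mean == pytest.approx(25.0, abs=0.05)

    def test_mean_matches_double_loop_oracle(self, rng):
        a = _point_ensemble(rng.normal(0, 3, size=(50, 3)),
                            weights=rng.uniform(0.5, 2, 50))
        b = _point_ensemble(rng.normal(30, 3, size=(50, 3)),
                            weights=rng.uniform(0.5, 2, 50))
        dist = pairwise_distribution(a, b, grid=(5, 70, 0.1), smoothing=1.0)
        total, acc = 0.0, 0.0
        for ca, wa in zip(a.spin_centers, a.weights):
            for cb, wb in zip(b.spin_centers, b.weights):
                acc += wa * wb * np.linalg.norm(ca - cb)
                total += wa * wb
        assert dist.meta["sample_mean"] == pytest.approx(acc / total, abs=1e-6)

    def test_unit_area(self, rng):
        a = _point_ensemble(rng.normal(0, 2, size=(20, 3)))
        b = _point_ensemble(rng.normal(25, 2, size=(20, 3)))
        dist = pairwise_distribution(a, b, grid=(5, 60, 0.1))
        assert np.trapezoid(dist.p, dist.r) == pytest.approx(1.0, abs=1e-6)

    def test_joint_translation_invariance(self, rng):
        centers_a = rng.normal(0, 2, size=(10, 3))
        centers_b = rng.normal(20, 2, size=(10, 3))
        shift = np.array([7.0, -3.0, 2.0])
        d0 = pairwise_distribution(
            _point_ensemble(centers_a), _point_ensemble(centers_b), grid=(5, 50, 0.1)
        )
        d1 = pairwise_distribution(
            _point_ensemble(centers_a + shift), _point_ensemble(centers_b + shift),
            grid=(5, 50, 0.1),
        )
        np.testing.assert_allclose(d0.p, d1.p, atol=1e-12)

    def test_empty_ensemble_rejected(self):
        empty = RotamerEnsemble(
            label="E", sites=(), atom_names=(), elements=(),
            dihedrals=np.zeros((0, 1)), coords=np.zeros((0, 0, 3)),
            spin_centers=np.zeros((0, 3)),
        )
        with pytest.raises(ValueError, match="empty"):
            pairwise_distribution(empty, _point_ensemble([[0, 0, 0]]))

    def test_grid_clipping_is_an_error(self):
        a = _point_ensemble([[0.0, 0, 0]])
        b = _point_ensemble([[200.0, 0, 0]])  # far outside the default grid
        with pytest.raises(ValueError, match="widen the grid"):
            pairwise_distribution(a, b, grid=(10, 100, 0.5))


class TestStats:
    def test_gaussian_closed_form(self):
        dist = _gaussian_distribution(30.0, 2.0)
        s = stats(dist)
        assert s.mean == pytest.approx(30.0, abs=0.05)
        assert s.width == pytest.approx(2.0, rel=0.02)
        assert s.fwhm == pytest.approx(FWHM_FACTOR * 2.0, rel=0.02)
        assert not s.multimodal

    def test_single_bin_delta(self):
        r = np.arange(10.0, 40.0, 0.5)
        p = np.zeros_like(r)
        p[np.argmin(np.abs(r - 25.0))] = 1.0
        s = stats(DistanceDistribution(r, p))
        assert s.mean == pytest.approx(25.0, abs=1e-9)
        assert s.width < 0.5  # below one grid step

    def test_bimodal_mixture_mean(self):
        r = np.arange(10.0, 50.0 + 1e-9, 0.02)
        p = 0.5 * np.exp(-0.5 * ((r - 25) / 1.0) ** 2) + 0.5 * np.exp(
            -0.5 * ((r - 35) / 1.0) ** 2
        )
        s = stats(DistanceDistribution(r, p))
        assert s.mean == pytest.approx(30.0, abs=0.02)
        assert s.multimodal

    def test_resampling_shifts_mean_less_than_step(self):
        fine = _gaussian_distribution(30.0, 2.0, step=0.02)
        coarse_r = np.arange(10.0, 60.0 + 1e-9, 0.5)
        coarse = DistanceDistribution(
            coarse_r, np.interp(coarse_r, fine.r, fine.p)
        )
        assert abs(stats(coarse).mean - stats(fine).mean) < 0.5

    def test_all_zero_density_rejected(self):
        r = np.arange(10.0, 20.0, 0.5)
        with pytest.raises(ValueError):
            DistanceDistribution(r, np.zeros_like(r))


class TestDeltaMean:
    def test_identical_zero_and_signed_offset(self):
        a = stats(_gaussian_distribution(30.0, 2.0))
        b = stats(_gaussian_distribution(32.0, 2.0))
        assert delta_mean(a, a) == 0.0
        assert delta_mean(b, a) == pytest.approx(2.0, abs=0.01)

    def test_antisymmetry(self):
        a = stats(_gaussian_distribution(28.0, 1.5))
        b = stats(_gaussian_distribution(33.0, 2.5))
        assert delta_mean(a, b) == pytest.approx(-delta_mean(b, a))


class TestDistributionRmsd:
    def test_self_is_zero(self):
        d = _gaussian_distribution(30.0, 2.0)
        assert distribution_rmsd(d, d) == 0.0

    def test_symmetry(self):
        a = _gaussian_distribution(28.0, 2.0)
        b = _gaussian_distribution(33.0, 3.0)
        assert distribution_rmsd(a, b) == pytest.approx(distribution_rmsd(b, a))

    def test_matches_quadrature_oracle(self):
        # two unit-area Gaussians on one shared grid: the rmsd must equal
        # an independent direct evaluation of sqrt(mean((pa-pb)^2))
        r = np.arange(10.0, 60.0 + 1e-9, 0.05)

        def unit_gauss(mu, sigma):
            p = np.exp(-0.5 * ((r - mu) / sigma) ** 2) / (
                sigma * np.sqrt(2 * np.pi)
            )
            return p / np.trapezoid(p, r)

        pa, pb = unit_gauss(30.0, 2.0), unit_gauss(34.0, 3.0)
        oracle = float(np.sqrt(np.mean((pa - pb) ** 2)))
        result = distribution_rmsd(
            DistanceDistribution(r, pa), DistanceDistribution(r, pb)
        )
        assert result == pytest.approx(oracle, abs=1e-8)

    def test_disjoint_supports_warn(self):
        a = _gaussian_distribution(15.0, 0.5, lo=10, hi=20)
        b = _gaussian_distribution(45.0, 0.5, lo=40, hi=50)
        with pytest.warns(UserWarning, match="disjoint"):
            rmsd = distribution_rmsd(a, b)
        assert rmsd > 0


class TestGlobalRmsd:
    def test_identical_vectors_zero(self):
        v = [20.0, 25.0, 30.0]
        assert global_rmsd(v, v) == 0.0

    def test_constant_offset_equals_offset(self):
        exp = np.array([20.0, 25.0, 30.0, 35.0])
        assert global_rmsd(exp + 1.7, exp) == pytest.approx(1.7)

    def test_matches_direct_formula(self, rng):
        sim = rng.uniform(20, 60, 8)
        exp = rng.uniform(20, 60, 8)
        assert global_rmsd(sim, exp) == pytest.approx(
            float(np.sqrt(np.mean((sim - exp) ** 2)))
        )

    def test_length_mismatch_and_empty(self):
        with pytest.raises(ValueError):
            global_rmsd([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            global_rmsd([], [])


class TestFileIO:
    def test_round_trip_in_angstrom(self, tmp_path):
        d = _gaussian_distribution(30.0, 2.0)
        path = tmp_path / "dist.dat"
        write_distribution(d, path)
        again = read_distribution(path)
        np.testing.assert_allclose(again.r, d.r, atol=1e-6)
        np.testing.assert_allclose(again.p, d.p, atol=1e-4)

    def test_nanometre_axis_autodetected(self, tmp_path):
        r_nm = np.arange(1.0, 6.0, 0.05)
        p = np.exp(-0.5 * ((r_nm - 3.0) / 0.2) ** 2)
        path = tmp_path / "nm.dat"
        np.savetxt(path, np.column_stack([r_nm, p]))
        d = read_distribution(path)
        assert d.meta["unit_in"] == "nm"
        assert stats(d).mean == pytest.approx(30.0, abs=0.05)

    def test_comma_separated_accepted(self, tmp_path):
        path = tmp_path / "c.csv"
        r = np.arange(20.0, 40.0, 0.5)
        p = np.exp(-0.5 * ((r - 30.0) / 2.0) ** 2)
        path.write_text("\n".join(f"{a},{b}" for a, b in zip(r, p)))
        d = read_distribution(path)
        assert stats(d).mean == pytest.approx(30.0, abs=0.1)


def test_default_grid_covers_pds_range():
    g = default_grid()
    assert g[0] == 10.0 and g[-1] == 100.0
    assert np.allclose(np.diff(g), 0.5)
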