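"""Wilson B, anisotropic tensor fitting, directional limits and ratios."""

import numpy as np
import pytest

from anisoaudit.aniso import (
    AnisoFitError,
    AnisoTensor,
    aniso_ratio,
    delta_b,
    delta_res,
    directional_limits,
    fit_aniso_tensor,
    pct_rejected,
    shell_binning,
    wilson_b,
)
from anisoaudit.geometry import SpaceGroup, UnitCell
from anisoaudit.io import ReflectionSet
from anisoaudit.synthetic import SimulationSpec, gen_reflections
from conftest import CUBE, diag_tensor, iso_tensor

P1 = SpaceGroup.from_symbol("P 1")


def _toy_set(n, seed=0, cell=UnitCell(25, 25, 25)):
    """Small P1 reflection set with constant intensity for binning tests."""
    rng = np.random.default_rng(seed)
    hkl = []
    seen = set()
    while len(hkl) < n:
        h = tuple(int(x) for x in rng.integers(-8, 9, 3))
        if h == (0, 0, 0):
            continue
        key = max(h, tuple(-x for x in h))
        if key in seen:
            continue
        seen.add(key)
        hkl.append(h)
    i = np.full(n, 50.0)
    return ReflectionSet(hkl=np.array(hkl), cell=cell, spacegroup=P1,
                         i=i, sig_i=0.1 * i)


class TestShellBinning:
    def test_exact_partition(self):
        shells = shell_binning(_toy_set(100), n_shells=10)
        assert shells.counts.tolist() == [10] * 10

    def test_near_equal_partition(self):
        shells = shell_binning(_toy_set(105), n_shells=10)
        assert shells.counts.sum() == 105
        assert shells.counts.max() - shells.counts.min() <= 1

    def test_mean_intensity_decreases_with_resolution(self, iso_noise_free_b30):
        _, refl = iso_noise_free_b30
        shells = shell_binning(refl, n_shells=15)
        assert np.all(np.diff(shells.mean_i) < 0)  # exp(-2Bs^2) decay
        assert np.all(np.diff(shells.mean_d) < 0)  # ordered low -> high resolution

    def test_too_few_reflections(self):
        with pytest.raises(AnisoFitError, match="n_shells"):
            shell_binning(_toy_set(5), n_shells=10)


class TestWilsonB:
    def test_flat_intensities_give_zero(self):
        assert wilson_b(_toy_set(400), source="intensities") == pytest.approx(0.0, abs=1e-9)

    def test_recovery_noise_free(self, iso_noise_free_b30):
        _, refl = iso_noise_free_b30
        assert wilson_b(refl, source="intensities") == pytest.approx(30.0, abs=1.0)
        assert wilson_b(refl, source="amplitudes") == pytest.approx(30.0, abs=1.0)

    def test_recovery_b80_noise_free(self):
        refl = gen_reflections(SimulationSpec(cell=CUBE, dmin=2.0, b_tensor=iso_tensor(80),
                                              wilson_noise=False))
        assert wilson_b(refl, source="intensities") == pytest.approx(80.0, abs=2.0)

    def test_too_few_shells_in_range(self):
        # dmin of 9 A leaves every shell outside the 4.5 A Wilson range
        refl = gen_reflections(SimulationSpec(cell=UnitCell(30, 30, 30), dmin=9.0,
                                              wilson_noise=False))
        with pytest.raises(AnisoFitError):
            wilson_b(refl, source="intensities", n_shells=3)


class TestTensorFit:
    def test_recovery_noise_free(self, aniso_noise_free):
        _, refl = aniso_noise_free
        tensor, n_rej = fit_aniso_tensor(refl, source="intensities")
        assert n_rej == 0  # no outliers exist in noise-free data
        w = tensor.eigenvalues
        assert w[1] - w[0] == pytest.approx(0.0, abs=0.5)
        assert delta_b(tensor) == pytest.approx(50.0, abs=0.5)

    def test_isotropic_eigenvalues_equal(self, iso_noise_free_b30):
        _, refl = iso_noise_free_b30
        tensor, _ = fit_aniso_tensor(refl, source="intensities")
        assert tensor.eigenvalues.max() - tensor.eigenvalues.min() < 1.0

    def test_amplitude_intensity_consistency(self, aniso_noise_free):
        _, refl = aniso_noise_free
        t_int, _ = fit_aniso_tensor(refl, source="intensities")
        t_amp, _ = fit_aniso_tensor(refl, source="amplitudes")
        assert np.abs(t_int.b_cart - t_amp.b_cart).max() < 1e-6

    def test_rotational_equivariance(self):
        """Rotating the generating tensor rotates axes, not eigenvalues."""
        theta = np.radians(30.0)
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        b0 = np.diag([15.0, 25.0, 60.0])
        b_rot = rot @ b0 @ rot.T
        t0, _ = fit_aniso_tensor(
            gen_reflections(SimulationSpec(cell=CUBE, dmin=2.2,
                                           b_tensor=tuple(map(tuple, b0)),
                                           wilson_noise=False)),
            source="intensities",
        )
        t1, _ = fit_aniso_tensor(
            gen_reflections(SimulationSpec(cell=CUBE, dmin=2.2,
                                           b_tensor=tuple(map(tuple, 0.5 * (b_rot + b_rot.T))),
                                           wilson_noise=False)),
            source="intensities",
        )
        assert np.abs(t0.eigenvalues - t1.eigenvalues).max() < 1e-6 * 60
        assert abs(delta_b(t0) - delta_b(t1)) < 1e-6 * 45

    def test_coplanar_directions_rejected(self):
        hkl = [(h, k, 0) for h in range(-6, 7) for k in range(-6, 7)
               if (h, k) != (0, 0) and (h > 0 or (h == 0 and k > 0))]
        i = np.full(len(hkl), 10.0)
        refl = ReflectionSet(hkl=np.array(hkl), cell=UnitCell(25, 25, 25),
                             spacegroup=P1, i=i, sig_i=0.1 * i)
        with pytest.raises(AnisoFitError, match="coplanar"):
            fit_aniso_tensor(refl, source="intensities")

    def test_too_few_reflections(self):
        with pytest.raises(AnisoFitError, match="50"):
            fit_aniso_tensor(_toy_set(40), source="intensities")


class TestDeltaB:
    def test_eigenvalue_spread(self):
        assert delta_b(AnisoTensor(np.diag([10.0, 20.0, 60.0]))) == pytest.approx(50.0)

    def test_isotropic_zero(self):
        assert delta_b(AnisoTensor(17.0 * np.eye(3))) == 0.0

    def test_trace_shift_invariance(self):
        b = np.diag([10.0, 20.0, 60.0])
        assert delta_b(AnisoTensor(b + 15.0 * np.eye(3))) == pytest.approx(50.0)

    def test_tensor_must_be_symmetric(self):
        with pytest.raises(ValueError):
            AnisoTensor(np.array([[1, 2, 0], [0, 1, 0], [0, 0, 1.0]]))

    def test_eigendecomposition_reconstructs(self):
        rng = np.random.default_rng(3)
        m = rng.normal(size=(3, 3))
        t = AnisoTensor(m + m.T)
        rebuilt = t.eigenvectors @ np.diag(t.eigenvalues) @ t.eigenvectors.T
        assert np.abs(rebuilt - t.b_cart).max() < 1e-8 * max(1, np.abs(t.b_cart).max())
        assert np.all(np.diff(t.eigenvalues) >= 0)


class TestDirectionalLimits:
    def test_uniform_signal_reaches_dmin(self, flat_snr10):
        _, refl = flat_snr10
        dl = directional_limits(refl, np.eye(3))
        assert dl.limits == (refl.d.min(),) * 3
        assert delta_res(dl.limits) == 0.0

    def test_global_crossing(self):
        from anisoaudit.synthetic import DirectionalSigma
        spec = SimulationSpec(
            cell=CUBE, dmin=2.0, sigma_frac=2.0 / 6.0, wilson_noise=False,
            directional_sigma=(DirectionalSigma(factor=4.0, d_max=2.5),),
        )  # F/sigF = 6 above 2.5 A, 1.5 below, in every direction
        refl = gen_reflections(spec)
        dl = directional_limits(refl, np.eye(3))
        for lim in dl.limits:
            assert 2.45 <= lim <= 2.65  # crossing bin edge, +- half-bin quantization
        assert max(dl.limits) - min(dl.limits) < 0.15

    def test_single_axis_inflation(self, zaxis_inflated):
        _, refl = zaxis_inflated
        dl = directional_limits(refl, np.eye(3))
        dmin = refl.d.min()
        assert dl.limits[0] == pytest.approx(dmin)
        assert dl.limits[1] == pytest.approx(dmin)
        assert 2.9 <= dl.limits[2] <= 3.15  # planted crossing at 3.0 A
        assert delta_res(dl.limits) == pytest.approx(dl.limits[2] - dmin)

    def test_sigma_inflation_never_deepens_limits(self, zaxis_inflated):
        _, refl = zaxis_inflated
        base = directional_limits(refl, np.eye(3))
        worse = ReflectionSet(hkl=refl.hkl, cell=refl.cell, spacegroup=refl.spacegroup,
                              f=refl.f, sig_f=refl.sig_f * 3.5, i=refl.i,
                              sig_i=refl.sig_i * 3.5)
        inflated = directional_limits(worse, np.eye(3))
        for b, w in zip(base.limits, inflated.limits):
            assert w >= b - 1e-12

    def test_sparse_cone_flagged_unreliable(self):
        refl = gen_reflections(SimulationSpec(cell=UnitCell(12, 12, 12), dmin=4.0,
                                              sigma_frac=0.2, wilson_noise=False))
        dl = directional_limits(refl, np.eye(3), min_cone_count=20)
        assert any(dl.unreliable)


class TestScalars:
    @pytest.mark.parametrize("limits,expected", [((2.0, 2.3, 3.1), 1.1), ((1.8, 1.8, 1.8), 0.0)])
    def test_delta_res(self, limits, expected):
        assert delta_res(limits) == pytest.approx(expected)

    def test_delta_res_needs_positive_limits(self):
        with pytest.raises(ValueError):
            delta_res((2.0, -1.0, 3.0))

    @pytest.mark.parametrize("a,w,expected", [(50.0, 25.0, 2.0), (0.0, 25.0, 0.0)])
    def test_aniso_ratio(self, a, w, expected):
        assert aniso_ratio(a, w) == pytest.approx(expected)

    def test_aniso_ratio_guarded_division(self):
        assert aniso_ratio(50.0, 0.0) is None
        assert aniso_ratio(50.0, None) is None

    @pytest.mark.parametrize("rej,total,expected", [(5, 100, 5.0), (0, 100, 0.0)])
    def test_pct_rejected(self, rej, total, expected):
        assert pct_rejected(rej, total) == expected

    def test_pct_rejected_errors(self):
        with pytest.raises(ValueError):
            pct_rejected(0, 0)
        with pytest.raises(ValueError):
            pct_rejected(5, 4)


def test_trace_shift_invariance_of_generated_data():
    """Adding an isotropic component to the generating tensor leaves delta-B."""
    base = np.diag([5.0, 15.0, 45.0])
    vals = []
    for shift in (0.0, 20.0):
        spec = SimulationSpec(cell=CUBE, dmin=2.2,
                              b_tensor=tuple(map(tuple, base + shift * np.eye(3))),
                              seed=11)
        tensor, _ = fit_aniso_tensor(gen_reflections(spec), source="intensities")
        vals.append(delta_b(tensor))
    assert vals[0] == pytest.approx(vals[1], abs=1.0)
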