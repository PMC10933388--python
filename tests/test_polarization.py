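"""Stokes processing: retardation, optic axis, DOPU, unwrapping, birefringence."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from psoct.phantom import LayerSpec, PhantomSpec, simulate_tomogram
from psoct.polarization import (
    DualChannelTomogram,
    StokesField,
    compute_dopu,
    compute_local_birefringence,
    compute_optic_axis,
    compute_polarization_maps,
    compute_retardation,
    compute_retardation_profile,
    compute_stokes,
    unwrap_retardation,
)

HALF_PI = np.pi / 2


def _tom(a0, a1):
    return DualChannelTomogram(
        a0=np.atleast_2d(np.asarray(a0, complex)),
        a1=np.atleast_2d(np.asarray(a1, complex)),
        axial_px_um=3.5,
        wavelength_um=1.3,
    )


class TestStokes:
    def test_pure_horizontal_gives_q_minus_one(self):
        st_ = compute_stokes(_tom([[1.0]], [[0.0]]))
        assert (st_.i[0, 0], st_.q[0, 0], st_.u[0, 0], st_.v[0, 0]) == (1, -1, 0, 0)

    def test_pure_vertical_gives_q_plus_one(self):
        st_ = compute_stokes(_tom([[0.0]], [[1.0]]))
        assert (st_.i[0, 0], st_.q[0, 0], st_.u[0, 0], st_.v[0, 0]) == (1, 1, 0, 0)

    def test_pointwise_field_is_fully_polarized(self, rng):
        a0 = rng.normal(size=(30, 7)) + 1j * rng.normal(size=(30, 7))
        a1 = rng.normal(size=(30, 7)) + 1j * rng.normal(size=(30, 7))
        st_ = compute_stokes(_tom(a0, a1))
        assert np.allclose(st_.q**2 + st_.u**2 + st_.v**2, st_.i**2)

    def test_intensity_is_channel_energy_sum(self, slab_tomogram):
        _, tom = slab_tomogram
        st_ = compute_stokes(tom)
        assert np.array_equal(st_.i, np.abs(tom.a0) ** 2 + np.abs(tom.a1) ** 2)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            DualChannelTomogram(
                a0=np.zeros((3, 3)), a1=np.zeros((3, 4)),
                axial_px_um=3.5, wavelength_um=1.3,
            )


class TestRetardation:
    def test_equal_amplitudes_give_quarter_pi(self):
        ret = compute_retardation(_tom([[1.0 + 1j]], [[1.0 - 1j]]))
        assert ret[0, 0] == pytest.approx(np.pi / 4)

    def test_no_cross_signal_gives_zero(self):
        assert compute_retardation(_tom([[2.0]], [[0.0]]))[0, 0] == 0.0

    def test_dead_pixels_take_fill_value(self):
        ret = compute_retardation(_tom([[0.0]], [[0.0]]), fill=0.123)
        assert ret[0, 0] == 0.123

    def test_slab_retardation_linear_in_depth(self, slab_tomogram):
        # δ(z) = (2π/λ)Δn·z before the first fold; π/4 at 162.5 μm
        spec, tom = slab_tomogram
        prof = compute_retardation(tom).mean(axis=1)
        z = tom.depth_um()
        i = int(np.argmin(np.abs(z - 162.5)))
        slope = 2 * np.pi / 1.3 * 1e-3
        assert prof[i] == pytest.approx(np.pi / 4, abs=slope * spec.axial_px_um)

    def test_intensity_mode_squares_the_ratio(self, rng):
        a0 = rng.normal(size=(5, 5)) + 1j * rng.normal(size=(5, 5))
        a1 = rng.normal(size=(5, 5)) + 1j * rng.normal(size=(5, 5))
        amp = compute_retardation(_tom(a0, a1), mode="amplitude")
        inten = compute_retardation(_tom(a0, a1), mode="intensity")
        assert np.allclose(np.tan(inten), np.tan(amp) ** 2)


class TestOpticAxis:
    @pytest.mark.parametrize(
        "q,u,expected",
        [(1.0, 0.0, 0.0), (0.0, 1.0, np.pi / 4), (-1.0, 0.0, np.pi / 2)],
    )
    def test_printed_examples(self, q, u, expected):
        st_ = StokesField(
            i=np.ones((1, 1)), q=np.full((1, 1), q),
            u=np.full((1, 1), u), v=np.zeros((1, 1)),
        )
        assert compute_optic_axis(st_)[0, 0] == pytest.approx(expected)

    def test_range_bounds(self, rng):
        st_ = StokesField(
            i=np.ones((40, 8)),
            q=rng.normal(size=(40, 8)),
            u=rng.normal(size=(40, 8)),
            v=rng.normal(size=(40, 8)),
        )
        ax = compute_optic_axis(st_)
        assert ax.min() >= -HALF_PI and ax.max() <= HALF_PI

    @pytest.mark.parametrize("theta", [0.3, -0.6, 1.2])
    def test_slab_fast_axis_recovered_from_transverse_pair(self, theta):
        layer = LayerSpec(thickness_um=400.0, birefringence=1e-3, fast_axis_rad=theta)
        tom = simulate_tomogram(PhantomSpec(layers=(layer,), seed=2, lateral_px=64))
        ax = compute_optic_axis(compute_stokes(tom), pair="uv")
        mean_axis = 0.5 * np.angle(np.exp(2j * ax).mean())
        # modulo-π circular mean within 2 degrees
        err = np.angle(np.exp(2j * (mean_axis - theta))) / 2
        assert abs(err) < np.deg2rad(2.0)


class TestDopu:
    def test_uniform_fully_polarized_field_is_one(self):
        n = 64
        st_ = StokesField(
            i=np.ones((n, n)), q=np.ones((n, n)),
            u=np.zeros((n, n)), v=np.zeros((n, n)),
        )
        dopu = compute_dopu(st_, 8, 8)
        assert np.allclose(dopu, 1.0, atol=1e-9)

    def test_cancelling_neighbourhood_gives_zero(self):
        q = np.ones((2, 8))
        q[:, ::2] = -1.0
        st_ = StokesField(i=np.ones((2, 8)), q=q, u=np.zeros((2, 8)), v=np.zeros((2, 8)))
        dopu = compute_dopu(st_, 2, 8)
        assert dopu[0, 4] == pytest.approx(0.0, abs=1e-12)

    def test_random_walk_scaling(self, rng):
        # kernel of n=100 uniform unit Stokes vectors: sqrt(E[DOPU^2]) = 1/sqrt(n)
        vals = []
        for _ in range(500):
            xyz = rng.normal(size=(3, 10, 10))
            xyz /= np.linalg.norm(xyz, axis=0)
            st_ = StokesField(i=np.ones((10, 10)), q=xyz[0], u=xyz[1], v=xyz[2])
            vals.append(compute_dopu(st_, 10, 10)[5, 5])
        rms = float(np.sqrt(np.mean(np.square(vals))))
        assert rms == pytest.approx(0.1, abs=0.01)

    def test_dopu_decreases_with_depolarizing_fraction(self):
        means = []
        for f in (0.0, 0.25, 0.5, 1.0):
            per_seed = []
            for seed in range(5):
                layer = LayerSpec(
                    thickness_um=300.0, birefringence=1e-3, depol_fraction=f
                )
                tom = simulate_tomogram(
                    PhantomSpec(layers=(layer,), seed=seed, lateral_px=64)
                )
                per_seed.append(compute_dopu(compute_stokes(tom), 8, 8).mean())
            means.append(np.mean(per_seed))
        assert means[0] > means[1] > means[2] > means[3]

    def test_kernel_larger_than_field_rejected(self):
        st_ = StokesField(
            i=np.ones((4, 4)), q=np.ones((4, 4)),
            u=np.zeros((4, 4)), v=np.zeros((4, 4)),
        )
        with pytest.raises(ValueError):
            compute_dopu(st_, 8, 8)


class TestUnwrap:
    def test_monotone_profile_without_fold_is_identity(self):
        prof = np.linspace(0.0, 1.4, 120)
        assert np.allclose(unwrap_retardation(prof), prof)

    def test_constant_zero_stays_zero(self):
        assert np.allclose(unwrap_retardation(np.zeros(50)), 0.0)

    @pytest.mark.parametrize("slope,n", [(0.013, 400), (0.02, 500), (0.037, 270)])
    def test_noiseless_triangle_recovers_exact_line(self, slope, n):
        z = np.arange(n, dtype=float)
        cum_true = slope * z
        folded = np.abs(((cum_true + HALF_PI) % np.pi) - HALF_PI)
        rec = unwrap_retardation(folded)
        assert np.allclose(rec, cum_true, atol=1e-9)

    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValueError):
            unwrap_retardation(np.array([0.1, 2.0]))

    @given(st.integers(min_value=0, max_value=2_000))
    def test_random_layer_stacks_reconstruct_cumulative_phase(self, seed):
        # Piecewise-constant nonnegative slopes (a layer stack) folded into
        # [0, pi/2]: the reconstruction matches the true cumulative phase and
        # never decreases, up to single-sample branch ambiguity at folds that
        # coincide with slope changes.  The profile is truncated near a trough
        # so the final fold is complete (a trailing partial descent is
        # inherently ambiguous).
        rng = np.random.default_rng(seed)
        slopes = rng.uniform(0.0, 0.05, size=5)
        cum = np.cumsum(np.concatenate([np.full(60, s) for s in slopes]))
        folded = np.abs(((cum + HALF_PI) % np.pi) - HALF_PI)
        # end mid-ascent, well past the previous trough and well before the
        # next top fold, so every fold in the profile is complete
        phase = cum % np.pi
        ok = np.nonzero((phase >= 0.45) & (phase <= 1.0))[0]
        if ok.size == 0 or ok[-1] < 30:
            return
        end = ok[-1] + 1
        rec = unwrap_retardation(folded[:end])
        step = float(np.max(slopes))
        assert np.allclose(rec, cum[:end], atol=2.5 * step + 1e-9)
        assert np.all(np.diff(rec) >= -(2.5 * step + 1e-9))


class TestLocalBirefringence:
    def test_constant_retardation_gives_zero(self):
        dn = compute_local_birefringence(np.full(100, 0.4), 1.3, 3.5)
        assert np.allclose(dn, 0.0, atol=1e-12)

    def test_doubling_wavelength_doubles_dn(self):
        prof = np.linspace(0.0, 1.2, 100)
        a = compute_local_birefringence(prof, 1.3, 3.5)
        b = compute_local_birefringence(prof, 2.6, 3.5)
        assert np.allclose(b, 2.0 * a)

    def test_noiseless_slab_recovery_within_5_percent(self):
        dn_true = 2e-3
        layer = LayerSpec(thickness_um=700.0, birefringence=dn_true)
        tom = simulate_tomogram(PhantomSpec(layers=(layer,), seed=4, lateral_px=64))
        prof = compute_retardation_profile(tom)
        dn = compute_local_birefringence(prof, 1.3, 3.5)
        med = np.median(dn[15:-15])
        assert abs(med - dn_true) / dn_true < 0.05

    def test_window_exceeding_depth_rejected(self):
        with pytest.raises(ValueError):
            compute_local_birefringence(np.zeros(10), 1.3, 3.5, window_px=20)


class TestPipeline:
    def test_maps_share_tomogram_shape_and_bounds(self):
        spec = PhantomSpec(
            layers=(LayerSpec(thickness_um=300.0, birefringence=1e-3,
                              depol_fraction=0.3),),
            seed=0, lateral_px=32, noise_sigma=0.05,
        )
        tom = simulate_tomogram(spec)
        maps = compute_polarization_maps(tom)
        for arr in maps.as_dict().values():
            assert arr.shape == tom.shape
        assert maps.retardation.min() >= 0 and maps.retardation.max() <= HALF_PI
        assert maps.optic_axis.min() >= -HALF_PI and maps.optic_axis.max() <= HALF_PI
        assert maps.dopu.min() >= 0 and maps.dopu.max() <= 1
        assert maps.local_birefringence.min() >= 0
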