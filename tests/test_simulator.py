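"""Synthetic acquisition generator: reproducibility, statistics, structure."""

import numpy as np
import pytest

from mcslr.config import SimulationSpec
from mcslr.fourier import fft2c
from mcslr.sampling import bin_shots, generate_seg_caipi
from mcslr.simulator import (
    make_coil_maps,
    make_motion_trace,
    make_phantom,
    make_phase_states,
    sigma_for_snr_db,
    simulate,
    simulate_acquisition,
    smooth_random_field,
    support_mask,
)


class TestPhantom:
    def test_reproducible_and_bounded(self):
        a = make_phantom((64, 64), seed=4)
        b = make_phantom((64, 64), seed=4)
        assert np.array_equal(a, b)
        assert np.abs(a).max() <= 1.0 and np.abs(a).min() >= 0.0

    def test_support_margin(self):
        ph = make_phantom((96, 64), seed=1, margin=8)
        m = support_mask(ph)
        assert not m[:8].any() and not m[-8:].any()
        assert not m[:, :8].any() and not m[:, -8:].any()
        assert m.any()


class TestCoilMaps:
    def test_sos_normalized(self):
        sens = make_coil_maps((48, 48), 8, seed=2)
        sos = np.sqrt((np.abs(sens.maps) ** 2).sum(axis=0))
        assert np.allclose(sos, 1.0, atol=1e-6)

    def test_single_coil_constant(self):
        sens = make_coil_maps((32, 32), 1, seed=2)
        assert np.allclose(sens.maps, 1.0)

    def test_smoothness(self):
        sens = make_coil_maps((64, 64), 8, seed=3)
        for c in range(8):
            g = np.abs(np.diff(sens.maps[c], axis=0)).max()
            assert g < 0.2  # max finite-difference gradient bound


class TestPhaseStates:
    def test_first_state_zero_and_amplitude(self):
        st = make_phase_states((64, 64), 4, 3.0, 8.0, seed=5)
        assert not st[0].any()
        for k in range(1, 4):
            assert st[k].max() - st[k].min() == pytest.approx(3.0, rel=0.05)

    def test_zero_amplitude(self):
        st = make_phase_states((32, 32), 3, 0.0, 8.0, seed=5)
        assert not st.any()

    def test_autocorrelation_length_matches_smoothness(self):
        """Filtered white noise has Gaussian autocorrelation with std
        sigma*sqrt(2): half width ~ 1.665 sigma."""
        sigma = 6.0
        f = smooth_random_field((512, 512), sigma, np.random.default_rng(0))
        ac = np.fft.ifft2(np.abs(np.fft.fft2(f)) ** 2).real
        ac /= ac[0, 0]
        prof = ac[0, :50]
        half = np.interp(0.5, prof[::-1], np.arange(50)[::-1])
        assert half == pytest.approx(1.665 * sigma, rel=0.2)


class TestMotionTrace:
    def test_zero_ranges_identity(self):
        trace = make_motion_trace(48, 8, 0.0, 0.0, seed=3)
        assert all(p.is_identity() for p in trace)

    def test_interpolation_within_knot_hull(self):
        trace = make_motion_trace(48, 8, 1.5, 1.5, seed=3)
        vecs = np.stack([p.as_vector() for p in trace])
        assert (np.abs(vecs[:, 0]) <= 1.5).all()
        assert (np.abs(vecs[:, 1]) <= 1.5).all()
        assert (vecs[:, 2] == 0).all()  # 1D translation along y only

    def test_knot_distribution_uniform(self):
        """KS test of pooled knot draws against U(-1.5, 1.5)."""
        from scipy import stats

        draws = []
        for seed in range(1250):
            trace = make_motion_trace(8, 8, 1.5, 1.5, seed=seed)
            draws.extend(p.rotations[0] for p in trace)  # knots == shots here
        res = stats.kstest(np.asarray(draws), stats.uniform(-1.5, 3.0).cdf)
        assert res.pvalue > 0.01


class TestAcquisition:
    def test_clean_acquisition_is_masked_fft(self):
        sch = bin_shots(generate_seg_caipi((32, 32), (2, 2), 4, n_interleaves=2), 2, 2)
        ph = make_phantom((32, 32), seed=1)
        sens = make_coil_maps((32, 32), 4, seed=2)
        trace = make_motion_trace(4, 2, 0.0, 0.0, seed=0)
        states = np.zeros((2, 32, 32))
        Y = simulate_acquisition(ph, sens, states, trace, sch, 0.0, seed=0)
        k = fft2c(sens.maps * ph[None])
        for s in range(4):
            assert np.allclose(Y[s], k * sch.shot_masks[s][None], atol=1e-12)

    def test_noise_standard_deviation(self):
        sch = bin_shots(generate_seg_caipi((64, 64), (1, 1), 4, n_interleaves=2), 2, 2)
        ph = make_phantom((64, 64), seed=1)
        sens = make_coil_maps((64, 64), 8, seed=2)
        trace = make_motion_trace(4, 2, 0.0, 0.0, seed=0)
        states = np.zeros((2, 64, 64))
        clean = simulate_acquisition(ph, sens, states, trace, sch, 0.0, seed=0)
        noisy = simulate_acquisition(ph, sens, states, trace, sch, 0.05, seed=0)
        diff = np.concatenate(
            [(noisy - clean)[s, :, sch.shot_masks[s]].ravel() for s in range(4)]
        )
        assert diff.size >= 1e5 / 4
        assert diff.real.std() == pytest.approx(0.05, rel=0.02)
        assert diff.imag.std() == pytest.approx(0.05, rel=0.02)

    def test_trace_length_mismatch_errors(self):
        sch = bin_shots(generate_seg_caipi((32, 32), (2, 2), 4, n_interleaves=2), 2, 2)
        ph = make_phantom((32, 32), seed=1)
        sens = make_coil_maps((32, 32), 4, seed=2)
        with pytest.raises(ValueError, match="shots"):
            simulate_acquisition(
                ph, sens, np.zeros((2, 32, 32)), make_motion_trace(3, 2, 0, 0, 0),
                sch, 0.0, seed=0,
            )


class TestFullSimulation:
    def test_same_seed_bitwise_identical(self):
        spec = SimulationSpec(
            image_shape=(32, 32), n_coils=2, n_shots=4, n_groups=2,
            shots_per_subdivision=2, n_volumes=2, seed=42,
        )
        a, b = simulate(spec), simulate(spec)
        assert np.array_equal(a.kspace, b.kspace)
        assert np.array_equal(a.sens.maps, b.sens.maps)

    def test_motion_raises_lifted_spectrum_tail(self):
        """Inter-shot motion degrades the low-rank structure of the lifted
        matrix: the motion-corrupted spectrum dominates the motion-free one
        beyond the group count, on matched seeds."""
        from mcslr.hankel_slr import HankelOperatorSpec, singular_spectrum

        from mcslr.rigid_motion import apply_rigid

        base = dict(
            image_shape=(64, 64), n_coils=4, n_shots=8, n_groups=4,
            shots_per_subdivision=2, n_volumes=1, snr_db=None, seed=17,
        )
        moving = simulate(SimulationSpec(**base, rot_range_deg=3.0, trans_range_mm=0.0))
        spec = HankelOperatorSpec((6, 6), (64, 64), 4)
        truth = moving.truth_images[0].astype(np.complex128)
        tt = moving.truth_trace(0)

        def spectrum(with_motion):
            chans = []
            for i in range(4):
                img = truth[i]
                if with_motion:
                    img = apply_rigid(img, tt.t_intra[i][0])
                chans.append(fft2c(img))
            return singular_spectrum(np.stack(chans), spec)

        s_still, s_mov = spectrum(False), spectrum(True)
        n = 4
        assert s_mov[n:].sum() > s_still[n:].sum()
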