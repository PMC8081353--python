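"""Phantom geometry, ball-and-stick forward model, noise and k-space."""

import numpy as np
import pytest

from protocol_lab.gradients import GradientScheme, interleave_b0s
from protocol_lab.phantom import (
    DWIVolume,
    PhantomSpec,
    PhantomVolume,
    ball_and_stick_signal,
    build_phantom,
    from_kspace,
    simulate_signal,
    to_kspace,
)


@pytest.fixture(scope="module")
def phantom():
    return build_phantom(seed=0)


class TestGeometry:
    def test_crossing_zone_has_two_sticks_at_60deg_plus(self, phantom):
        cross = np.isin(
            phantom.labels,
            [phantom.region_id("L_cross"), phantom.region_id("R_cross")],
        )
        assert np.all(phantom.n_sticks[cross] == 2)
        v = phantom.sticks[cross]
        cosang = np.abs(np.sum(v[:, 0] * v[:, 1], axis=1))
        assert np.all(cosang <= np.cos(np.deg2rad(60)) + 1e-6)

    def test_region_volume_fractions(self, phantom):
        hc = phantom.volume_fraction("Hc")
        fx = phantom.volume_fraction("fx")
        assert 0.025 <= hc * 100 <= 0.10 * 100  # within a factor of 2 of 5%
        assert 2.5 <= hc * 100 <= 10.0
        assert 0.025 <= fx * 100 <= 0.10

    def test_sticks_unit_and_fractions_bounded(self, phantom):
        f = phantom.fractions
        present = f > 0
        norms = np.linalg.norm(phantom.sticks, axis=-1)
        assert np.allclose(norms[present], 1.0, atol=1e-5)
        assert np.all(f.sum(axis=-1) <= 1.0 + 1e-6)

    def test_single_bundle_spec_all_parallel(self):
        p = build_phantom(PhantomSpec(single_bundle_only=True), seed=0)
        fi = p.labels > 0
        v = p.sticks[fi][:, 0]
        assert np.allclose(np.abs(v @ [0, 1, 0]), 1.0, atol=1e-6)

    def test_deterministic(self):
        a = build_phantom(seed=3)
        b = build_phantom(seed=3)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.sticks, b.sticks)

    def test_hemisphere_tags(self, phantom):
        hems = {r.hemisphere for r in phantom.regions.values()}
        assert hems == {"L", "R"}

    def test_invalid_fractions_rejected(self, phantom):
        bad = phantom.fractions.copy()
        bad[phantom.labels > 0] = 0.6  # three sticks x 0.6 > 1
        with pytest.raises(ValueError):
            PhantomVolume(
                shape=phantom.shape, voxel_size=phantom.voxel_size,
                labels=phantom.labels, sticks=phantom.sticks, fractions=bad,
                brain_mask=phantom.brain_mask, regions=phantom.regions,
                spec=phantom.spec, seed=0,
            )


class TestSignal:
    def test_b0_gives_s0(self, phantom, scheme120):
        dwi = simulate_signal(phantom, scheme120, S0=2.5, snr=None)
        b0 = dwi.data[..., dwi.scheme.bvalues == 0]
        inside = phantom.brain_mask
        assert np.allclose(b0[inside], 2.5, atol=1e-5)
        assert np.allclose(b0[~inside], 0.0)

    def test_single_stick_parallel_closed_form(self):
        """f = 1, g parallel to v: S = S0 exp(-b d) = S0 e^-4."""
        g = np.array([[0.0, 0.0, 1.0]])
        S = ball_and_stick_signal(
            np.array([4000.0]), g,
            sticks=np.array([[[0.0, 0.0, 1.0], [0, 0, 0], [0, 0, 0]]]),
            fractions=np.array([[1.0, 0.0, 0.0]]),
            S0=1.0, d=1e-3,
        )
        assert S[0, 0] == pytest.approx(np.exp(-4.0), rel=1e-12)

    def test_crossing_voxel_matches_scalar_formula(self):
        """90-degree crossing evaluated against a plain-Python loop."""
        v1, v2 = np.array([0.0, 1.0, 0.0]), np.array([1.0, 0.0, 0.0])
        rng = np.random.default_rng(4)
        g = rng.standard_normal((5, 3))
        g /= np.linalg.norm(g, axis=1, keepdims=True)
        b, d, S0 = 4000.0, 1e-3, 1.3
        S = ball_and_stick_signal(
            np.full(5, b), g,
            sticks=np.array([[v1, v2, np.zeros(3)]]),
            fractions=np.array([[0.35, 0.35, 0.0]]),
            S0=S0, d=d,
        )[0]
        for j in range(5):
            expect = S0 * (
                0.30 * np.exp(-b * d)
                + 0.35 * np.exp(-b * d * float(g[j] @ v1) ** 2)
                + 0.35 * np.exp(-b * d * float(g[j] @ v2) ** 2)
            )
            assert S[j] == pytest.approx(expect, rel=1e-12)

    def test_attenuation_extremes_for_single_stick(self):
        v = np.array([0.0, 0.0, 1.0])
        gs = np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0], [np.sqrt(0.5), 0, np.sqrt(0.5)]])
        S = ball_and_stick_signal(
            np.full(3, 4000.0), gs,
            sticks=np.array([[v, np.zeros(3), np.zeros(3)]]),
            fractions=np.array([[0.8, 0.0, 0.0]]),
            S0=1.0, d=1e-3,
        )[0]
        assert S[1] == max(S)  # perpendicular: maximal signal
        assert S[0] == min(S)  # parallel: minimal signal

    def test_rician_noise_floor(self, phantom, scheme120):
        """Background (S = 0) magnitude averages sigma sqrt(pi/2)."""
        dwi = simulate_signal(phantom, scheme120, snr=20.0, seed=9)
        sigma = 1.0 / 20.0
        bg = dwi.data[~phantom.brain_mask]
        assert bg.mean() == pytest.approx(sigma * np.sqrt(np.pi / 2), rel=0.05)

    def test_noise_deterministic(self, phantom, scheme120):
        a = simulate_signal(phantom, scheme120, snr=30.0, seed=1)
        b = simulate_signal(phantom, scheme120, snr=30.0, seed=1)
        assert np.array_equal(a.data, b.data)

    def test_interleaved_b0_layout(self, scheme120):
        acq = interleave_b0s(scheme120, every=12)
        assert acq.n == 130
        assert np.count_nonzero(acq.bvalues == 0) == 10
        assert acq.bvalues[0] == 0.0


class TestKSpace:
    @staticmethod
    def _small_dwi(seed=0):
        rng = np.random.default_rng(seed)
        data = rng.random((8, 8, 8, 2))
        scheme = GradientScheme(
            np.array([[0.0, 0, 0], [0, 0, 1.0]]), np.array([0.0, 4000.0])
        )
        return DWIVolume(data=data, scheme=scheme, voxel_size=43.0)

    def test_round_trip(self):
        dwi = self._small_dwi()
        back = from_kspace(to_kspace(dwi), dwi.scheme, dwi.voxel_size)
        assert np.max(np.abs(back.data - dwi.data)) < 1e-10 * np.max(dwi.data)

    def test_constant_volume_concentrates_at_dc(self):
        dwi = self._small_dwi()
        dwi.data[..., 0] = 3.0
        k = to_kspace(dwi)[..., 0]
        dc = k[4, 4, 4]  # floor(dim/2)
        assert abs(dc) == pytest.approx(3.0 * 8**3, rel=1e-12)
        energy = np.sum(np.abs(k) ** 2)
        assert abs(dc) ** 2 == pytest.approx(energy, rel=1e-12)

    def test_parseval(self):
        dwi = self._small_dwi(2)
        k = to_kspace(dwi)
        lhs = np.sum(dwi.data.astype(float) ** 2)
        rhs = np.sum(np.abs(k) ** 2) / 8**3  # DFT normalization
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_nonfinite_rejected(self):
        dwi = self._small_dwi()
        dwi.data[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            to_kspace(dwi)
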