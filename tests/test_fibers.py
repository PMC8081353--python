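"""Tensor fit, ball-and-stick fit, dispersion and the dyad census."""

import numpy as np
import pytest

from protocol_lab.fibers import (
    dyad_census,
    dyad_dispersion,
    fit_ball_and_stick,
    fit_tensor,
)
from protocol_lab.gradients import interleave_b0s, subset_by_dot_product, generate_uniform_directions
from protocol_lab.phantom import DWIVolume, ball_and_stick_signal


def _as_dwi(signals, acq):
    V = signals.shape[0]
    return DWIVolume(
        data=signals.reshape(V, 1, 1, -1), scheme=acq, voxel_size=43.0
    )


def _signals(acq, sticks, fracs, S0=1.0, d=1e-3, snr=None, seed=0):
    bv = np.where(acq.bvalues > 0, 4000.0, 0.0)
    S = ball_and_stick_signal(bv, acq.directions, sticks, fracs, S0, d)
    if snr:
        rng = np.random.default_rng(seed)
        e1 = rng.normal(0, S0 / snr, S.shape)
        e2 = rng.normal(0, S0 / snr, S.shape)
        S = np.sqrt((S + e1) ** 2 + e2**2)
    return S


@pytest.fixture(scope="module")
def acq(acq120):
    return acq120


class TestTensor:
    def test_isotropic_voxel(self, acq):
        sticks = np.zeros((1, 3, 3))
        fracs = np.zeros((1, 3))
        dwi = _as_dwi(_signals(acq, sticks, fracs), acq)
        tf = fit_tensor(dwi, np.ones((1, 1, 1), bool))
        assert tf.md[0] == pytest.approx(1e-3, abs=1e-6)
        assert tf.fa[0] < 0.01

    def test_single_stick_principal_direction(self, acq):
        v = np.array([0.48, 0.6, 0.64])
        v /= np.linalg.norm(v)
        sticks = np.zeros((1, 3, 3))
        sticks[0, 0] = v
        fracs = np.zeros((1, 3))
        fracs[0, 0] = 0.8
        dwi = _as_dwi(_signals(acq, sticks, fracs), acq)
        tf = fit_tensor(dwi, np.ones((1, 1, 1), bool))
        # oracle: independent log-linear fit assembled in the test
        bv, g = acq.bvalues, acq.directions
        X = np.column_stack([
            -bv * g[:, 0] ** 2, -bv * g[:, 1] ** 2, -bv * g[:, 2] ** 2,
            -bv * 2 * g[:, 0] * g[:, 1], -bv * 2 * g[:, 0] * g[:, 2],
            -bv * 2 * g[:, 1] * g[:, 2], np.ones(len(bv)),
        ])
        coef = np.linalg.lstsq(X, np.log(dwi.data[0, 0, 0]), rcond=None)[0]
        T = np.array([
            [coef[0], coef[3], coef[4]],
            [coef[3], coef[1], coef[5]],
            [coef[4], coef[5], coef[2]],
        ])
        w, Q = np.linalg.eigh(T)
        expect = Q[:, np.argmax(w)]
        assert abs(tf.principal[0] @ expect) > np.cos(np.deg2rad(0.1))
        assert abs(tf.principal[0] @ v) > np.cos(np.deg2rad(2.0))

    def test_crossing_lowers_fa(self, acq):
        sticks = np.zeros((2, 3, 3))
        fracs = np.zeros((2, 3))
        sticks[0, 0] = (0, 1, 0)
        fracs[0, 0] = 0.7
        sticks[1, 0], sticks[1, 1] = (0, 1, 0), (1, 0, 0)
        fracs[1, 0] = fracs[1, 1] = 0.35
        dwi = _as_dwi(_signals(acq, sticks, fracs), acq)
        tf = fit_tensor(dwi, np.ones((2, 1, 1), bool))
        assert tf.fa[1] < tf.fa[0]

    def test_needs_enough_volumes(self, acq120):
        small = acq120.subset(list(range(5)))
        dwi = DWIVolume(
            data=np.ones((1, 1, 1, 5)), scheme=small, voxel_size=43.0
        )
        with pytest.raises(ValueError):
            fit_tensor(dwi, np.ones((1, 1, 1), bool))


class TestBallAndStick:
    def test_noiseless_single_stick_recovery(self, acq):
        rng = np.random.default_rng(8)
        V = 20
        sticks = np.zeros((V, 3, 3))
        fracs = np.zeros((V, 3))
        v = rng.standard_normal((V, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        sticks[:, 0] = v
        fracs[:, 0] = 0.7
        dwi = _as_dwi(_signals(acq, sticks, fracs), acq)
        ff = fit_ball_and_stick(
            dwi, np.ones((V, 1, 1), bool), max_sticks=2, n_bootstrap=10, seed=0
        )
        assert np.all(ff.n_supported == 1)
        dots = np.abs(np.sum(ff.dyads[:, 0] * v, axis=1))
        assert np.all(dots > np.cos(np.deg2rad(5.0)))
        assert np.allclose(ff.fractions[:, 0], 0.7, atol=1e-3)
        assert np.allclose(ff.d, 1e-3, atol=1e-6)
        assert np.all(ff.dispersion[:, 0] < 0.01)

    def test_crossing_detection_snr30(self, snapped, acq):
        """90-degree equal crossing at SNR 30: >= 80% two-dyad with 60
        directions, and strictly fewer with the 12-direction subset."""
        acq60 = interleave_b0s(snapped[60])
        # denser b0 interleave so the 12-direction protocol still has the
        # volume budget for a 2-stick model (as when subsets keep every
        # b0 of the parent acquisition)
        acq12 = interleave_b0s(snapped[12], every=2)
        V = 300
        sticks = np.zeros((V, 3, 3))
        fracs = np.zeros((V, 3))
        sticks[:, 0], sticks[:, 1] = (0, 1, 0), (1, 0, 0)
        fracs[:, 0] = fracs[:, 1] = 0.35
        props = {}
        for name, a in (("60", acq60), ("12", acq12)):
            dwi = _as_dwi(_signals(a, sticks, fracs, snr=30, seed=3), a)
            ff = fit_ball_and_stick(
                dwi, np.ones((V, 1, 1), bool), max_sticks=2,
                n_bootstrap=0, seed=0,
            )
            props[name] = float(np.mean(ff.n_supported == 2))
        assert props["60"] >= 0.8
        assert props["12"] < props["60"]

    def test_insufficient_volumes_rejected(self, snapped):
        acq12 = interleave_b0s(snapped[12])
        dwi = DWIVolume(
            data=np.ones((1, 1, 1, acq12.n)), scheme=acq12, voxel_size=43.0
        )
        with pytest.raises(ValueError, match="volumes"):
            fit_ball_and_stick(dwi, np.ones((1, 1, 1), bool), max_sticks=4)


class TestDyadDispersion:
    def test_identical_replicates(self):
        v = np.tile([0.0, 0.0, 1.0], (10, 1))
        assert dyad_dispersion(v) == pytest.approx(0.0, abs=1e-12)

    def test_antipodal_pair(self):
        v = np.array([[0.0, 0, 1.0], [0.0, 0, -1.0]])
        assert dyad_dispersion(v) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_dyads_near_half(self):
        """Uniformly random dyads: compare against an independent Monte
        Carlo of the same hemisphere-alignment statistic."""
        rng = np.random.default_rng(0)
        v = rng.standard_normal((10_000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        got = dyad_dispersion(v)
        # oracle: align to a fixed axis by sign and average, independently
        w = rng.standard_normal((10_000, 3))
        w /= np.linalg.norm(w, axis=1, keepdims=True)
        axis = np.array([0.0, 0.0, 1.0])
        sign = np.sign(w @ axis)
        expect = 1.0 - np.linalg.norm(np.mean(w * sign[:, None], axis=0))
        assert got == pytest.approx(expect, abs=0.02)
        assert got == pytest.approx(0.5, abs=0.02)

    def test_errors(self):
        with pytest.raises(ValueError):
            dyad_dispersion(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            dyad_dispersion(np.array([[0.0, 0, 1.0]]))


class TestCensus:
    @staticmethod
    def _single_stick_fit(acq, V=8):
        sticks = np.zeros((V, 3, 3))
        fracs = np.zeros((V, 3))
        sticks[:, 0] = (0, 1, 0)
        fracs[:, 0] = 0.7
        dwi = _as_dwi(_signals(acq, sticks, fracs), acq)
        return fit_ball_and_stick(
            dwi, np.ones((V, 1, 1), bool), max_sticks=2, n_bootstrap=0, seed=0
        )

    def test_all_single_stick(self, acq):
        ff = self._single_stick_fit(acq)
        labels = np.ones((8, 1, 1), dtype=np.int16)
        census = dyad_census(ff, labels, {1: "bundle"})
        assert census.proportions("global")[1] == pytest.approx(1.0)
        assert census.proportions("bundle")[1] == pytest.approx(1.0)

    def test_empty_region_absent(self, acq):
        ff = self._single_stick_fit(acq)
        labels = np.ones((8, 1, 1), dtype=np.int16)
        census = dyad_census(ff, labels, {1: "bundle", 9: "ghost"})
        assert "ghost" not in set(census.table.region)
        with pytest.raises(KeyError):
            census.proportions("ghost")

    def test_shape_mismatch(self, acq):
        ff = self._single_stick_fit(acq)
        with pytest.raises(ValueError):
            dyad_census(ff, np.ones((4, 1, 1), dtype=np.int16), None)

    def test_proportions_sum_to_one(self, acq):
        ff = self._single_stick_fit(acq)
        labels = np.ones((8, 1, 1), dtype=np.int16)
        census = dyad_census(ff, labels, {1: "bundle"})
        for region in census.table.region:
            assert census.proportions(region).sum() == pytest.approx(1.0)
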