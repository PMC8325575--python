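import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from casct.errors import ContractError
from casct.fbp import fbp_reconstruct
from casct.geometry import Image
from casct.pdfl import (
    FidelityParams,
    ViewMask,
    fuse_sinogram,
    pdfl_backward,
    pdfl_forward,
    sinogram_error_trace,
)
from casct.projector import FanSinogram, forward_project


def masked(values, mask):
    out = np.zeros_like(values)
    out[mask.acquired] = values[mask.acquired]
    return out


@pytest.fixture
def tiny_mask(tiny_geometry):
    return ViewMask(np.arange(0, 16, 4), 16)


class TestViewMask:
    def test_sorted_unique_serialization(self):
        m = ViewMask(np.array([5, 1, 3, 1]), 8)
        assert m.to_list() == [1, 3, 5]
        assert len(m) == 3

    def test_invalid_masks_rejected(self):
        with pytest.raises(ContractError):
            ViewMask(np.array([], dtype=int), 8)
        with pytest.raises(ContractError):
            ViewMask(np.array([8]), 8)

    def test_row_weights(self):
        m = ViewMask(np.array([0, 2]), 4)
        e = m.row_weights(0.5)
        assert np.allclose(e, [1 / 3, 1.0, 1 / 3, 1.0])
        assert np.allclose(m.row_weights(0.0), [0.0, 1.0, 0.0, 1.0])


class TestFuseSinogram:
    def test_lambda_zero_replaces_acquired_rows_exactly(self, tiny_geometry, tiny_mask):
        rng = np.random.default_rng(0)
        s_cnn = FanSinogram(rng.normal(size=(16, 21)), tiny_geometry)
        s_u = FanSinogram(masked(rng.normal(size=(16, 21)), tiny_mask), tiny_geometry)
        out = fuse_sinogram(s_cnn, s_u, tiny_mask, FidelityParams(0.0))
        ind = tiny_mask.indicator()
        assert np.array_equal(out.values[ind], s_u.values[ind])
        assert np.array_equal(out.values[~ind], s_cnn.values[~ind])

    def test_lambda_one_arithmetic(self, tiny_geometry):
        mask = ViewMask(np.array([2]), 16)
        s_cnn = FanSinogram(np.full((16, 21), 2.0), tiny_geometry)
        s_u = FanSinogram(masked(np.full((16, 21), 4.0), mask), tiny_geometry)
        out = fuse_sinogram(s_cnn, s_u, mask, FidelityParams(1.0))
        assert np.allclose(out.values[2], 3.0)  # (1*2 + 4) / 2
        assert np.allclose(out.values[3], 2.0)

    def test_nonzero_outside_mask_rejected(self, tiny_geometry, tiny_mask):
        s_cnn = FanSinogram(np.zeros((16, 21)), tiny_geometry)
        bad = FanSinogram(np.ones((16, 21)), tiny_geometry)
        with pytest.raises(ContractError):
            fuse_sinogram(s_cnn, bad, tiny_mask)

    def test_idempotent_at_lambda_zero(self, tiny_geometry, tiny_mask):
        rng = np.random.default_rng(1)
        s_cnn = FanSinogram(rng.normal(size=(16, 21)), tiny_geometry)
        s_u = FanSinogram(masked(rng.normal(size=(16, 21)), tiny_mask), tiny_geometry)
        once = fuse_sinogram(s_cnn, s_u, tiny_mask, FidelityParams(0.0))
        twice = fuse_sinogram(once, s_u, tiny_mask, FidelityParams(0.0))
        assert np.array_equal(once.values, twice.values)

    @given(lam=st.floats(0.0, 10.0, allow_nan=False), seed=st.integers(0, 100))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_fused_rows_are_convex_combinations(self, lam, seed):
        """On acquired rows the fusion lies between s_cnn and s_u elementwise."""
        from casct.geometry import make_fan_geometry

        g = make_fan_geometry(8, 16, 21, 10.0, 3.0)
        mask = ViewMask(np.arange(0, 16, 2), 16)
        rng = np.random.default_rng(seed)
        s_cnn = FanSinogram(rng.normal(size=(16, 21)), g)
        s_u = FanSinogram(masked(rng.normal(size=(16, 21)), mask), g)
        out = fuse_sinogram(s_cnn, s_u, mask, FidelityParams(lam))
        ind = mask.indicator()
        lo = np.minimum(s_cnn.values[ind], s_u.values[ind])
        hi = np.maximum(s_cnn.values[ind], s_u.values[ind])
        assert np.all(out.values[ind] >= lo - 1e-12)
        assert np.all(out.values[ind] <= hi + 1e-12)


class TestPdflForward:
    def test_full_view_lambda_zero_ignores_network_image(self, tiny_geometry):
        """With everything acquired and lam=0, the output is FBP(s_u)."""
        g = tiny_geometry
        mask = ViewMask(np.arange(16), 16)
        rng = np.random.default_rng(2)
        s_u = FanSinogram(rng.normal(size=(16, 21)), g)
        out1 = pdfl_forward(Image(rng.normal(size=(8, 8))), s_u, mask, FidelityParams(0.0))
        out2 = pdfl_forward(Image(rng.normal(size=(8, 8))), s_u, mask, FidelityParams(0.0))
        ref = fbp_reconstruct(s_u)
        scale = np.abs(ref.values).max()
        assert np.abs(out1.values - out2.values).max() <= 1e-6 * scale
        assert np.array_equal(out1.values, ref.values)

    def test_equals_explicit_composition(self, tiny_geometry, tiny_mask):
        g = tiny_geometry
        rng = np.random.default_rng(3)
        i_cnn = Image(rng.normal(size=(8, 8)))
        s_u = FanSinogram(
            masked(forward_project(Image(rng.uniform(0, 1, (8, 8))), g).values, tiny_mask),
            g,
        )
        params = FidelityParams(0.001)
        out = pdfl_forward(i_cnn, s_u, tiny_mask, params)
        ref = fbp_reconstruct(
            fuse_sinogram(forward_project(i_cnn, g), s_u, tiny_mask, params)
        )
        assert np.array_equal(out.values, ref.values)

    def test_affine_in_inputs(self, tiny_geometry, tiny_mask):
        """pdfl(i1) - pdfl(i2) is linear in i1 - i2 (the s_u part cancels)."""
        g = tiny_geometry
        rng = np.random.default_rng(4)
        s_u = FanSinogram(masked(rng.normal(size=(16, 21)), tiny_mask), g)
        params = FidelityParams(0.3)
        i1, i2 = rng.normal(size=(8, 8)), rng.normal(size=(8, 8))
        d_out = (
            pdfl_forward(Image(i1), s_u, tiny_mask, params).values
            - pdfl_forward(Image(i2), s_u, tiny_mask, params).values
        )
        lin = pdfl_backward(Image(i1 - i2), g, tiny_mask, params).values
        assert np.allclose(d_out, lin, atol=1e-10 * max(1.0, np.abs(lin).max()))


class TestPdflBackward:
    def test_all_views_lambda_zero_annihilates(self, tiny_geometry):
        g = tiny_geometry
        mask = ViewMask(np.arange(16), 16)
        rng = np.random.default_rng(5)
        out = pdfl_backward(Image(rng.normal(size=(8, 8))), g, mask, FidelityParams(0.0))
        assert np.abs(out.values).max() <= 1e-10

    def test_single_view_mask_passes_rest_through(self, tiny_geometry):
        """Unacquired rows carry weight 1, so with one masked view the map is
        close to plain FBP(FP(.)) with that row scaled."""
        g = tiny_geometry
        mask = ViewMask(np.array([0]), 16)
        rng = np.random.default_rng(6)
        cot = Image(rng.normal(size=(8, 8)))
        out = pdfl_backward(cot, g, mask, FidelityParams(0.0))
        s = forward_project(cot, g)
        ref = s.values.copy()
        ref[0] = 0.0
        expected = fbp_reconstruct(FanSinogram(ref, g))
        assert np.allclose(out.values, expected.values, atol=1e-12)


class TestSinogramErrorTrace:
    def test_reference_itself_gives_zero(self, tiny_geometry):
        s = np.random.default_rng(7).normal(size=(16, 21))
        assert sinogram_error_trace([s], s) == [0.0]

    def test_constant_offset(self, tiny_geometry):
        s = np.random.default_rng(8).normal(size=(16, 21))
        tr = sinogram_error_trace([s + 2.5, s - 1.0], s)
        assert np.allclose(tr, [2.5, 1.0])

    def test_empty_list_rejected(self):
        with pytest.raises(ContractError):
            sinogram_error_trace([], np.zeros((2, 2)))
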