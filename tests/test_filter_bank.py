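"""Filter-bank identities: constants, derivatives, frozen kernels, stacking."""

import numpy as np
import pytest

from vesselseg import FilterSpec, VolumeImage, apply_filter, build_feature_stack, hessian_response, pillow_kernel
from vesselseg.filter_bank import KNOWN_FILTERS, PILLOW_KERNELS, default_registry

CONST = np.full((32, 32), 80.0)

# smoothing-type operators preserve constants; derivative-type vanish
SMOOTHERS = ["gaussian", "median", "mean", "minimum", "bilateral",
             "pl_blur", "pl_smooth", "pl_smooth_more"]
DERIVATIVES = ["sobel", "laplacian", "pl_find_edges", "canny"]


@pytest.mark.parametrize("name", SMOOTHERS)
def test_smoothers_preserve_constants(name):
    out = apply_filter(CONST, FilterSpec(name))
    assert out == pytest.approx(CONST, abs=1e-6)


@pytest.mark.parametrize("name", DERIVATIVES)
def test_derivatives_vanish_on_constants(name):
    out = apply_filter(CONST, FilterSpec(name))
    assert out == pytest.approx(np.zeros_like(CONST), abs=1e-6)


def test_hessian_vanishes_on_constant():
    assert hessian_response(CONST) == pytest.approx(np.zeros_like(CONST), abs=1e-9)


def test_emboss_constant_gives_offset():
    # zero-sum kernel plus +128 offset
    out = apply_filter(CONST, FilterSpec("pl_emboss"))
    assert out == pytest.approx(np.full_like(CONST, 128.0))


def test_contour_constant_gives_offset():
    out = apply_filter(CONST, FilterSpec("pl_contour"))
    assert out == pytest.approx(np.full_like(CONST, 255.0))


def test_median_sort_oracle():
    im = np.arange(1.0, 82.0).reshape(9, 9)
    patch = im[3:6, 3:6].ravel()
    out = apply_filter(im, FilterSpec("median", {"size": (3, 3)}))
    assert out[4, 4] == sorted(patch)[4]


def test_gamma_identity():
    im = np.linspace(0, 255, 64).reshape(8, 8)
    out = apply_filter(im, FilterSpec("gamma", {"lam": 1.0, "gamma": 1.0}))
    assert out == pytest.approx(im)


def test_canny_output_is_binary(small_stack):
    sl = small_stack.data[small_stack.shape[0] // 2, :, :, 0]
    out = apply_filter(np.asarray(sl, dtype=float), FilterSpec("canny"))
    assert set(np.unique(out)).issubset({0.0, 1.0})


def test_pillow_kernels_match_frozen_table():
    # the ten classic fixed kernels, asserted against their frozen constants
    expected_scale_offset = {
        "pl_blur": (16, 0), "pl_contour": (1, 255), "pl_detail": (6, 0),
        "pl_edge_enhance": (2, 0), "pl_edge_enhance_more": (1, 0),
        "pl_emboss": (1, 128), "pl_find_edges": (1, 0), "pl_sharpen": (16, 0),
        "pl_smooth": (13, 0), "pl_smooth_more": (100, 0),
    }
    for name, (scale, offset) in expected_scale_offset.items():
        k, s, o = pillow_kernel(name)
        assert (s, o) == (scale, offset)
        if offset == 0 and name not in ("pl_find_edges",):
            assert k.sum() / s == pytest.approx(1.0)  # unit gain smoothers/sharpeners
        if name in ("pl_contour", "pl_emboss", "pl_find_edges"):
            assert k.sum() == 0  # derivative-style kernels are zero-sum


def test_pillow_kernels_match_pillow_itself():
    # cross-check the frozen constants against the Pillow package
    ImageFilter = pytest.importorskip("PIL.ImageFilter")
    mapping = {
        "pl_blur": "BLUR", "pl_contour": "CONTOUR", "pl_detail": "DETAIL",
        "pl_edge_enhance": "EDGE_ENHANCE", "pl_edge_enhance_more": "EDGE_ENHANCE_MORE",
        "pl_emboss": "EMBOSS", "pl_find_edges": "FIND_EDGES", "pl_sharpen": "SHARPEN",
        "pl_smooth": "SMOOTH", "pl_smooth_more": "SMOOTH_MORE",
    }
    for ours, theirs in mapping.items():
        size, scale, offset, kernel = getattr(ImageFilter, theirs).filterargs
        k, s, o = pillow_kernel(ours)
        assert k.shape == (size[1], size[0])
        assert (s, o) == (scale, offset)
        assert np.array_equal(k.ravel(), np.array(kernel, dtype=float))


def test_hessian_ridge_vs_disk():
    im = np.zeros((40, 40))
    im[20, :] = 100.0  # 1-px bright line
    line = hessian_response(im, sigma=2.0)
    on_line = line[20, 5:35].max()
    off_line = np.abs(line[5:12, 5:35]).max()
    assert on_line > 3 * off_line
    ii, jj = np.mgrid[0:40, 0:40]
    disk = np.where((ii - 20) ** 2 + (jj - 20) ** 2 <= 15**2, 100.0, 0.0)
    disk_resp = hessian_response(disk, sigma=2.0)
    assert on_line > 3 * np.abs(disk_resp[18:23, 18:23]).max()  # interior ~ flat


def test_default_stack_has_23_ordered_channels(small_stack):
    assert small_stack.d == 23
    assert small_stack.channel_names[0] == "origin"
    assert list(small_stack.channel_names[1:]) == [s.name for s in default_registry()]
    assert len(KNOWN_FILTERS) == 22
    assert len(PILLOW_KERNELS) == 10


def test_empty_registry_stack_is_input(rng):
    vol = VolumeImage(rng.normal(size=(3, 10, 10)))
    stack = build_feature_stack(vol, registry=[])
    assert stack.d == 1
    assert stack.data[..., 0] == pytest.approx(vol.data, abs=1e-6)


def test_registry_order_and_determinism(rng):
    vol = VolumeImage(rng.uniform(0, 255, size=(2, 16, 16)))
    reg = [FilterSpec("mean"), FilterSpec("sobel")]
    s1 = build_feature_stack(vol, registry=reg)
    s2 = build_feature_stack(vol, registry=reg)
    assert s1.channel_names == ("origin", "mean", "sobel")
    assert np.array_equal(s1.data, s2.data)  # bitwise determinism
    direct = apply_filter(vol.data[0], FilterSpec("sobel"))
    np.testing.assert_allclose(s1.data[0, :, :, 2], direct, rtol=1e-4, atol=1e-3)


def test_unknown_filter_rejected():
    with pytest.raises(KeyError):
        FilterSpec("frangi")
    with pytest.raises(KeyError):
        pillow_kernel("pl_unknown")
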