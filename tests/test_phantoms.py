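import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cbctdiff.phantoms import (
    NULL_DEGRADATION,
    AnatomySpec,
    DegradationSpec,
    FormatError,
    PairedSample,
    PhantomError,
    cupping_field,
    degrade_to_cbct,
    fov_mask,
    generate_phantom_ct,
    make_pair_dataset,
    preprocess,
    resample_and_crop,
    to_hu,
)


# -- anatomy ----------------------------------------------------------------

def test_phantom_values_are_exactly_the_material_levels(rng):
    spec = AnatomySpec()
    img, body = generate_phantom_ct((64, 64), spec, rng)
    assert set(np.unique(img)) <= {spec.air_hu, spec.soft_tissue_hu, spec.bone_hu}
    assert img.shape == body.shape == (64, 64)


def test_body_area_fraction_in_plausible_range():
    fractions = []
    for seed in range(100):
        _, body = generate_phantom_ct((48, 48), AnatomySpec(), np.random.default_rng(seed))
        fractions.append(body.mean())
    assert 0.2 < min(fractions) and max(fractions) < 0.8


def test_phantom_is_seed_deterministic():
    a, _ = generate_phantom_ct((40, 40), AnatomySpec(), np.random.default_rng(5))
    b, _ = generate_phantom_ct((40, 40), AnatomySpec(), np.random.default_rng(5))
    np.testing.assert_array_equal(a, b)
    with pytest.raises(PhantomError):
        generate_phantom_ct((16, 16), AnatomySpec(), np.random.default_rng(0))


# -- degradations -----------------------------------------------------------

def test_null_degradation_is_identity(rng):
    img, _ = generate_phantom_ct((40, 40), AnatomySpec(), rng)
    np.testing.assert_array_equal(degrade_to_cbct(img, NULL_DEGRADATION, rng), img)


def test_bias_only_shift_matches_applied_field(rng):
    """With only the cupping bias active, the in-body HU shift equals the
    analytic field averaged over the body, to within 1 HU."""
    spec = dataclasses.replace(NULL_DEGRADATION, bias_amplitude=60.0)
    img, body = generate_phantom_ct(
        (48, 48), AnatomySpec(air_cavity_prob=0.0), rng
    )
    cbct = degrade_to_cbct(img, spec, rng)
    field = cupping_field((48, 48), 60.0)
    assert abs((cbct - img)[body].mean() - field[body].mean()) < 1.0


def test_noise_only_sd_matches_spec(rng):
    spec = dataclasses.replace(NULL_DEGRADATION, noise_sd=30.0)
    img, body = generate_phantom_ct((64, 64), AnatomySpec(air_cavity_prob=0.0), rng)
    cbct = degrade_to_cbct(img, spec, rng)
    sd = (cbct - img)[body].std()
    assert sd == pytest.approx(30.0, rel=0.1)


def test_fov_crop_fills_outside_with_air(rng):
    spec = dataclasses.replace(NULL_DEGRADATION, fov_radius_frac=0.5)
    img, _ = generate_phantom_ct((40, 40), AnatomySpec(), rng)
    cbct = degrade_to_cbct(img, spec, rng)
    outside = ~fov_mask((40, 40), 0.5)
    assert np.all(cbct[outside] == -1000.0)
    np.testing.assert_array_equal(cbct[~outside], img[~outside])


def test_invalid_degradation_spec_raises():
    with pytest.raises(PhantomError):
        DegradationSpec(noise_sd=-1.0)
    with pytest.raises(PhantomError):
        DegradationSpec(fov_radius_frac=0.0)


# -- dataset ----------------------------------------------------------------

def test_pair_dataset_reproducible_and_valid():
    kw = dict(
        anatomy_spec=AnatomySpec(), degradation_spec=DegradationSpec(), shape=(32, 32)
    )
    a = make_pair_dataset(5, rng=np.random.default_rng(3), **kw)
    b = make_pair_dataset(5, rng=np.random.default_rng(3), **kw)
    assert len(a) == 5
    for s1, s2 in zip(a, b):
        np.testing.assert_array_equal(s1.pct, s2.pct)
        np.testing.assert_array_equal(s1.cbct, s2.cbct)
        assert s1.unit_tag == "HU"
        assert s1.pct.min() >= -1000 and s1.pct.max() <= 3000
        assert s1.cbct.min() >= -1000 and s1.cbct.max() <= 3000
    # distinct anatomies across the set
    assert np.abs(a[0].pct - a[1].pct).max() > 0


def test_paired_sample_shape_invariant_enforced(rng):
    with pytest.raises(PhantomError):
        PairedSample(
            pct=np.zeros((8, 8)), cbct=np.zeros((8, 8)), fov_mask=np.ones((4, 4), bool)
        )


def test_preprocessed_pairs_are_normalized(rng):
    s = make_pair_dataset(1, AnatomySpec(), DegradationSpec(), rng)[0]
    n = s.preprocessed()
    assert n.unit_tag == "normalized"
    assert n.pct.min() >= -1.0 and n.pct.max() <= 1.0
    np.testing.assert_allclose(to_hu(n.pct), s.pct, atol=1e-9)


# -- intensity maps ---------------------------------------------------------

def test_preprocess_anchor_points():
    vals = np.array([-1000.0, 3000.0, 1000.0, 5000.0, -2000.0])
    np.testing.assert_allclose(preprocess(vals), [-1.0, 1.0, 0.0, 1.0, -1.0])


def test_to_hu_anchor_points_and_range_guard():
    np.testing.assert_allclose(to_hu(np.array([0.0, -1.0, 1.0])), [1000.0, -1000.0, 3000.0])
    with pytest.raises(PhantomError):
        to_hu(np.array([1.5]))


@settings(deadline=None, max_examples=50)
@given(st.floats(min_value=-5000, max_value=9000, allow_nan=False))
def test_roundtrip_is_clamped_identity(hu):
    assert to_hu(preprocess(np.array([hu])))[0] == pytest.approx(
        np.clip(hu, -1000, 3000), abs=1e-9
    )


# -- FOV mask ---------------------------------------------------------------

def test_full_radius_mask_touches_edge_midpoints():
    m = fov_mask((33, 33), 1.0)
    assert m[16, 0] and m[16, 32] and m[0, 16] and m[32, 16]
    assert not m[0, 0]


def test_mask_area_approaches_circle_area():
    m = fov_mask((256, 256), 0.8)
    r = 0.8 * 128
    assert m.sum() == pytest.approx(np.pi * r**2, rel=0.02)


def test_small_mask_lies_inside_default_bodies():
    for seed in range(10):
        rng = np.random.default_rng(seed)
        _, body = generate_phantom_ct((48, 48), AnatomySpec(), rng)
        m = fov_mask((48, 48), 0.3)
        assert np.all(body[m])


# -- resampling -------------------------------------------------------------

def test_identity_resample_and_matching_crop_is_noop(rng):
    vol = rng.uniform(-1000, 3000, (4, 64, 64))
    out = resample_and_crop(vol, (3.0, 1.0, 1.0), crop_size=64)
    np.testing.assert_allclose(out, vol)


def test_upsampling_constant_volume_stays_constant():
    vol = np.full((2, 32, 32), 40.0)
    out = resample_and_crop(vol, (3.0, 2.0, 2.0), crop_size=64)
    np.testing.assert_allclose(out, 40.0)


def test_center_crop_retains_central_region(rng):
    vol = rng.uniform(-1000, 3000, (1, 300, 300))
    out = resample_and_crop(vol, (3.0, 1.0, 1.0), crop_size=256)
    np.testing.assert_allclose(out[0], vol[0, 22:278, 22:278])


def test_pad_with_air_when_smaller_than_crop():
    vol = np.full((1, 100, 100), 500.0)
    out = resample_and_crop(vol, (3.0, 1.0, 1.0), crop_size=128)
    assert out.shape == (1, 128, 128)
    assert out[0, 0, 0] == -1000.0
    assert out[0, 64, 64] == 500.0


def test_missing_spacing_metadata_is_a_format_error():
    with pytest.raises(FormatError):
        resample_and_crop(np.zeros((2, 8, 8)), None)
    with pytest.raises(FormatError):
        resample_and_crop(np.zeros((8, 8)), (1.0, 1.0, 1.0))
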