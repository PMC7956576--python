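import numpy as np
import pytest
from scipy.spatial.distance import cdist

from htsim.phantom import (HeatingSetting, PhantomConfig, build_phantom,
                           reference_slices, region_masks)
from htsim.volumes import LabelVolume, TISSUE_LABELS, Tissue


def test_default_phantom_contains_expected_labels(coarse_phantom):
    present = {Tissue(int(v)) for v in np.unique(coarse_phantom.labels)}
    for t in (Tissue.MUSCLE, Tissue.FAT_SUBCUTANEOUS, Tissue.BONE,
              Tissue.TUMOR, Tissue.REGULAR_BOLUS, Tissue.OVERLAY_BOLUS,
              Tissue.ELECTRODE):
        assert t in present


def test_no_overlay_bolus_means_zero_ob_voxels(coarse_config):
    vol = build_phantom(coarse_config, HeatingSetting(use_overlay_bolus=False))
    assert not np.any(vol.labels == int(Tissue.OVERLAY_BOLUS))


def test_igc_flag_fills_cleft(coarse_config):
    on = build_phantom(coarse_config, HeatingSetting(use_igc_bolus=True))
    off = build_phantom(coarse_config, HeatingSetting(use_igc_bolus=False))
    igc = on.labels == int(Tissue.IGC_BOLUS)
    assert igc.any()
    assert not np.any(off.labels == int(Tissue.IGC_BOLUS))
    # the cleft region is air when the bolus is absent
    assert np.all(off.labels[igc] == int(Tissue.AIR))


def test_tumor_voxelization_matches_sphere_volume():
    """Voxelized tumor volume within 5% of (4/3) pi r^3 for h <= r/10."""
    config = PhantomConfig(spacing=0.003, torso_length=0.30)
    vol = build_phantom(config, HeatingSetting())
    n = int(np.sum(vol.labels == int(Tissue.TUMOR)))
    v_exact = 4.0 / 3.0 * np.pi * config.tumor_radius ** 3
    assert n * vol.voxel_volume == pytest.approx(v_exact, rel=0.05)


def test_tumor_escaping_muscle_raises(coarse_config):
    import dataclasses
    bad = dataclasses.replace(coarse_config, tumor_center_y=0.09)
    with pytest.raises(ValueError, match="tumor"):
        build_phantom(bad, HeatingSetting())


def test_determinism(coarse_config):
    a = build_phantom(coarse_config, HeatingSetting())
    b = build_phantom(coarse_config, HeatingSetting())
    assert np.array_equal(a.labels, b.labels)


def test_midsagittal_symmetry(coarse_phantom):
    assert np.array_equal(coarse_phantom.labels, coarse_phantom.labels[::-1])


def test_volume_fractions_converge_on_refinement():
    """Tissue volume fractions change <2% when halving voxel spacing."""
    fracs = {}
    for h in (0.003, 0.0015):
        vol = build_phantom(PhantomConfig.fast_2d(spacing=h), HeatingSetting())
        body = vol.body_mask().sum()
        fracs[h] = {t: np.sum(vol.labels == int(t)) / body for t in TISSUE_LABELS}
    for t in TISSUE_LABELS:
        assert fracs[0.003][t] == pytest.approx(fracs[0.0015][t], rel=0.02)


def test_heating_setting_defaults_and_validation():
    conv = HeatingSetting()
    assert (conv.rb_concentration, conv.rb_temperature) == (5.0, 10.0)
    no_ob = HeatingSetting(use_overlay_bolus=False)
    assert (no_ob.rb_concentration, no_ob.rb_temperature) == (0.5, 5.0)
    with pytest.raises(ValueError, match="tabulated"):
        HeatingSetting(ob_concentration=2.0)
    with pytest.warns(UserWarning, match="40-70"):
        HeatingSetting(electrode_potential=90.0)


def test_config_yaml_round_trip(tmp_path, coarse_config):
    path = tmp_path / "phantom.yaml"
    coarse_config.to_yaml(path)
    text = path.read_text()
    assert "torso_half_width_m" in text  # unit-suffixed keys
    back = PhantomConfig.from_yaml(path)
    assert back == coarse_config


# ---------------------------------------------------------------------------
# region masks
# ---------------------------------------------------------------------------

def _toy_volume() -> LabelVolume:
    """Hand-built 20^3 volume: a flat OB slab over an SF layer."""
    labels = np.zeros((20, 20, 20), dtype=np.int16)
    labels[:, :8, :] = int(Tissue.MUSCLE)
    labels[:, 8:11, :] = int(Tissue.FAT_SUBCUTANEOUS)
    labels[4:16, 11:13, 4:16] = int(Tissue.OVERLAY_BOLUS)  # bolus footprint 12x12
    labels[7:13, 14, 7:13] = int(Tissue.ELECTRODE)
    labels[2:18, 2:4, 2:18] = int(Tissue.REGULAR_BOLUS)  # irrelevant side pad
    return LabelVolume(labels, 0.005)


def test_sf_edge_matches_brute_force_distance():
    vol = _toy_volume()
    band = 0.012
    masks = region_masks(vol, edge_band_width=band)
    # brute force: rim voxels = OB voxels whose (x,z) footprint cell is on
    # the footprint boundary (8-connected erosion)
    from scipy import ndimage
    ob = vol.labels == int(Tissue.OVERLAY_BOLUS)
    fp = ob.any(axis=1)
    rim2d = fp & ~ndimage.binary_erosion(
        fp, structure=ndimage.generate_binary_structure(2, 2))
    rim3d = ob & rim2d[:, None, :]
    sf = vol.labels == int(Tissue.FAT_SUBCUTANEOUS)
    pts_sf = np.argwhere(sf) * 0.005
    pts_rim = np.argwhere(rim3d) * 0.005
    dmin = cdist(pts_sf, pts_rim).min(axis=1)
    expected = np.zeros_like(sf)
    expected[tuple(np.argwhere(sf)[dmin <= band + 1e-12].T)] = True
    assert np.array_equal(masks["sf_edge"], expected)


def test_zero_band_width_gives_empty_edge():
    masks = region_masks(_toy_volume(), edge_band_width=0.0)
    assert not masks["sf_edge"].any()


def test_rim_is_rb_when_no_overlay_bolus(coarse_config):
    """Without OBs the 2 cm band hugs the regular-bolus rim instead."""
    setting = HeatingSetting(use_overlay_bolus=False)
    vol = build_phantom(coarse_config, setting)
    masks = region_masks(vol, edge_band_width=0.02)
    rb_pts = np.argwhere(vol.labels == int(Tissue.REGULAR_BOLUS)) * vol.spacing
    edge_pts = np.argwhere(masks["sf_edge"]) * vol.spacing
    assert edge_pts.size
    assert cdist(edge_pts, rb_pts).min(axis=1).max() <= 0.02 + 1e-9


def test_empty_bolus_raises():
    labels = np.full((6, 6, 6), int(Tissue.MUSCLE), dtype=np.int16)
    with pytest.raises(ValueError, match="bolus"):
        region_masks(LabelVolume(labels, 0.005))


def test_sf_under_electrode_within_footprint(coarse_phantom):
    masks = region_masks(coarse_phantom)
    fp = (coarse_phantom.labels == int(Tissue.ELECTRODE)).any(axis=1)
    assert masks["sf_under_electrode"].any()
    assert not np.any(masks["sf_under_electrode"] & ~fp[:, None, :])


# ---------------------------------------------------------------------------
# reference slices
# ---------------------------------------------------------------------------

def test_reference_slices(coarse_phantom):
    from scipy import ndimage
    secs = reference_slices(coarse_phantom)
    tumor = coarse_phantom.labels == int(Tissue.TUMOR)
    ck = int(round(ndimage.center_of_mass(tumor)[2]))
    assert np.all(secs["axial_tumor"][2] == ck)
    body = coarse_phantom.body_mask()
    ys = coarse_phantom.axis_coords(1)
    for name, (i, j, k) in secs.items():
        assert body[i, j, k].any(), f"section {name} misses the body"
    # dorsal line passes through the dorsal SF centroid depth
    sf = coarse_phantom.labels == int(Tissue.FAT_SUBCUTANEOUS)
    dorsal = sf & (ys[None, :, None] > 0)
    j_c = int(round(ndimage.center_of_mass(dorsal)[1]))
    assert np.all(secs["dorsal_sf_line_e"][1] == j_c)
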