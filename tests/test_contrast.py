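"""Size and anisotropy subtraction contrasts, scalar and voxel-wise."""

import numpy as np
import pytest

from mdetune import (
    anisotropy_contrast,
    default_protocol,
    make_phantom,
    predict_signals,
    render_volume,
    roi_mean,
    size_contrast,
    voxelwise_maps,
)

OVERLAP = 0.01   # curves "overlap" below this |dE|
DIVERGE = 0.03   # curves "diverge" above this |dE|


@pytest.fixture(scope="module")
def proto():
    return default_protocol(n_orientations=12)


@pytest.fixture(scope="module")
def phantom_curves(proto):
    return {kind: predict_signals(make_phantom(kind), proto)
            for kind in ("polymer", "yeast", "liquid_crystal", "microfibers")}


@pytest.fixture(scope="module")
def b_star(proto):
    return proto.b_values[-1]


class TestScalarContrasts:
    def test_polymer_both_contrasts_vanish(self, phantom_curves, b_star):
        c = phantom_curves["polymer"]
        assert abs(size_contrast(c["tuned"], c["detuned"], b_star).value) <= OVERLAP
        assert abs(anisotropy_contrast(c["tuned"], c["isotropic"], b_star).value) <= OVERLAP

    def test_yeast_size_only(self, phantom_curves, b_star):
        c = phantom_curves["yeast"]
        assert size_contrast(c["tuned"], c["detuned"], b_star).value >= DIVERGE
        assert abs(anisotropy_contrast(c["tuned"], c["isotropic"], b_star).value) <= OVERLAP

    def test_liquid_crystal_anisotropy_only(self, phantom_curves, b_star):
        c = phantom_curves["liquid_crystal"]
        assert abs(size_contrast(c["tuned"], c["detuned"], b_star).value) <= OVERLAP
        assert anisotropy_contrast(c["tuned"], c["isotropic"], b_star).value >= DIVERGE

    def test_microfibers_both_contrasts(self, phantom_curves, b_star):
        c = phantom_curves["microfibers"]
        assert size_contrast(c["tuned"], c["detuned"], b_star).value >= DIVERGE
        assert anisotropy_contrast(c["tuned"], c["isotropic"], b_star).value >= DIVERGE

    def test_missing_b_star_rejected(self, phantom_curves):
        c = phantom_curves["yeast"]
        with pytest.raises(ValueError):
            size_contrast(c["tuned"], c["detuned"], 9.9e9)

    def test_contrast_linear_in_fractions_at_low_b(self, proto):
        # signal differences proportional to component signal fractions
        from mdetune import CompartmentSystem

        b_low = proto.b_values[1]  # lowest non-zero b: b <ADC> << 1
        values = {}
        for f in (0.25, 0.5, 1.0):
            yeast = make_phantom("yeast", f_restricted=f)
            c = predict_signals(yeast, proto)
            values[f] = size_contrast(c["tuned"], c["detuned"], b_low).value
        ratio_half = values[0.5] / values[1.0]
        ratio_quarter = values[0.25] / values[1.0]
        assert ratio_half == pytest.approx(0.5, abs=0.05)
        assert ratio_quarter == pytest.approx(0.25, abs=0.05)

    def test_quadrant_stratification(self, phantom_curves, b_star):
        # the 2x2 (size, anisotropy) plane separates the four archetypes
        quadrant = {}
        for kind, c in phantom_curves.items():
            s = size_contrast(c["tuned"], c["detuned"], b_star).value
            a = anisotropy_contrast(c["tuned"], c["isotropic"], b_star).value
            quadrant[kind] = (s >= DIVERGE, a >= DIVERGE)
        assert quadrant == {"polymer": (False, False), "yeast": (True, False),
                            "liquid_crystal": (False, True),
                            "microfibers": (True, True)}


@pytest.fixture(scope="module")
def two_region():
    from mdetune.phantoms import default_b_grid

    proto = default_protocol(n_orientations=6, b_values=default_b_grid(n=6))
    labels = np.zeros((6, 4, 1), dtype=int)
    labels[:3] = 1   # yeast
    labels[3:] = 2   # polymer
    systems = {1: make_phantom("yeast"), 2: make_phantom("polymer")}
    vol, sidecar, voxel = render_volume(labels, systems, proto)
    return proto, labels, vol, sidecar, voxel


class TestVoxelwiseMaps:
    def test_noiseless_two_region_maps(self, two_region):
        proto, labels, vol, sidecar, voxel = two_region
        maps = voxelwise_maps(vol, sidecar, b_star=proto.b_values[-1])
        yeast_size, _ = roi_mean(maps["size"], labels, 1)
        polymer_size, _ = roi_mean(maps["size"], labels, 2)
        yeast_aniso, _ = roi_mean(maps["anisotropy"], labels, 1)
        assert yeast_size >= DIVERGE
        assert abs(polymer_size) <= OVERLAP
        assert abs(yeast_aniso) <= OVERLAP

    def test_smoothing_mixes_regions(self, two_region):
        proto, labels, vol, sidecar, voxel = two_region
        sharp = voxelwise_maps(vol, sidecar, b_star=proto.b_values[-1])
        smooth = voxelwise_maps(vol, sidecar, b_star=proto.b_values[-1],
                                fwhm_mm=2.0, voxel_size_mm=voxel)
        # smoothing preserves the mean but reduces the contrast step
        assert smooth["size"].mean() == pytest.approx(sharp["size"].mean(), rel=0.05)
        step_sharp = sharp["size"][2].mean() - sharp["size"][3].mean()
        step_smooth = smooth["size"][2].mean() - smooth["size"][3].mean()
        assert abs(step_smooth) < abs(step_sharp)

    def test_noisy_region_means_within_tolerance(self, two_region):
        proto, labels, vol, sidecar, voxel = two_region
        noiseless = voxelwise_maps(vol, sidecar, b_star=proto.b_values[-1])
        from mdetune import add_rician_noise

        noisy_vol = add_rician_noise(vol, snr=50.0, seed=21)
        noisy = voxelwise_maps(noisy_vol, sidecar, b_star=proto.b_values[-1])
        for name in ("size", "anisotropy"):
            m0, _ = roi_mean(noiseless[name], labels, 1)
            m1, s1 = roi_mean(noisy[name], labels, 1)
            n_vox = int((labels == 1).sum())
            assert abs(m1 - m0) <= 3.0 * max(s1, 1e-3) / np.sqrt(n_vox) + 5e-3

    def test_missing_encoding_rejected(self, two_region):
        proto, labels, vol, sidecar, voxel = two_region
        side2 = sidecar[sidecar.waveform != "detuned"].reset_index(drop=True)
        with pytest.raises(ValueError, match="detuned"):
            voxelwise_maps(vol[..., :len(side2)], side2, b_star=proto.b_values[-1])


class TestRoiMean:
    def test_uniform_map(self):
        labels = np.ones((4, 4, 1), dtype=int)
        m, s = roi_mean(np.full((4, 4, 1), 0.7), labels, 1)
        assert m == 0.7 and s == 0.0

    def test_single_voxel_roi(self):
        labels = np.zeros((3, 3, 1), dtype=int)
        labels[1, 1, 0] = 5
        field = np.arange(9.0).reshape(3, 3, 1)
        m, s = roi_mean(field, labels, 5)
        assert m == field[1, 1, 0] and s == 0.0

    def test_partition_identity(self):
        labels = np.zeros((4, 4, 1), dtype=int)
        labels[:2] = 1
        labels[2:] = 2
        field = np.random.default_rng(0).uniform(size=(4, 4, 1))
        m1, _ = roi_mean(field, labels, 1)
        m2, _ = roi_mean(field, labels, 2)
        assert 0.5 * (m1 + m2) == pytest.approx(field.mean(), rel=1e-12)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            roi_mean(np.zeros((2, 2, 1)), np.zeros((2, 2, 1), dtype=int), 3)
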