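"""The synthetic renderer must honor its own ground truth: dose-response
shape, determinism, and the photometric meaning of each device knob."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lfaquant.errors import DegeneratePoseError
from lfaquant.layout import DeviceModel, DoseResponse, Pose, StripLayout
from lfaquant.synthetic import (
    dose_response_density,
    generate_validation_panel,
    line_densities,
    make_paired_captures,
    render_strip,
)


class TestDoseResponse:
    def test_zero_analyte_gives_floor(self):
        dr = DoseResponse(d_max=1.0, k_half=50.0, floor=0.01)
        assert dose_response_density(0.0, dr) == pytest.approx(0.01)

    def test_saturation_limit(self):
        dr = DoseResponse(d_max=1.0, k_half=50.0, floor=0.01)
        assert dose_response_density(1e9, dr) == pytest.approx(1.01, rel=1e-6)

    def test_half_saturation(self):
        dr = DoseResponse(d_max=1.0, k_half=50.0, floor=0.0)
        assert dose_response_density(50.0, dr) == pytest.approx(0.5)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            dose_response_density(-1.0, DoseResponse())

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(min_value=0, max_value=500), st.floats(min_value=0, max_value=500))
    def test_strictly_increasing_and_bounded(self, a, b):
        dr = DoseResponse()
        lo, hi = sorted((a, b))
        d_lo, d_hi = dr.density(lo), dr.density(hi)
        if hi - lo > 1e-9:  # strict except below float resolution of the floor
            assert d_hi > d_lo
        assert d_lo <= d_hi <= dr.floor + dr.d_max


class TestRenderStrip:
    def test_blank_test_line_indistinguishable_from_substrate(self, layout, dr_no_floor):
        img, _ = render_strip(layout, 0.0, dr_no_floor)
        lo, hi = layout.line_window("T")
        t_window = img.pixels[:, lo:hi, :]
        substrate = img.pixels[:, hi + 40 : hi + 60, :]
        assert np.abs(t_window.mean(axis=(0, 1)) - substrate.mean(axis=(0, 1))).max() < 1e-6

    def test_determinism_identical_bytes(self, layout, dr, framed_pose):
        dev = DeviceModel()
        a, _ = render_strip(layout, 30.0, dr, dev, framed_pose, seed=7)
        b, _ = render_strip(layout, 30.0, dr, dev, framed_pose, seed=7)
        assert np.array_equal(a.pixels, b.pixels)

    def test_test_line_darkens_with_concentration(self, layout, dr):
        lo, hi = layout.line_window("T")
        img_hi, _ = render_strip(layout, 100.0, dr)
        img_lo, _ = render_strip(layout, 5.0, dr)
        assert img_hi.pixels[:, lo:hi, 1].mean() < img_lo.pixels[:, lo:hi, 1].mean()

    def test_reference_densities_invariant_to_concentration(self, layout, dr):
        d5 = line_densities(layout, 5.0, dr)
        d100 = line_densities(layout, 100.0, dr)
        for k in ("ref1", "ref2", "ref3", "ref4", "ref5", "C"):
            assert d5[k] == d100[k]

    def test_degenerate_pose_rejected(self, layout):
        with pytest.raises(DegeneratePoseError):
            Pose(((10, 10), (10, 200), (10, 400), (10, 500)), (260, 720))

    def test_srgb_device_tags_color_space(self, layout, dr):
        img, _ = render_strip(layout, 20.0, dr, DeviceModel(noise_sd=0.0))
        assert img.color_space == "srgb"


class TestPairedCaptures:
    def test_identical_devices_identical_images(self, layout, dr, identity_device):
        a, b, _ = make_paired_captures(layout, 40.0, dr, identity_device, identity_device, seed=3)
        assert np.array_equal(a.pixels, b.pixels)

    def test_same_device_differs_only_by_noise(self, layout, dr):
        dev = DeviceModel(noise_sd=0.004)
        a, b, _ = make_paired_captures(layout, 40.0, dr, dev, dev, seed=3)
        diff = a.pixels - b.pixels
        assert not np.array_equal(a.pixels, b.pixels)
        # independent zero-mean noise: difference is small and unbiased
        assert abs(diff.mean()) < 1e-4
        assert diff.std() == pytest.approx(np.sqrt(2) * 0.004, rel=0.1)

    def test_white_balance_tint_shows_in_neutral_zone(self, layout, dr, identity_device):
        tinted = DeviceModel(wb_gains=(1.2, 1.0, 0.9), gamma="none", noise_sd=0.0)
        a, b, _ = make_paired_captures(layout, 40.0, dr, identity_device, tinted, seed=5)
        r0, r1, c0, c1 = layout.neutral_zone_px()
        ratios = b.pixels[r0:r1, c0:c1].mean(axis=(0, 1)) / a.pixels[r0:r1, c0:c1].mean(axis=(0, 1))
        assert ratios == pytest.approx((1.2, 1.0, 0.9), rel=1e-6)


class TestValidationPanel:
    def test_counts_and_level_metadata(self, layout, dr):
        panel = generate_validation_panel([(0.0, 20), (5.0, 20)], seed=1, layout=layout, dr=dr)
        assert len(panel) == 40
        assert sum(t.true_concentration == 0.0 for _, t in panel) == 20

    def test_eight_level_design(self, layout, dr):
        levels = [(c, 5) for c in (5, 10, 20, 30, 45, 60, 80, 100)]
        panel = generate_validation_panel(levels, seed=2, layout=layout, dr=dr)
        assert len(panel) == 40
        concs = [t.true_concentration for _, t in panel]
        for c, _ in levels:
            assert concs.count(float(c)) == 5

    def test_panel_deterministic(self, layout, dr):
        p1 = generate_validation_panel([(10.0, 2)], seed=9, layout=layout, dr=dr)
        p2 = generate_validation_panel([(10.0, 2)], seed=9, layout=layout, dr=dr)
        for (a, _), (b, _) in zip(p1, p2):
            assert np.array_equal(a.pixels, b.pixels)

    def test_writes_manifest_and_sidecars(self, tmp_path, layout, dr):
        generate_validation_panel([(10.0, 2)], seed=4, layout=layout, dr=dr, out_dir=tmp_path)
        assert (tmp_path / "manifest.csv").exists()
        assert len(list(tmp_path.glob("*.png"))) == 2
        assert len(list(tmp_path.glob("*.truth.json"))) == 2
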