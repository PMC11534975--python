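"""Acquisition-geometry arithmetic, volume assembly, MPR and I/O round-trips."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from uro3d import (
    AcquisitionGeometry,
    FrameStack,
    LabelVolume,
    Volume,
    assemble_volume,
    compute_frame_count,
    compute_slice_spacing,
    disassemble_volume,
    extract_plane,
)
from uro3d.io import (
    read_geometry,
    read_label_volume,
    read_stack,
    read_volume,
    write_geometry,
    write_label_volume,
    write_stack,
    write_volume,
)


class TestFrameArithmetic:
    @pytest.mark.parametrize(
        "time_s,rate_hz,expected",
        [(21, 20, 420), (1, 1, 1), (10, 100, 1000), (0.55, 1, 1), (1.25, 2, 3)],
    )
    def test_frame_count(self, time_s, rate_hz, expected):
        assert compute_frame_count(time_s, rate_hz) == expected

    @pytest.mark.parametrize("bad", [(0, 20), (21, 0), (-1, 20)])
    def test_frame_count_rejects_nonpositive(self, bad):
        with pytest.raises(ValueError):
            compute_frame_count(*bad)

    @pytest.mark.parametrize(
        "travel,count,expected",
        [(35, 420, 0.0833), (10, 100, 0.1), (35, 1, 35.0)],
    )
    def test_slice_spacing(self, travel, count, expected):
        assert compute_slice_spacing(travel, count) == pytest.approx(expected, abs=5e-5)

    def test_slice_spacing_rejects_bad_count(self):
        with pytest.raises(ValueError):
            compute_slice_spacing(35, 0)

    @given(
        travel=st.floats(0.1, 100),
        time_s=st.floats(0.1, 60),
        rate=st.floats(0.5, 100),
    )
    def test_travel_conservation(self, travel, time_s, rate):
        n = compute_frame_count(time_s, rate)
        assert compute_slice_spacing(travel, n) * n == pytest.approx(travel, abs=1e-12)

    def test_geometry_reference_acquisition(self):
        g = AcquisitionGeometry()
        assert g.frame_count == 420
        assert g.slice_spacing_mm == pytest.approx(0.0833, abs=5e-5)
        z = g.slice_positions_mm()
        assert z[0] == 0.0
        assert len(z) == 420


class TestAssembly:
    def test_stacking_preserves_shape_and_values(self, rng):
        frames = [rng.random((4, 4)) for _ in range(3)]
        g = AcquisitionGeometry(travel_mm=3, scan_time_s=3, frame_rate_hz=1)
        vol = assemble_volume(FrameStack(frames=frames, geometry=g))
        assert vol.shape == (4, 4, 3)
        for k in range(3):
            np.testing.assert_array_equal(vol.voxels[:, :, k], frames[k])
        assert vol.voxel_mm[2] == pytest.approx(1.0)

    def test_reference_spacing_propagates(self, rng):
        g = AcquisitionGeometry()  # 35 mm / 420 frames
        frames = [rng.random((4, 4)) for _ in range(5)]
        vol = assemble_volume(FrameStack(frames=frames, geometry=g))
        assert vol.voxel_mm[2] == pytest.approx(0.0833, abs=5e-5)

    def test_round_trip_bijection(self, rng):
        frames = [rng.random((6, 5)) for _ in range(4)]
        g = AcquisitionGeometry(travel_mm=4, scan_time_s=4, frame_rate_hz=1)
        stack = FrameStack(frames=frames, geometry=g)
        back = disassemble_volume(assemble_volume(stack), g)
        assert len(back) == 4
        for f0, f1 in zip(frames, back.frames):
            np.testing.assert_array_equal(f0, f1)

    def test_heterogeneous_shapes_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            FrameStack(frames=[rng.random((4, 4)), rng.random((5, 4))])

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            assemble_volume(FrameStack(frames=[]))


class TestExtractPlane:
    def test_axial_identity(self, rng):
        frames = [rng.random((5, 5)) for _ in range(3)]
        g = AcquisitionGeometry(travel_mm=3, scan_time_s=3, frame_rate_hz=1)
        vol = assemble_volume(FrameStack(frames=frames, geometry=g))
        img, px = extract_plane(vol, "axial", 1)
        np.testing.assert_array_equal(img, frames[1])
        assert px == (vol.voxel_mm[0], vol.voxel_mm[1])

    def test_mid_sagittal_mirror_symmetry(self, small_geometry):
        # fibrosis-free phantom: mirror-symmetric about the tube axis
        from uro3d import PhantomSpec, generate_labels

        spec = PhantomSpec(
            geometry=small_geometry,
            frame_shape=(64, 64),
            stricture_length_mm=14.0,
            stricture_depth=0.8,
            fibrosis_pattern="none",
            speckle_sigma=0.0,
        )
        labels = generate_labels(spec)
        vol = Volume(voxels=labels.labels.astype(float), voxel_mm=labels.voxel_mm)
        mid = vol.shape[1] // 2  # centred at (n-1)/2: columns mid and mid-1 mirror
        img_a, _ = extract_plane(vol, "sagittal", mid)
        img_b, _ = extract_plane(vol, "sagittal", vol.shape[1] - 1 - mid)
        np.testing.assert_allclose(img_a, img_b, atol=1e-12)
        # each sagittal image is also its own mirror across the row axis
        np.testing.assert_allclose(img_a, img_a[::-1, :], atol=1e-12)

    def test_sagittal_pixel_sizes_anisotropic(self, noiseless_labels):
        _, px = extract_plane(noiseless_labels, "sagittal", 10)
        assert px == (noiseless_labels.voxel_mm[0], noiseless_labels.voxel_mm[2])

    def test_sagittal_narrowing_matches_phantom(self, noiseless_spec, noiseless_labels):
        """The lumen band in the mid-sagittal MPR narrows at the stricture centre."""
        mid = noiseless_labels.shape[1] // 2
        img, _ = extract_plane(noiseless_labels, "sagittal", mid)
        lumen_width = (img == 1).sum(axis=0)  # per-slice width in the sagittal plane
        spacing = noiseless_labels.voxel_mm[2]
        centre_idx = int(round(noiseless_spec.stricture_center_mm / spacing))
        assert lumen_width[centre_idx] < lumen_width[5]
        # the narrowest column lies within the stricture segment
        half = noiseless_spec.stricture_length_mm / 2 / spacing
        assert abs(np.argmin(lumen_width) - centre_idx) <= half

    def test_out_of_bounds(self, noiseless_labels):
        with pytest.raises(IndexError):
            extract_plane(noiseless_labels, "axial", noiseless_labels.shape[2])


class TestIO:
    def test_volume_nifti_round_trip(self, tmp_path, rng):
        vol = Volume(voxels=rng.random((8, 8, 5)), voxel_mm=(0.1, 0.12, 0.0833))
        path = write_volume(vol, tmp_path / "v.nii.gz")
        back = read_volume(path)
        np.testing.assert_allclose(back.voxels, vol.voxels, atol=1e-6)
        np.testing.assert_allclose(back.voxel_mm, vol.voxel_mm, rtol=1e-6)

    def test_label_volume_round_trip_exact(self, tmp_path, rng):
        labels = LabelVolume(
            labels=rng.integers(0, 4, size=(6, 6, 4)).astype(np.uint8),
            voxel_mm=(0.1, 0.1, 0.5),
        )
        back = read_label_volume(write_label_volume(labels, tmp_path / "l.nii.gz"))
        np.testing.assert_array_equal(back.labels, labels.labels)

    @pytest.mark.parametrize("fmt", ["tiff", "png"])
    def test_stack_round_trip_on_integer_grid(self, tmp_path, rng, fmt):
        # frames living exactly on the uint16 grid survive bit-exactly
        raw = rng.integers(0, 65536, size=(3, 8, 8))
        frames = [r / 65535.0 for r in raw]
        g = AcquisitionGeometry(travel_mm=3, scan_time_s=3, frame_rate_hz=1)
        dest = tmp_path / ("s.tiff" if fmt == "tiff" else "frames")
        path = write_stack(FrameStack(frames=frames, geometry=g), dest, fmt=fmt)
        back = read_stack(path)
        assert len(back) == 3
        for f0, f1 in zip(frames, back.frames):
            np.testing.assert_array_equal(f0, f1)
        assert back.geometry == g

    def test_missing_sidecar_is_metadata_error(self, tmp_path, rng):
        import tifffile

        tifffile.imwrite(tmp_path / "s.tiff", rng.integers(0, 255, (2, 4, 4)).astype(np.uint8))
        with pytest.raises(FileNotFoundError, match="geometry"):
            read_stack(tmp_path / "s.tiff")

    def test_unknown_extension_rejected(self, tmp_path, rng):
        vol = Volume(voxels=rng.random((2, 2, 2)), voxel_mm=(1, 1, 1))
        with pytest.raises(ValueError, match="format"):
            write_volume(vol, tmp_path / "v.mha")

    def test_geometry_sidecar_round_trip(self, tmp_path):
        g = AcquisitionGeometry(pixel_mm=(0.08, 0.11))
        assert read_geometry(write_geometry(g, tmp_path / "geometry.json")) == g
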