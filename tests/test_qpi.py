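"""Phase-image morphometry: preprocessing, seeding, watershed, measurement."""

import heapq
import math

import numpy as np
import pytest

from stromakit.qpi import (
    CellObject,
    PhaseFrame,
    SegmentationParams,
    consolidate_seeds,
    detect_seeds,
    measure_cells,
    preprocess_frame,
    segment_cells,
    segment_frame,
)
from stromakit.synthetic import PopulationSpec, TimelapseSpec, generate_timelapse

from conftest import render_ellipse


def brute_force_ball_background(img, radius, height):
    """Independent rolling-ball background by direct loops.

    A ball (ellipsoid: spatial radius x intensity height) is pushed up
    under the surface at every position; its apex height there is
    background[p] = min_s(img[p+s] + drop(s)) with
    drop(s) = height * (1 - sqrt(1 - |s|^2/radius^2)).
    """
    r = int(radius)
    offs = []
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            rho2 = (dy * dy + dx * dx) / (radius * radius)
            if rho2 <= 1:
                offs.append((dy, dx, height * (1.0 - math.sqrt(1 - rho2))))
    h, w = img.shape
    pad = np.pad(img, r, mode="constant", constant_values=np.inf)
    out = np.full((h, w), np.inf)
    for dy, dx, drop in offs:
        out = np.minimum(out, pad[r + dy : r + dy + h, r + dx : r + dx + w] + drop)
    return out


def brute_force_flood(img, seeds, mask):
    """Priority flood from seeds over -img within mask (independent oracle)."""
    labels = np.zeros(img.shape, dtype=int)
    heap = []
    for k, (r, c) in enumerate(seeds, start=1):
        labels[r, c] = k
        heapq.heappush(heap, (-img[r, c], int(r), int(c)))
    order = 0
    while heap:
        _, r, c = heapq.heappop(heap)
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < img.shape[0] and 0 <= cc < img.shape[1]:
                if mask[rr, cc] and labels[rr, cc] == 0:
                    labels[rr, cc] = labels[r, c]
                    order += 1
                    heapq.heappush(heap, (-img[rr, cc], rr, cc))
    return labels


class TestPreprocess:
    def test_constant_frame_becomes_zero(self):
        frame = PhaseFrame(np.full((64, 64), 0.7), pixel_size=1.0)
        params = SegmentationParams(rolling_ball_radius=10)
        out = preprocess_frame(frame, params)
        assert np.allclose(out.pixels, 0.0, atol=1e-9)

    def test_ramp_removed_blob_peak_preserved(self):
        h = w = 96
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        ramp = 0.3 * xx / w
        blob = render_ellipse((h, w), center=(48, 40), a=8, b=8, peak=1.0, power=1)
        frame = PhaseFrame(ramp + blob, pixel_size=1.0)
        params = SegmentationParams(rolling_ball_radius=30, smooth_sigma=0.8)
        out = preprocess_frame(frame, params)
        # background far from the blob is flattened to ~0
        assert abs(out.pixels[5, 5]) < 0.05
        assert abs(out.pixels[90, 90]) < 0.05
        peak = np.unravel_index(np.argmax(out.pixels), out.pixels.shape)
        assert abs(peak[0] - 48) <= 1 and abs(peak[1] - 40) <= 1

    def test_matches_brute_force_ball_background(self):
        rng = np.random.default_rng(4)
        base = rng.normal(0, 0.05, (40, 40))
        img = base + render_ellipse((40, 40), center=(20, 20), a=6, b=4, peak=1.0)
        from skimage.restoration import ellipsoid_kernel, rolling_ball

        radius, height = 8, 1.0
        # the module's kernel convention: dome height = `height` in phase units
        kernel = ellipsoid_kernel((2 * radius + 1,) * 2, height)
        bg = rolling_ball(img, kernel=kernel)
        oracle = brute_force_ball_background(img, radius, height)
        assert np.max(np.abs(bg - oracle)) < 1e-6

    def test_smoothing_conserves_mass(self):
        img = np.zeros((64, 64))
        img[32, 32] = 1.0
        frame = PhaseFrame(img, pixel_size=1.0)
        params = SegmentationParams(rolling_ball_radius=30, smooth_sigma=2.0)
        out = preprocess_frame(frame, params, subtract_background=False)
        assert out.pixels.sum() == pytest.approx(img.sum(), rel=1e-6)

    def test_non_finite_pixels_rejected(self):
        img = np.zeros((16, 16))
        img[3, 3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            preprocess_frame(PhaseFrame(img, pixel_size=1.0),
                             SegmentationParams(rolling_ball_radius=5))


class TestSeeds:
    def test_blank_frame_no_seeds(self, small_params):
        frame = PhaseFrame(np.zeros((64, 64)), pixel_size=1.0)
        assert len(detect_seeds(frame, small_params)) == 0

    @pytest.mark.parametrize("separation,expected", [(50, 2), (5, 1)])
    def test_min_distance_rule(self, separation, expected):
        img = np.zeros((96, 96))
        img += render_ellipse((96, 96), center=(48, 20), a=4, b=4, peak=1.0)
        img += render_ellipse((96, 96), center=(48, 20 + separation), a=4, b=4,
                              peak=0.9)
        frame = PhaseFrame(img, pixel_size=1.0)
        params = SegmentationParams(min_seed_distance=20, threshold=0.3)
        seeds = detect_seeds(frame, params)
        assert len(seeds) == expected
        if expected == 2:
            rows = sorted(tuple(s) for s in seeds)
            assert abs(rows[0][1] - 20) <= 1 and abs(rows[1][1] - 70) <= 1

    def test_consolidation_merges_plateau_splits_cells(self):
        # one flat-topped cell with two spurious seeds -> 1; two distinct
        # cells separated by background -> stay 2
        img = render_ellipse((64, 128), center=(32, 30), a=20, b=8, peak=1.0,
                             power=6)
        img += render_ellipse((64, 128), center=(32, 95), a=8, b=8, peak=1.0)
        frame = PhaseFrame(img, pixel_size=1.0)
        params = SegmentationParams(threshold=0.3, consolidation_delta=0.1)
        seeds = np.array([[32, 24], [32, 36], [32, 95]])
        # oracle: min intensity along dense straight-line samples
        def line_min(p, q):
            ts = np.linspace(0, 1, 200)
            vals = [img[int(round(p[0] + t * (q[0] - p[0]))),
                        int(round(p[1] + t * (q[1] - p[1])))] for t in ts]
            return min(vals)

        assert min(img[32, 24], img[32, 36]) - line_min((32, 24), (32, 36)) < 0.1
        assert min(img[32, 36], img[32, 95]) - line_min((32, 36), (32, 95)) > 0.1
        out = consolidate_seeds(seeds, frame, params)
        assert len(out) == 2
        assert {tuple(s)[1] for s in out} <= {24, 36, 95}
        assert 95 in {s[1] for s in out}

    def test_single_seed_unchanged(self, small_params):
        frame = PhaseFrame(np.ones((32, 32)), pixel_size=1.0)
        seeds = np.array([[10, 10]])
        assert np.array_equal(consolidate_seeds(seeds, frame, small_params), seeds)


class TestSegmentation:
    def test_no_seeds_all_background(self, ellipse_frame, small_params):
        labels = segment_cells(ellipse_frame, np.empty((0, 2), int), small_params)
        assert labels.max() == 0

    def test_half_max_threshold_recovers_ellipse_area(self, ellipse_frame):
        params = SegmentationParams(threshold=0.5)
        labels = segment_cells(ellipse_frame, np.array([[63, 63]]), params)
        area = (labels == 1).sum()
        assert area == pytest.approx(math.pi * 30 * 10, rel=0.05)

    def test_touching_blobs_split_into_two(self):
        img = render_ellipse((64, 64), center=(32, 22), a=10, b=10, peak=1.0)
        img += render_ellipse((64, 64), center=(32, 42), a=10, b=10, peak=1.0)
        frame = PhaseFrame(img, pixel_size=1.0)
        params = SegmentationParams(threshold=0.3)
        labels = segment_cells(frame, np.array([[32, 22], [32, 42]]), params)
        areas = [(labels == k).sum() for k in (1, 2)]
        single = render_ellipse((64, 64), center=(32, 32), a=10, b=10, peak=1.0)
        ref = (single > 0.3).sum()
        assert len(areas) == 2
        for a in areas:
            assert a == pytest.approx(ref, rel=0.10)

    def test_watershed_matches_brute_force_flood(self):
        rng = np.random.default_rng(0)
        img = np.zeros((64, 64))
        img += render_ellipse((64, 64), center=(20, 20), a=9, b=6, peak=1.0)
        img += render_ellipse((64, 64), center=(40, 40), a=8, b=8, peak=0.8)
        img += rng.normal(0, 0.01, img.shape)
        frame = PhaseFrame(img, pixel_size=1.0)
        params = SegmentationParams(threshold=0.2)
        seeds = np.array([[20, 20], [40, 40]])
        labels = segment_cells(frame, seeds, params)
        oracle = brute_force_flood(img, seeds, img > 0.2)
        fg = oracle > 0
        agree = (labels[fg] == oracle[fg]).mean()
        assert agree > 0.98

    def test_label_count_equals_surviving_seeds(self, ellipse_frame):
        params = SegmentationParams(threshold=0.5)
        # second seed sits below threshold -> no region
        seeds = np.array([[63, 63], [5, 5]])
        labels = segment_cells(ellipse_frame, seeds, params)
        assert set(np.unique(labels)) == {0, 1}


class TestMeasurement:
    def test_disc_aspect_ratio_unity(self):
        img = render_ellipse((96, 96), a=20, b=20, peak=1.0)
        frame = PhaseFrame(img, pixel_size=1.0)
        labels = (img > 0.5).astype(np.int32)
        cells = measure_cells(labels, frame, SegmentationParams())
        assert cells[0].aspect_ratio == pytest.approx(1.0, abs=0.02)

    def test_ellipse_aspect_and_area(self):
        img = render_ellipse((128, 128), a=30, b=10, peak=1.0, theta=0.4)
        frame = PhaseFrame(img, pixel_size=1.0)
        labels = (img > 0.5).astype(np.int32)
        cells = measure_cells(labels, frame, SegmentationParams())
        assert cells[0].aspect_ratio == pytest.approx(3.0, rel=0.02)
        assert cells[0].area == pytest.approx(math.pi * 30 * 10, rel=0.02)

    def test_dry_mass_closed_form(self):
        # phi = 1 rad over 1000 um^2, lambda 0.6 um, alpha 0.2 um^3/pg
        img = np.zeros((64, 64))
        img[10:50, 10:35] = 1.0  # 40 x 25 px = 1000 px^2 at 1 um/px
        frame = PhaseFrame(img, pixel_size=1.0, wavelength=0.6)
        labels = (img > 0).astype(np.int32)
        cells = measure_cells(labels, frame, SegmentationParams(dry_mass_alpha=0.2))
        expect = 0.6 * 1000 / (2 * math.pi * 0.2)
        assert cells[0].dry_mass == pytest.approx(expect, rel=1e-9)
        assert expect == pytest.approx(477.5, abs=0.1)

    def test_dry_mass_linear_in_phase(self):
        img = render_ellipse((64, 64), a=10, b=6, peak=0.9)
        labels = (img > 0.3).astype(np.int32)
        params = SegmentationParams()
        m1 = measure_cells(labels, PhaseFrame(img, 1.0), params)[0].dry_mass
        m3 = measure_cells(labels, PhaseFrame(3 * img, 1.0), params)[0].dry_mass
        assert m3 == pytest.approx(3 * m1, rel=1e-12)

    def test_scale_equivariance_physical_units(self):
        cells = {}
        for p in (1.0, 0.5):
            img = render_ellipse((int(128 / p),) * 2, a=30, b=10, peak=1.0,
                                 pixel_size=p)
            frame = PhaseFrame(img, pixel_size=p)
            labels = (img > 0.5).astype(np.int32)
            cells[p] = measure_cells(labels, frame, SegmentationParams())[0]
        for attr in ("area", "length", "width", "aspect_ratio"):
            v1, v2 = getattr(cells[1.0], attr), getattr(cells[0.5], attr)
            assert v2 == pytest.approx(v1, rel=0.03)

    def test_tiny_labels_skipped(self):
        img = np.ones((16, 16))
        labels = np.zeros((16, 16), dtype=np.int32)
        labels[0, 0] = 1  # 1 px
        labels[5:9, 5:9] = 2
        cells = measure_cells(labels, PhaseFrame(img, 1.0), SegmentationParams())
        assert [c.label for c in cells] == [2]

    def test_invalid_cellobject_rejected(self):
        with pytest.raises(ValueError):
            CellObject(0, 1, (0, 0), area=-5, length=2, width=1,
                       aspect_ratio=2, dry_mass=1, mean_phase=0.1)


class TestPopulationRecovery:
    def test_two_population_means_recovered_from_rendered_frames(self):
        # small-n version of the full recovery experiment: one field per
        # population, measured means within 5% of the generator values
        measured = {}
        for label, ar, sd, area in [("Y201", 3.59, 0.072, 1400.0),
                                    ("Y202", 2.016, 0.051, 1800.0)]:
            spec = TimelapseSpec(
                populations=[PopulationSpec(n_cells=15, mean_aspect_ratio=ar,
                                            sd_aspect_ratio=sd, mean_area=area,
                                            label=label)],
                duration=0.0, field_size=(512, 512), seed=42,
            )
            stack, _ = generate_timelapse(spec)
            cells = segment_frame(stack[0], SegmentationParams())
            assert len(cells) >= 13  # adjacent cells may occasionally merge
            measured[label] = np.mean([c.aspect_ratio for c in cells])
        assert measured["Y201"] == pytest.approx(3.59, rel=0.05)
        assert measured["Y202"] == pytest.approx(2.016, rel=0.05)
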