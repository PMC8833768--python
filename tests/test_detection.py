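"""Segmentation and feature extraction against synthetic ground truth."""

import numpy as np
import pytest

from raresight import (
    ChannelStack,
    DetectionParams,
    FrameSpec,
    extract_features,
    generate_frame,
    match_events,
    segment_cell_bodies,
    segment_nuclei,
)
from raresight.detection import EMPTY_MASK, Mask, detect_events
from raresight.simulate import WBC

ROLE_MAP = {"DAPI": 0, "Vim": 1, "CK": 2, "CD45/CD31": 3}


def noise_stack(shape=(128, 128), seed=0, background=100.0, sigma=5.0):
    rng = np.random.default_rng(seed)
    images = rng.normal(background, sigma, size=(4, *shape))
    return ChannelStack("test", images, dict(ROLE_MAP))


def add_disk(stack, role, center, radius, amplitude):
    rr, cc = np.mgrid[: stack.shape[0], : stack.shape[1]]
    d = np.hypot(rr - center[0], cc - center[1])
    stack.images[ROLE_MAP[role]] += amplitude / (1 + np.exp((d - radius) / 0.8))


class TestSegmentNuclei:
    def test_empty_frame_gives_no_nuclei(self):
        assert segment_nuclei(noise_stack()) == []

    def test_recovers_well_separated_nuclei(self):
        """20 planted nuclei are each found with centroid within 2 px."""
        spec = FrameSpec(shape=(512, 512), counts={WBC: 20})
        stack, truth = generate_frame(spec, seed=11)
        masks = segment_nuclei(stack)
        assert len(masks) == 20
        centroids = []
        for m in masks:
            px = m.pixels()
            centroids.append(px.mean(axis=0))
        _, recall, _ = match_events(truth, centroids, max_dist=2.0)
        assert recall == 1.0

    def test_watershed_splits_touching_pair(self):
        """Two nuclei planted 1.5 radii apart resolve into 2 masks."""
        stack = noise_stack(shape=(96, 96), seed=1)
        r = 6.0
        add_disk(stack, "DAPI", (48, 43), r, 150)
        add_disk(stack, "DAPI", (48, 43 + 1.5 * r), r, 150)
        masks = segment_nuclei(stack)
        assert len(masks) == 2

    def test_otsu_threshold_option(self):
        stack = noise_stack(seed=2)
        add_disk(stack, "DAPI", (64, 64), 5, 150)
        masks = segment_nuclei(stack, DetectionParams(nucleus_threshold="otsu"))
        assert len(masks) == 1


class TestSegmentCellBodies:
    def test_fallback_dilation_for_dapi_only_cell(self):
        """With no cytoplasmic signal the cell mask is the nucleus
        dilated by the fallback radius."""
        params = DetectionParams()
        stack = noise_stack(seed=3)
        add_disk(stack, "DAPI", (64, 64), 5, 150)
        nuclei = segment_nuclei(stack, params)
        cells = segment_cell_bodies(nuclei, stack, params)
        assert len(cells) == 1
        assert cells[0].contains(nuclei[0])
        # dilation by r grows a disk's radius by about r
        grown = np.sqrt(cells[0].area / np.pi) - np.sqrt(nuclei[0].area / np.pi)
        assert grown == pytest.approx(params.fallback_dilation_radius, abs=1.0)

    def test_cytoplasm_area_recovered(self):
        """A mesenchymal CTC with cytoplasm radius r yields a cell area
        within 20% of pi r^2."""
        spec = FrameSpec(shape=(256, 256), counts={"mes.CTC": 1})
        stack, truth = generate_frame(spec, seed=12)
        nuclei = segment_nuclei(stack)
        cells = segment_cell_bodies(nuclei, stack)
        assert len(cells) == 1
        r = truth.iloc[0]["cell_radius"]
        assert cells[0].area == pytest.approx(np.pi * r**2, rel=0.2)

    def test_edge_nucleus_clipped_without_error(self):
        stack = noise_stack(seed=4)
        add_disk(stack, "DAPI", (2, 64), 5, 150)
        add_disk(stack, "CK", (2, 64), 8, 150)
        nuclei = segment_nuclei(stack)
        assert len(nuclei) == 1
        cells = segment_cell_bodies(nuclei, stack)
        px = cells[0].pixels()
        assert px[:, 0].min() >= 0
        assert cells[0].contains(nuclei[0])

    def test_no_pixel_in_two_cells(self):
        spec = FrameSpec(shape=(512, 512), counts={WBC: 60, "epi.CTC": 2})
        stack, _ = generate_frame(spec, seed=13)
        nuclei = segment_nuclei(stack)
        cells = segment_cell_bodies(nuclei, stack)
        union = np.zeros(stack.shape, dtype=int)
        for c in cells:
            union += c.to_full(stack.shape)
        assert union.max() == 1


class TestExtractFeatures:
    def test_disk_eccentricity_near_zero(self):
        rr, cc = np.mgrid[:41, :41]
        disk = np.hypot(rr - 20, cc - 20) <= 15
        mask = Mask((0, 0), disk)
        stack = noise_stack(shape=(41, 41))
        rec = extract_features(mask, EMPTY_MASK, stack)
        assert rec.cell_eccentricity < 0.05

    def test_ellipse_eccentricity_matches_closed_form(self):
        """A 2:1 ellipse has eccentricity sqrt(1 - 1/4) ~ 0.866."""
        rr, cc = np.mgrid[:81, :81]
        ell = ((rr - 40) / 15.0) ** 2 + ((cc - 40) / 30.0) ** 2 <= 1
        stack = noise_stack(shape=(81, 81))
        rec = extract_features(Mask((0, 0), ell), EMPTY_MASK, stack)
        assert rec.cell_eccentricity == pytest.approx(np.sqrt(1 - 0.25), abs=0.02)

    def test_uniform_image_gives_uniform_medians(self):
        images = np.full((4, 32, 32), 7.5)
        stack = ChannelStack("u", images, dict(ROLE_MAP))
        mask = Mask((10, 10), np.ones((5, 5), dtype=bool))
        background = {r: (0.0, 1.0) for r in ROLE_MAP}
        rec = extract_features(mask, EMPTY_MASK, stack, background)
        for role in ROLE_MAP:
            assert rec.median_intensity[role] == pytest.approx(7.5)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty cell mask"):
            extract_features(EMPTY_MASK, EMPTY_MASK, noise_stack())

    def test_order_invariant(self):
        """Features depend only on the event's own masks, not on the
        order events are processed in."""
        spec = FrameSpec(shape=(256, 256), counts={WBC: 8})
        stack, _ = generate_frame(spec, seed=14)
        nuclei = segment_nuclei(stack)
        cells = segment_cell_bodies(nuclei, stack)
        fwd = [extract_features(c, n, stack) for c, n in zip(cells, nuclei)]
        rev = [
            extract_features(c, n, stack)
            for c, n in zip(reversed(cells), reversed(nuclei))
        ]
        for a, b in zip(fwd, reversed(rev)):
            assert a.median_intensity == b.median_intensity
            assert a.cell_area == b.cell_area


class TestLevCandidates:
    def test_candidate_count_and_attachment(self):
        """All planted LEVs surface as candidates; the attached flag
        matches the planted attachment ground truth."""
        spec = FrameSpec(
            shape=(512, 512),
            counts={WBC: 30, "LEV CK only": 3, "LEV CK|Vim": 2},
            lev_attached_fraction=0.5,
        )
        stack, truth = generate_frame(spec, seed=15)
        cells, levs = detect_events(stack)
        t_levs = truth[truth["kind"].str.startswith("LEV")]
        _, recall, precision = match_events(
            t_levs, [r.centroid for r in levs], max_dist=3.0
        )
        assert recall == 1.0 and precision == 1.0
        n_attached_truth = int(t_levs["attached_to"].notna().sum())
        assert sum(r.attached_flag for r in levs) == n_attached_truth

    def test_cells_only_frame_has_no_candidates(self):
        spec = FrameSpec(shape=(256, 256), counts={WBC: 15})
        stack, _ = generate_frame(spec, seed=16)
        _, levs = detect_events(stack)
        assert levs == []

    def test_attached_lev_not_merged_into_cell(self):
        """A cell-attached LEV stays a separate anucleate event and the
        host cell keeps its own mask."""
        spec = FrameSpec(
            shape=(256, 256),
            counts={WBC: 3, "LEV CK only": 1},
            lev_attached_fraction=1.0,
        )
        stack, truth = generate_frame(spec, seed=17)
        cells, levs = detect_events(stack)
        assert len(cells) == 3
        assert len(levs) == 1
        assert levs[0].attached_flag
        assert levs[0].nucleus_mask.is_empty
        # LEV mask never contains nucleus pixels
        lev_full = levs[0].cell_mask.to_full(stack.shape)
        for c in cells:
            assert not (lev_full & c.nucleus_mask.to_full(stack.shape)).any()
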