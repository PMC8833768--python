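"""End-to-end slide processing: frames in, per-test profile out."""

from __future__ import annotations

from .categories import COMMON_CELL, RARE_CATEGORIES
from .classification import ClassificationParams, classify_events
from .detection import ChannelStack, DetectionParams, EventRecord, detect_events, estimate_background
from .enumeration import SampleProfile, events_per_ml, ml_analyzed

__all__ = ["process_frame", "process_slide", "slide_profile"]


def process_frame(
    stack: ChannelStack,
    det_params: DetectionParams | None = None,
    cls_params: ClassificationParams | None = None,
) -> tuple[list[EventRecord], list[EventRecord]]:
    """Detect and classify one frame; returns (cells, retained LEVs).

    Note the rarity screen is calibrated per frame here; use
    :func:`process_slide` to pool a slide's frames before screening,
    which is the intended granularity.
    """
    cells, levs = detect_events(stack, det_params)
    background = estimate_background(stack, [c.cell_mask for c in cells])
    return classify_events(cells, levs, background, cls_params)


def process_slide(
    stacks: list[ChannelStack],
    det_params: DetectionParams | None = None,
    cls_params: ClassificationParams | None = None,
) -> tuple[list[EventRecord], list[EventRecord]]:
    """Detect across all frames of a slide, then classify jointly.

    Pooling the frames gives the rarity screen its common-cell
    reference population and lets the junk-frame LEV rule see per-frame
    candidate counts.  Positivity thresholds use the first frame's
    background estimate (frames of a slide share acquisition settings).
    """
    all_cells: list[EventRecord] = []
    all_levs: list[EventRecord] = []
    background = None
    for stack in stacks:
        cells, levs = detect_events(stack, det_params)
        if background is None:
            background = estimate_background(stack, [c.cell_mask for c in cells])
        all_cells.extend(cells)
        all_levs.extend(levs)
    if background is None:
        return [], []
    return classify_events(all_cells, all_levs, background, cls_params)


def slide_profile(
    stacks: list[ChannelStack],
    sample_id: str,
    group: str,
    wbc_cbc: float,
    det_params: DetectionParams | None = None,
    cls_params: ClassificationParams | None = None,
) -> SampleProfile:
    """Process one slide into a per-slide events/mL profile.

    The blood volume analyzed is recovered from the detected
    common-cell (WBC) count and the patient's CBC WBC concentration.
    """
    cells, levs = process_slide(stacks, det_params, cls_params)
    wbcs_detected = sum(1 for c in cells if c.label == COMMON_CELL)
    ml = ml_analyzed(wbcs_detected, wbc_cbc)
    counts: dict[str, float] = {c: 0.0 for c in RARE_CATEGORIES}
    for rec in cells:
        if rec.is_rare and rec.label in counts:
            counts[rec.label] += 1
    for rec in levs:
        if rec.label in counts:
            counts[rec.label] += 1
    rates = events_per_ml(counts, ml)
    return SampleProfile(
        sample_id=sample_id,
        group=group,
        wbc_cbc=wbc_cbc,
        wbcs_detected_per_slide=[float(wbcs_detected)],
        ml_analyzed_per_slide=[ml],
        events_per_ml=rates,
        slides=1,
        lev_free_count=float(sum(1 for r in levs if not r.attached_flag)),
        lev_attached_count=float(sum(1 for r in levs if r.attached_flag)),
    )
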