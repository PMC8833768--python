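"""Shared fixtures: a multi-frame synthetic slide run with ground truth,
and builders for synthetic event records used by classification tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from raresight import ClassificationParams, FrameSpec, generate_frame
from raresight.detection import EMPTY_MASK, EventRecord, Mask
from raresight.pipeline import process_slide
from raresight.simulate import BUBBLE, HALO, WBC


def make_record(
    event_id: int = 0,
    frame_id: str = "f0",
    dapi: float = 40.0,
    ck: float = 0.0,
    vim: float = 0.0,
    cd: float = 36.0,
    cell_area: float = 150.0,
    nucleus_area: float = 50.0,
    cell_ecc: float = 0.15,
    nucleus_ecc: float = 0.15,
    nucleated: bool = True,
    solidity: float = 0.95,
    annularity: float = 0.0,
    attached: bool = False,
    positivity: dict | None = None,
) -> EventRecord:
    """A synthetic event record bypassing image segmentation."""
    nucleus = (
        Mask((0, 0), np.ones((1, 1), dtype=bool)) if nucleated else EMPTY_MASK
    )
    rec = EventRecord(
        event_id=event_id,
        frame_id=frame_id,
        centroid=(0.0, 0.0),
        cell_mask=Mask((0, 0), np.ones((1, 1), dtype=bool)),
        nucleus_mask=nucleus,
        cell_area=int(cell_area),
        nucleus_area=int(nucleus_area) if nucleated else 0,
        cell_eccentricity=cell_ecc,
        nucleus_eccentricity=nucleus_ecc if nucleated else float("nan"),
        median_intensity={"DAPI": dapi, "CK": ck, "Vim": vim, "CD45/CD31": cd},
        is_dapi_positive=nucleated,
        attached_flag=attached,
        solidity=solidity,
        annularity=annularity,
    )
    if positivity is not None:
        rec.positivity = dict(positivity)
    return rec


def wbc_record(rng: np.random.Generator, event_id: int = 0) -> EventRecord:
    """One ordinary leukocyte: CD45/CD31-only pattern, typical morphology."""
    size = np.exp(rng.normal(0.0, 0.16))
    rec = make_record(
        event_id=event_id,
        dapi=float(np.exp(rng.normal(np.log(40), 0.15))),
        ck=float(rng.normal(0.0, 0.5)),
        vim=float(rng.normal(0.0, 0.5)),
        cd=float(np.exp(rng.normal(np.log(36), 0.15))),
        cell_area=150 * size,
        nucleus_area=50 * size,
        cell_ecc=float(abs(rng.normal(0.15, 0.05))),
        nucleus_ecc=float(abs(rng.normal(0.15, 0.05))),
        positivity={"DAPI": True, "CK": False, "Vim": False, "CD45/CD31": True},
    )
    return rec


# Per-frame object counts for the synthetic slide.  Frames carry a
# leukocyte background, a rotating cast of rare kinds, at most three
# LEVs, and one ring artifact; the last frame is a junk frame holding
# six CK-positive candidates.
_RARE_ROTATION = [
    {"epi.CTC": 1, "Vim only": 1},
    {"mes.CTC": 1, "DAPI only": 1},
    {"CK|Vim|CD45/CD31": 1, "CD45/CD31 only": 1},
    {"Vim|CD45/CD31": 1, "CK|CD45/CD31": 1},
]
_LEV_ROTATION = [
    {"LEV CK only": 2},
    {"LEV CK only": 1, "LEV CK|Vim": 1},
    {"LEV CK|CD45/CD31": 1, "LEV CK only": 1},
    {"LEV CK|Vim|CD45/CD31": 1, "LEV CK only": 2},
]

N_FRAMES = 20
JUNK_FRAME = f"frame_{N_FRAMES - 1:02d}"


def _slide_specs() -> list[FrameSpec]:
    specs = []
    for i in range(N_FRAMES - 1):
        counts = {WBC: 110, HALO if i % 2 == 0 else BUBBLE: 1}
        counts.update(_RARE_ROTATION[i % 4])
        counts.update(_LEV_ROTATION[i % 4])
        specs.append(FrameSpec(shape=(512, 512), counts=counts))
    specs.append(
        FrameSpec(shape=(512, 512), counts={WBC: 110, "LEV CK only": 6})
    )
    return specs


@pytest.fixture(scope="session")
def slide_run():
    """One processed 20-frame synthetic slide with pooled ground truth."""
    stacks, truths = [], []
    for i, spec in enumerate(_slide_specs()):
        frame_id = f"frame_{i:02d}"
        stack, truth = generate_frame(spec, seed=9000 + i, frame_id=frame_id)
        truth["frame_id"] = frame_id
        stacks.append(stack)
        truths.append(truth)
    cells, levs = process_slide(stacks, cls_params=ClassificationParams())
    truth = pd.concat(truths, ignore_index=True)
    return {
        "stacks": stacks,
        "truth": truth,
        "cells": cells,
        "levs": levs,
        "junk_frame": JUNK_FRAME,
    }
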