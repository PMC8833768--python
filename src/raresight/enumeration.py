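"""Events-per-mL enumeration.

The assay plates a slide's worth of nucleated blood cells without
enrichment, so the blood volume actually analyzed varies per slide.  It
is recovered from the slide's detected white-blood-cell count and the
patient's complete-blood-count WBC concentration:

    mL analyzed = WBCs detected on slide / (WBC concentration x 10^6)

with the WBC concentration in million cells per mL.  Category counts
divided by that volume give events/mL; a test's value is the average of
its slides' events/mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .categories import (
    CELL_CATEGORIES,
    CK_POSITIVE_CELL_CATEGORIES,
    LEV_CATEGORIES,
    RARE_CATEGORIES,
    TOTAL_CELLS,
    TOTAL_CK_CELLS,
    TOTAL_EVENTS,
    TOTAL_LEVS,
)

__all__ = [
    "SampleProfile",
    "CohortDataset",
    "ml_analyzed",
    "events_per_ml",
    "aggregate_test",
    "add_totals",
    "attachment_fractions",
    "positive_sample_percent",
    "misclassified_from_accuracy",
]


def ml_analyzed(wbcs_detected: float, wbc_cbc: float) -> float:
    """Blood volume analyzed on one slide, in mL.

    ``wbc_cbc`` is the complete-blood-count WBC concentration in
    million cells per mL of whole blood.
    """
    if wbc_cbc <= 0:
        raise ValueError("WBC concentration must be positive")
    if wbcs_detected < 0:
        raise ValueError("WBC count cannot be negative")
    return wbcs_detected / (wbc_cbc * 1e6)


def add_totals(rates: dict[str, float]) -> dict[str, float]:
    """Attach the four derived totals to a per-category rate mapping."""
    out = dict(rates)
    out[TOTAL_CELLS] = sum(rates.get(c, 0.0) for c in CELL_CATEGORIES)
    out[TOTAL_LEVS] = sum(rates.get(c, 0.0) for c in LEV_CATEGORIES)
    out[TOTAL_EVENTS] = out[TOTAL_CELLS] + out[TOTAL_LEVS]
    out[TOTAL_CK_CELLS] = sum(
        rates.get(c, 0.0) for c in CK_POSITIVE_CELL_CATEGORIES
    )
    return out


def events_per_ml(counts: dict[str, float], ml: float) -> dict[str, float]:
    """Convert per-slide category counts into events/mL with totals."""
    if ml <= 0:
        raise ValueError("analyzed volume must be positive")
    unknown = set(counts) - set(RARE_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    rates = {c: counts.get(c, 0.0) / ml for c in RARE_CATEGORIES}
    return add_totals(rates)


@dataclass
class SampleProfile:
    """Per-test rare-event profile for one individual."""

    sample_id: str
    group: str  # "BCa" or "ND"
    wbc_cbc: float  # million WBC per mL whole blood
    wbcs_detected_per_slide: list[float]
    ml_analyzed_per_slide: list[float]
    events_per_ml: dict[str, float]
    slides: int = 0
    lev_free_count: float = 0.0
    lev_attached_count: float = 0.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.slides == 0:
            self.slides = len(self.ml_analyzed_per_slide)


@dataclass
class CohortDataset:
    """Stacked per-test profiles with group labels (BCa vs ND)."""

    profiles: list[SampleProfile]

    def to_frame(self):
        """One row per individual: metadata plus events/mL columns."""
        import pandas as pd

        rows = []
        for p in self.profiles:
            row = {
                "sample_id": p.sample_id,
                "group": p.group,
                "wbc_cbc": p.wbc_cbc,
                "ml_analyzed": float(np.sum(p.ml_analyzed_per_slide)),
                "lev_free_count": p.lev_free_count,
                "lev_attached_count": p.lev_attached_count,
            }
            row.update(p.events_per_ml)
            rows.append(row)
        return pd.DataFrame(rows)

    def group_frames(self):
        """(BCa frame, ND frame) split of :meth:`to_frame`."""
        df = self.to_frame()
        return df[df["group"] == "BCa"], df[df["group"] == "ND"]


def aggregate_test(slide_profiles: list[SampleProfile]) -> SampleProfile:
    """Average per-slide events/mL into one per-test profile.

    All slides must come from the same sample; derived totals are
    recomputed from the averaged category rates.
    """
    if not slide_profiles:
        raise ValueError("need at least one slide profile")
    ids = {p.sample_id for p in slide_profiles}
    if len(ids) != 1:
        raise ValueError(f"inconsistent sample ids across slides: {sorted(ids)}")
    first = slide_profiles[0]
    rates = {
        c: float(np.mean([p.events_per_ml.get(c, 0.0) for p in slide_profiles]))
        for c in RARE_CATEGORIES
    }
    return SampleProfile(
        sample_id=first.sample_id,
        group=first.group,
        wbc_cbc=first.wbc_cbc,
        wbcs_detected_per_slide=[
            w for p in slide_profiles for w in p.wbcs_detected_per_slide
        ],
        ml_analyzed_per_slide=[
            v for p in slide_profiles for v in p.ml_analyzed_per_slide
        ],
        events_per_ml=add_totals(rates),
        slides=sum(p.slides for p in slide_profiles),
        lev_free_count=sum(p.lev_free_count for p in slide_profiles),
        lev_attached_count=sum(p.lev_attached_count for p in slide_profiles),
    )


def attachment_fractions(free_count: float, attached_count: float) -> tuple[float, float]:
    """Percent of LEVs detected free-floating vs in close proximity to
    cells, from raw counts.  Returns (free %, attached %)."""
    total = free_count + attached_count
    if total <= 0:
        raise ValueError("no LEVs counted")
    return 100.0 * free_count / total, 100.0 * attached_count / total


def positive_sample_percent(n_positive: int, n_samples: int) -> float:
    """Percent of samples calling positive under some threshold."""
    if n_samples <= 0:
        raise ValueError("need at least one sample")
    return 100.0 * n_positive / n_samples


def misclassified_from_accuracy(accuracy_percent: float, n: int) -> int:
    """Misclassified individuals implied by a cohort accuracy."""
    return int(round(n * (1.0 - accuracy_percent / 100.0)))
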