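"""Channel-type classification of detected events.

Each event's four marker positivities (DAPI, CK, Vim, CD45/CD31) are
called against background-referenced thresholds and mapped through a
deterministic 16-row lookup onto the 12 rare categories, ``common
cell`` or ``excluded``.  Because ordinary leukocytes share the
CD45/CD31-only pattern, events with that pattern are only kept as rare
when their morphometric feature vector is a robust-distance outlier
against the slide's common-cell population (a rarity screen standing in
for the assay's interactive outlier report).  LEV candidates then pass
morphology filters that reject ring-shaped optical artifacts (halos,
bubbles) and drop every candidate from frames holding more than a
configured maximum, which flags CK-positive junk contamination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2
from sklearn.covariance import MinCovDet

from .categories import (
    CD_ONLY,
    COMMON_CELL,
    EXCLUDED,
    LEV_CATEGORIES,
    PATTERN_TO_LABEL,
    ROLES,
)
from .detection import EventRecord

__all__ = [
    "ClassificationParams",
    "call_positivity",
    "classify_event",
    "rarity_screen",
    "apply_lev_filters",
    "classify_events",
    "MORPHO_FEATURES",
]

# The eight morphometric measures used by the rarity screen and the
# downstream morphometric clustering: four median channel intensities
# plus area and eccentricity of the cell and of the nucleus.
MORPHO_FEATURES = (
    "median_DAPI",
    "median_CK",
    "median_Vim",
    "median_CD45/CD31",
    "cell_area",
    "nucleus_area",
    "cell_eccentricity",
    "nucleus_eccentricity",
)


@dataclass
class ClassificationParams:
    """Thresholds for positivity calling, rarity screening and LEV filters."""

    k_sigma: float = 5.0  # positivity at background + k * robust sigma
    min_population: int = 100  # events needed for the rarity screen
    outlier_quantile: float = 0.999  # chi-square reference quantile
    arcsinh_cofactor: float = 5.0  # intensity variance stabilisation
    max_levs_per_frame: int = 3
    min_solidity: float = 0.8
    max_annularity: float = 0.3
    junk_frame_mode: str = "drop_all"  # or "keep_top"


def call_positivity(
    event: EventRecord, thresholds: dict[str, float]
) -> tuple[bool, bool, bool, bool]:
    """Call per-role positivity for one event.

    ``thresholds`` hold, per role, the minimum background-subtracted
    median intensity counted as positive (typically ``k * robust
    sigma``).  DAPI positivity additionally requires a nonempty nucleus
    mask: a bright but anucleate object is not a cell.
    """
    missing = [r for r in ROLES if r not in thresholds]
    if missing:
        raise ValueError(f"missing positivity thresholds for roles: {missing}")
    calls = []
    for role in ROLES:
        pos = event.median_intensity[role] > thresholds[role]
        if role == "DAPI":
            pos = pos and not event.nucleus_mask.is_empty
        calls.append(bool(pos))
    return tuple(calls)


def classify_event(positivity: tuple[bool, bool, bool, bool]) -> str:
    """Map a (DAPI, CK, Vim, CD45/CD31) positivity pattern to its label.

    Total and deterministic over all 16 combinations; DAPI-negative
    CK-negative patterns are ``excluded``.
    """
    return PATTERN_TO_LABEL[tuple(bool(b) for b in positivity)]


def _feature_matrix(events: list[EventRecord]) -> np.ndarray:
    rows = []
    for e in events:
        rows.append(
            [
                e.median_intensity["DAPI"],
                e.median_intensity["CK"],
                e.median_intensity["Vim"],
                e.median_intensity["CD45/CD31"],
                e.cell_area,
                e.nucleus_area,
                e.cell_eccentricity,
                e.nucleus_eccentricity,
            ]
        )
    return np.asarray(rows, dtype=float)


def rarity_screen(
    events: list[EventRecord],
    params: ClassificationParams | None = None,
) -> np.ndarray:
    """Screen a slide's nucleated events for rarity.

    Events whose marker pattern is CD45/CD31-only (the ordinary
    leukocyte/endothelial pattern) are labeled common unless their
    morphometric vector is a robust-distance outlier above the
    chi-square ``outlier_quantile`` against the slide population.
    Every other nucleated pattern is rare by markers alone.  With fewer
    than ``min_population`` events the screen cannot be calibrated: all
    non-leukocyte patterns are kept rare and a warning is raised.

    Intensities are arcsinh-transformed (the standard cytometry
    variance stabilisation: linear through zero for background noise,
    logarithmic for bright signal) and areas log-transformed, since
    fluorescence signal and cell size are right-skewed; the squared
    distance is a robust Mahalanobis distance
    (minimum-covariance-determinant location and scatter), so the
    chi-square reference accounts for the strong correlation between,
    e.g., cell and nucleus area.  Features with zero spread carry no
    outlier information and are dropped.

    Returns a boolean array, True where the event is rare.  Events must
    already carry their positivity calls.
    """
    params = params or ClassificationParams()
    n = len(events)
    patterns = np.array(
        [classify_event(tuple(e.positivity[r] for r in ROLES)) for e in events]
    )
    is_wbc_pattern = patterns == CD_ONLY
    if n < params.min_population:
        warnings.warn(
            f"only {n} events on slide (< {params.min_population}); "
            "rarity screen skipped, all non-leukocyte patterns kept rare",
            stacklevel=2,
        )
        return ~is_wbc_pattern

    x = _feature_matrix(events)
    x[:, :4] = np.arcsinh(x[:, :4] / params.arcsinh_cofactor)
    x[:, 4:6] = np.log1p(x[:, 4:6])  # areas
    spread = 1.4826 * np.median(
        np.abs(x - np.median(x, axis=0)), axis=0
    )
    informative = spread > 0
    if not informative.any():
        return ~is_wbc_pattern  # a constant population has no outliers
    x = x[:, informative]
    mcd = MinCovDet(random_state=0).fit(x)
    d2 = mcd.mahalanobis(x)
    cutoff = chi2.ppf(params.outlier_quantile, df=x.shape[1])
    return ~is_wbc_pattern | (d2 > cutoff)


def apply_lev_filters(
    lev_candidates: list[EventRecord],
    params: ClassificationParams | None = None,
) -> list[EventRecord]:
    """Apply artifact and junk-frame filters to LEV candidates.

    Candidates failing the shape checks are removed first: a high
    annularity (bright ring around a dark interior) marks halo/bubble
    artifacts, a low solidity marks non-membranous debris.  Any frame
    still holding more than ``max_levs_per_frame`` candidates is then
    treated as contaminated by CK-positive junk and contributes no LEVs
    at all (``junk_frame_mode="drop_all"``, the default); the
    alternative ``"keep_top"`` retains the brightest
    ``max_levs_per_frame`` candidates instead.
    """
    params = params or ClassificationParams()
    shaped = [
        c
        for c in lev_candidates
        if c.solidity >= params.min_solidity
        and c.annularity <= params.max_annularity
    ]
    by_frame: dict[str, list[EventRecord]] = {}
    for c in shaped:
        by_frame.setdefault(c.frame_id, []).append(c)
    retained: list[EventRecord] = []
    for frame_events in by_frame.values():
        if len(frame_events) <= params.max_levs_per_frame:
            retained.extend(frame_events)
        elif params.junk_frame_mode == "keep_top":
            frame_events.sort(
                key=lambda e: e.median_intensity["CK"], reverse=True
            )
            retained.extend(frame_events[: params.max_levs_per_frame])
        # drop_all: contaminated frame contributes nothing
    return retained


def classify_events(
    cell_records: list[EventRecord],
    lev_records: list[EventRecord],
    background: dict[str, tuple[float, float]],
    params: ClassificationParams | None = None,
) -> tuple[list[EventRecord], list[EventRecord]]:
    """Run the full classification stage on one slide's detections.

    Fills ``positivity``, ``label`` and ``is_rare`` on the cell records
    (applying the rarity screen) and returns the LEV records retained
    by the artifact and junk-frame filters, labeled by marker pattern.
    """
    params = params or ClassificationParams()
    thresholds = {role: params.k_sigma * background[role][1] for role in ROLES}

    for rec in cell_records:
        pos = call_positivity(rec, thresholds)
        rec.positivity = dict(zip(ROLES, pos))
        rec.label = classify_event(pos)
    if cell_records:
        rare = rarity_screen(cell_records, params)
        for rec, r in zip(cell_records, rare):
            rec.is_rare = bool(r)
            if rec.label == CD_ONLY and not r:
                rec.label = COMMON_CELL

    for rec in lev_records:
        pos = call_positivity(rec, thresholds)
        rec.positivity = dict(zip(ROLES, pos))
        rec.label = classify_event(pos)
        rec.is_rare = rec.label in LEV_CATEGORIES
    candidates = [r for r in lev_records if r.label != EXCLUDED]
    retained = apply_lev_filters(candidates, params)
    return cell_records, retained
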