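"""Synthetic slide frames and synthetic patient cohorts.

The real assay images every nucleated cell of a blood draw across
thousands of 4-channel fluorescence frames per slide.  This module
emulates that substrate with known ground truth at two levels:

* :func:`generate_frame` renders a single frame: planted white blood
  cells, the eight nucleated rare-cell channel types, the four LEV
  types (free-floating or attached to a cell), and ring-shaped optical
  artifacts (halos, bubbles), on top of i.i.d. Gaussian background
  noise.  Every planted object is returned in a ground-truth table.

* :func:`generate_cohort` draws per-patient events/mL profiles for a
  bladder-cancer (BCa) and a normal-donor (ND) group from zero-inflated
  log-normal distributions calibrated so each category's sample median
  converges to the cohort summaries the assay reports (e.g. BCa medians
  of 74.61 rare cells/mL and 30.91 LEVs/mL against ND medians of 34.46
  and 3.34).

Both generators are deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import norm

from .categories import (
    CD_ONLY,
    CELL_CATEGORIES,
    CK_CD,
    CK_VIM_CD,
    COMMON_CELL,
    DAPI_ONLY,
    EPI_CTC,
    LABEL_TO_PATTERN,
    LEV_CATEGORIES,
    LEV_CK,
    LEV_CK_CD,
    LEV_CK_VIM,
    LEV_CK_VIM_CD,
    MES_CTC,
    RARE_CATEGORIES,
    ROLES,
    VIM_CD,
    VIM_ONLY,
)
from .detection import ChannelStack
from .enumeration import CohortDataset, SampleProfile, add_totals, ml_analyzed

__all__ = [
    "PlantedObject",
    "FrameSpec",
    "PackingError",
    "generate_frame",
    "truth_table",
    "CategoryParams",
    "CohortSpec",
    "default_cohort_spec",
    "generate_cohort",
    "match_events",
    "WBC",
    "HALO",
    "BUBBLE",
]

# Planted kinds beyond the 12 rare categories.
WBC = "WBC"
HALO = "halo"
BUBBLE = "bubble"

ARTIFACT_KINDS = (HALO, BUBBLE)
PLANTABLE_KINDS = RARE_CATEGORIES + (WBC,) + ARTIFACT_KINDS

# Positivity pattern for the common leukocyte/endothelial population.
_WBC_PATTERN = (True, False, False, True)


class PackingError(ValueError):
    """Raised when the requested objects cannot be placed without
    overlaps beyond the packing limit."""


@dataclass
class PlantedObject:
    """Ground truth for one rendered object."""

    object_id: int
    kind: str
    center: tuple[float, float]  # (row, col)
    cell_radius: float
    nucleus_radius: float  # 0 for LEVs and artifacts
    channel_amplitudes: dict[str, float]
    attached_to: int | None = None  # LEVs only

    @property
    def expected_label(self) -> str | None:
        """Channel-type label the classifier should assign (None for
        artifacts, which must not survive filtering)."""
        if self.kind in RARE_CATEGORIES:
            return self.kind
        if self.kind == WBC:
            return COMMON_CELL
        return None


@dataclass
class FrameSpec:
    """Rendering parameters for one synthetic frame."""

    shape: tuple[int, int] = (1024, 1024)
    counts: dict[str, int] = field(default_factory=dict)
    background: float = 100.0
    noise_sigma: float = 5.0
    amplitude: float = 150.0  # peak signal over background, positive channels
    snr_multiple: float = 8.0  # required amplitude / noise_sigma minimum
    wbc_cell_radius: float = 6.0
    wbc_nucleus_radius: float = 4.0
    rare_cell_radius: float = 11.0
    rare_nucleus_radius: float = 7.0
    lev_radius: float = 3.0
    halo_radius: float = 10.0
    bubble_radius: float = 8.0
    ring_width: float = 1.0
    radius_jitter: float = 0.08  # log-normal sigma on object radii
    amplitude_jitter: float = 0.15  # log-normal sigma on peak amplitudes
    edge_softness: float = 0.5  # logistic edge width of disk profiles
    attach_gap: float = 2.0  # px between an attached LEV and its cell
    lev_attached_fraction: float = 0.55
    margin_factor: float = 4.0  # frame must be >= this x largest radius
    min_separation: float = 4.0  # extra px between unattached objects
    packing_limit: float = 0.25  # max fraction of frame area covered
    max_place_attempts: int = 200

    def __post_init__(self) -> None:
        bad = set(self.counts) - set(PLANTABLE_KINDS)
        if bad:
            raise ValueError(f"unknown planted kinds: {sorted(bad)}")
        if self.amplitude < self.snr_multiple * self.noise_sigma:
            raise ValueError(
                "signal amplitude below the required signal-to-background "
                f"multiple ({self.snr_multiple} x noise sigma)"
            )

    def radius_for(self, kind: str) -> tuple[float, float]:
        """(cell radius, nucleus radius) for a planted kind."""
        if kind == WBC:
            return self.wbc_cell_radius, self.wbc_nucleus_radius
        if kind in LEV_CATEGORIES:
            return self.lev_radius, 0.0
        if kind == HALO:
            return self.halo_radius, 0.0
        if kind == BUBBLE:
            return self.bubble_radius, 0.0
        return self.rare_cell_radius, self.rare_nucleus_radius


def _kind_amplitudes(kind: str, amplitude: float) -> dict[str, float]:
    """Per-role peak amplitude over background for a planted kind.

    Positive channels get ``amplitude``; negative channels get exactly
    0, so ground-truth marker patterns are unambiguous.  Artifacts are
    CK-channel-only optical features.
    """
    if kind == WBC:
        pattern = _WBC_PATTERN
    elif kind in ARTIFACT_KINDS:
        pattern = (False, True, False, False)
    else:
        pattern = LABEL_TO_PATTERN[kind]
    return {role: amplitude if p else 0.0 for role, p in zip(ROLES, pattern)}


def _disk_profile(r: np.ndarray, radius: float, softness: float) -> np.ndarray:
    # flat-top disk with a soft logistic edge: median over the mask is
    # ~the amplitude and the thresholded area is ~pi r^2
    return 1.0 / (1.0 + np.exp((r - radius) / softness))


def _ring_profile(r: np.ndarray, radius: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((r - radius) / width) ** 2)


def _render(
    images: np.ndarray,
    roles: dict[str, int],
    obj: PlantedObject,
    spec: FrameSpec,
) -> None:
    h, w = images.shape[1:]
    reach = int(math.ceil(max(obj.cell_radius, obj.nucleus_radius) + 6))
    r0 = max(0, int(obj.center[0]) - reach)
    r1 = min(h, int(obj.center[0]) + reach + 1)
    c0 = max(0, int(obj.center[1]) - reach)
    c1 = min(w, int(obj.center[1]) + reach + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dist = np.hypot(rr - obj.center[0], cc - obj.center[1])
    is_ring = obj.kind in ARTIFACT_KINDS
    for role, amp in obj.channel_amplitudes.items():
        if amp <= 0:
            continue
        if is_ring:
            prof = _ring_profile(dist, obj.cell_radius, spec.ring_width)
        elif role == "DAPI":
            prof = _disk_profile(dist, obj.nucleus_radius, spec.edge_softness)
        else:
            prof = _disk_profile(dist, obj.cell_radius, spec.edge_softness)
        images[roles[role], r0:r1, c0:c1] += amp * prof


def _place_objects(spec: FrameSpec, rng: np.random.Generator) -> list[PlantedObject]:
    h, w = spec.shape
    kinds: list[str] = []
    for kind in PLANTABLE_KINDS:  # canonical order keeps determinism
        kinds.extend([kind] * spec.counts.get(kind, 0))

    # packing-limit check on requested area
    area = sum(
        math.pi * spec.radius_for(k)[0] ** 2 for k in kinds
    )
    if area > spec.packing_limit * h * w:
        raise PackingError(
            f"requested objects cover {area / (h * w):.2f} of the frame, "
            f"over the packing limit {spec.packing_limit}"
        )
    largest = max((spec.radius_for(k)[0] for k in kinds), default=0.0)
    if largest and min(h, w) < spec.margin_factor * largest:
        raise ValueError("frame dimensions too small for the largest object")

    # cells and artifacts first, LEVs last so they can attach to cells
    cell_like = [k for k in kinds if k not in LEV_CATEGORIES]
    levs = [k for k in kinds if k in LEV_CATEGORIES]

    placed: list[PlantedObject] = []
    occupied: list[tuple[float, float, float]] = []  # (row, col, radius)

    def fits(r: float, c: float, radius: float, skip: int | None = None) -> bool:
        for i, (orow, ocol, orad) in enumerate(occupied):
            if i == skip:
                continue
            if math.hypot(r - orow, c - ocol) < radius + orad + spec.min_separation:
                return False
        return True

    def sample_center(radius: float) -> tuple[float, float]:
        pad = radius + 2
        for _ in range(spec.max_place_attempts):
            r = rng.uniform(pad, h - pad)
            c = rng.uniform(pad, w - pad)
            if fits(r, c, radius):
                return r, c
        raise PackingError(
            "could not place an object within the packing limit; "
            "reduce counts or enlarge the frame"
        )

    def jittered(kind: str) -> tuple[float, float, float]:
        """Per-object radius and amplitude with biological variability."""
        radius, nradius = spec.radius_for(kind)
        factor = math.exp(rng.normal(0.0, spec.radius_jitter))
        amp = spec.amplitude * math.exp(rng.normal(0.0, spec.amplitude_jitter))
        amp = max(amp, spec.snr_multiple * spec.noise_sigma)
        return radius * factor, nradius * factor, amp

    oid = 0
    for kind in cell_like:
        radius, nradius, amp = jittered(kind)
        r, c = sample_center(radius)
        placed.append(
            PlantedObject(
                object_id=oid,
                kind=kind,
                center=(r, c),
                cell_radius=radius,
                nucleus_radius=nradius,
                channel_amplitudes=_kind_amplitudes(kind, amp),
            )
        )
        occupied.append((r, c, radius))
        oid += 1

    host_cells = [p for p in placed if p.kind == WBC or p.kind in CELL_CATEGORIES]
    for kind in levs:
        radius, _, amp = jittered(kind)
        attach = bool(host_cells) and rng.random() < spec.lev_attached_fraction
        obj = None
        if attach:
            # sit just outside a host cell's boundary, within the
            # close-proximity band
            order = rng.permutation(len(host_cells))
            for idx in order:
                host = host_cells[idx]
                sep = host.cell_radius + radius + spec.attach_gap
                for _ in range(spec.max_place_attempts):
                    theta = rng.uniform(0, 2 * math.pi)
                    r = host.center[0] + sep * math.sin(theta)
                    c = host.center[1] + sep * math.cos(theta)
                    if not (radius + 2 <= r < h - radius - 2):
                        continue
                    if not (radius + 2 <= c < w - radius - 2):
                        continue
                    # clearance from everything except the host
                    host_idx = placed.index(host)
                    if fits(r, c, radius, skip=host_idx):
                        obj = PlantedObject(
                            object_id=oid,
                            kind=kind,
                            center=(r, c),
                            cell_radius=radius,
                            nucleus_radius=0.0,
                            channel_amplitudes=_kind_amplitudes(kind, amp),
                            attached_to=host.object_id,
                        )
                        break
                if obj is not None:
                    break
        if obj is None:  # free-floating (or attachment failed to fit)
            r, c = sample_center(radius)
            obj = PlantedObject(
                object_id=oid,
                kind=kind,
                center=(r, c),
                cell_radius=radius,
                nucleus_radius=0.0,
                channel_amplitudes=_kind_amplitudes(kind, amp),
            )
        placed.append(obj)
        occupied.append((obj.center[0], obj.center[1], radius))
        oid += 1
    return placed


def truth_table(objects: list[PlantedObject]) -> pd.DataFrame:
    """Ground-truth table, one row per planted object."""
    rows = []
    for o in objects:
        row = {
            "object_id": o.object_id,
            "kind": o.kind,
            "row": o.center[0],
            "col": o.center[1],
            "cell_radius": o.cell_radius,
            "nucleus_radius": o.nucleus_radius,
            "attached_to": o.attached_to,
            "expected_label": o.expected_label,
        }
        for role in ROLES:
            row[f"amp_{role}"] = o.channel_amplitudes[role]
        rows.append(row)
    columns = [
        "object_id", "kind", "row", "col", "cell_radius", "nucleus_radius",
        "attached_to", "expected_label",
    ] + [f"amp_{r}" for r in ROLES]
    df = pd.DataFrame(rows, columns=columns)
    # stable dtype whether or not any LEV is attached
    df["attached_to"] = df["attached_to"].astype(float)
    return df


def generate_frame(
    spec: FrameSpec,
    seed: int,
    frame_id: str = "frame_0",
    channel_roles: dict[str, int] | None = None,
) -> tuple[ChannelStack, pd.DataFrame]:
    """Render one synthetic 4-channel frame with ground truth.

    Channel roles default to the staining scheme's fluorophore order
    (DAPI, AF488=Vim, AF555=CK, AF647=CD45/CD31) but are configurable.
    """
    roles = channel_roles or {"DAPI": 0, "Vim": 1, "CK": 2, "CD45/CD31": 3}
    rng = np.random.default_rng(seed)
    h, w = spec.shape
    images = np.full((4, h, w), spec.background, dtype=float)
    images += rng.normal(0.0, spec.noise_sigma, size=images.shape)
    objects = _place_objects(spec, rng)
    for obj in objects:
        _render(images, roles, obj, spec)
    stack = ChannelStack(frame_id=frame_id, images=images, channel_roles=roles)
    return stack, truth_table(objects)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CategoryParams:
    """Zero-inflated log-normal model for one category's events/mL.

    A patient presents the category with probability ``detect_p``;
    presenting patients draw their true rate from a log-normal whose
    location is solved so the *overall* population median equals
    ``target_median`` (which requires ``detect_p > 0.5`` when the
    target is positive).  Categories with a population median of 0 set
    ``detect_p <= 0.5`` and give the log-median of the presenting
    subpopulation directly via ``positive_median``.
    """

    detect_p: float
    target_median: float
    sigma: float = 1.1
    positive_median: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.detect_p <= 1.0:
            raise ValueError("detect_p must be in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("log-scale sigma must be positive")
        if self.target_median > 0 and self.detect_p <= 0.5:
            raise ValueError(
                "a positive population median requires detect_p > 0.5"
            )
        if self.target_median <= 0 and self.positive_median is None:
            raise ValueError(
                "zero-median categories must give positive_median"
            )

    @property
    def mu(self) -> float:
        """Log-location of the presenting subpopulation."""
        if self.target_median > 0:
            q = (0.5 - (1.0 - self.detect_p)) / self.detect_p
            return math.log(self.target_median) - self.sigma * norm.ppf(q)
        return math.log(self.positive_median)


@dataclass
class CohortSpec:
    """Sampling plan for a synthetic BCa + ND cohort."""

    n_bca: int = 50
    n_nd: int = 50
    bca: dict[str, CategoryParams] = field(default_factory=dict)
    nd: dict[str, CategoryParams] = field(default_factory=dict)
    wbc_range: tuple[float, float] = (3.3, 25.0)  # million cells/mL
    wbc_median: float = 6.75
    wbc_log_sigma: float = 0.35
    slides_per_test: int = 2
    slide_sigma: float = 0.2  # per-slide log-normal measurement noise
    # Shared per-patient burden factor: rare-event categories co-vary
    # within a patient (reported inter-category rank correlations are
    # ~0.3-0.6).  The factor's log-sd is absorbed into each category's
    # marginal sigma, so per-category medians are unaffected.
    shared_log_sigma: float = 0.7
    wbcs_per_slide: float = 2.5e6
    attached_fraction_bca: float = 0.554
    attached_fraction_nd: float = 0.541
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bca < 2 or self.n_nd < 2:
            raise ValueError("need at least 2 individuals per group")
        for grp in (self.bca, self.nd):
            missing = set(RARE_CATEGORIES) - set(grp)
            if missing:
                raise ValueError(f"missing category parameters: {sorted(missing)}")


# Printed BCa per-category cohort medians (events/mL); zero-median
# categories carry the presenting-subpopulation log-median instead.
_BCA_PARAMS: dict[str, CategoryParams] = {
    EPI_CTC: CategoryParams(0.38, 0.0, positive_median=1.7),
    MES_CTC: CategoryParams(0.46, 0.0, positive_median=2.8),
    CK_CD: CategoryParams(0.75, 1.44),
    CK_VIM_CD: CategoryParams(0.90, 23.19),
    VIM_CD: CategoryParams(0.85, 10.51),
    VIM_ONLY: CategoryParams(0.85, 11.18),
    CD_ONLY: CategoryParams(0.40, 0.0, positive_median=2.6),
    DAPI_ONLY: CategoryParams(0.85, 5.00),
    LEV_CK: CategoryParams(1.00, 27.06),
    LEV_CK_VIM: CategoryParams(0.40, 0.0, positive_median=1.0),
    LEV_CK_CD: CategoryParams(0.30, 0.0, positive_median=1.0),
    LEV_CK_VIM_CD: CategoryParams(0.54, 1.05),
}

# ND per-category medians are not reported; they are taken as the BCa
# medians scaled so the ND *group totals* land on their reported
# medians (34.46 cells/mL, 3.34 LEVs/mL).  The scale is the ND/BCa
# total ratio times a calibration factor for the gap between the
# median of a sum of zero-inflated log-normals and the sum of the
# scaled component medians (fitted once against large-n draws).
_ND_CELL_SCALE = 34.46 / 74.61 * 0.94
_ND_LEV_SCALE = 3.34 / 30.91 * 0.84
_ND_PARAMS: dict[str, CategoryParams] = {
    EPI_CTC: CategoryParams(0.35, 0.0, positive_median=1.7),
    MES_CTC: CategoryParams(0.42, 0.0, positive_median=2.8),
    CK_CD: CategoryParams(0.70, 1.44 * _ND_CELL_SCALE),
    CK_VIM_CD: CategoryParams(0.90, 23.19 * _ND_CELL_SCALE),
    VIM_CD: CategoryParams(0.85, 10.51 * _ND_CELL_SCALE),
    VIM_ONLY: CategoryParams(0.85, 11.18 * _ND_CELL_SCALE),
    CD_ONLY: CategoryParams(0.35, 0.0, positive_median=2.6),
    DAPI_ONLY: CategoryParams(0.85, 5.00 * _ND_CELL_SCALE),
    LEV_CK: CategoryParams(0.85, 27.06 * _ND_LEV_SCALE),
    LEV_CK_VIM: CategoryParams(0.20, 0.0, positive_median=1.0),
    LEV_CK_CD: CategoryParams(0.15, 0.0, positive_median=1.0),
    LEV_CK_VIM_CD: CategoryParams(0.25, 0.0, positive_median=1.0),
}


def default_cohort_spec(n_bca: int = 50, n_nd: int = 50, seed: int = 0) -> CohortSpec:
    """Cohort spec calibrated to the reported group summaries."""
    return CohortSpec(
        n_bca=n_bca, n_nd=n_nd, bca=dict(_BCA_PARAMS), nd=dict(_ND_PARAMS), seed=seed
    )


def _draw_patient(
    params: dict[str, CategoryParams],
    spec: CohortSpec,
    rng: np.random.Generator,
    sample_id: str,
    group: str,
    attached_fraction: float,
) -> SampleProfile:
    wbc = float(
        np.clip(
            math.exp(rng.normal(math.log(spec.wbc_median), spec.wbc_log_sigma)),
            *spec.wbc_range,
        )
    )
    wbcs_detected = [
        float(max(1.0, rng.normal(spec.wbcs_per_slide, 0.1 * spec.wbcs_per_slide)))
        for _ in range(spec.slides_per_test)
    ]
    mls = [ml_analyzed(wd, wbc) for wd in wbcs_detected]

    # separate burden factors: cellular categories co-vary with each
    # other, LEV categories with each other; cell-LEV coupling is weak
    burden_cells = rng.normal(0.0, spec.shared_log_sigma)
    burden_levs = rng.normal(0.0, spec.shared_log_sigma)
    per_slide: dict[str, list[float]] = {}
    for cat in RARE_CATEGORIES:
        p = params[cat]
        detected = rng.random() < p.detect_p
        burden = burden_levs if cat in LEV_CATEGORIES else burden_cells
        resid = math.sqrt(max(p.sigma**2 - spec.shared_log_sigma**2, 0.01))
        rate = (
            math.exp(p.mu + burden + rng.normal(0.0, resid)) if detected else 0.0
        )
        per_slide[cat] = [
            rate * math.exp(rng.normal(0.0, spec.slide_sigma)) if rate else 0.0
            for _ in range(spec.slides_per_test)
        ]
    rates = {cat: float(np.mean(v)) for cat, v in per_slide.items()}
    rates = add_totals(rates)

    total_lev_count = sum(
        rates[c] * float(np.mean(mls)) * spec.slides_per_test
        for c in LEV_CATEGORIES
    )
    n_lev = rng.poisson(max(total_lev_count, 0.0))
    attached = rng.binomial(n_lev, attached_fraction) if n_lev else 0
    return SampleProfile(
        sample_id=sample_id,
        group=group,
        wbc_cbc=wbc,
        wbcs_detected_per_slide=wbcs_detected,
        ml_analyzed_per_slide=mls,
        events_per_ml=rates,
        slides=spec.slides_per_test,
        lev_free_count=float(n_lev - attached),
        lev_attached_count=float(attached),
    )


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> CohortDataset:
    """Draw a synthetic cohort; reproducible for a given spec + seed."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    profiles = [
        _draw_patient(spec.bca, spec, rng, f"BCa_{i:03d}", "BCa",
                      spec.attached_fraction_bca)
        for i in range(spec.n_bca)
    ] + [
        _draw_patient(spec.nd, spec, rng, f"ND_{i:03d}", "ND",
                      spec.attached_fraction_nd)
        for i in range(spec.n_nd)
    ]
    return CohortDataset(profiles=profiles)


def match_events(
    truth: pd.DataFrame,
    centroids: list[tuple[float, float]],
    max_dist: float = 3.0,
) -> tuple[int, float, float]:
    """Match detected centroids to planted objects.

    One-to-one assignment (Hungarian) with matches farther than
    ``max_dist`` pixels discarded.  Returns ``(n_matched, recall,
    precision)`` against the truth rows given.
    """
    n_truth = len(truth)
    n_det = len(centroids)
    if n_truth == 0 or n_det == 0:
        return 0, 0.0 if n_truth else 1.0, 0.0 if n_det else 1.0
    t = truth[["row", "col"]].to_numpy(dtype=float)
    d = np.asarray(centroids, dtype=float)
    cost = np.hypot(t[:, None, 0] - d[None, :, 0], t[:, None, 1] - d[None, :, 1])
    rows, cols = linear_sum_assignment(cost)
    matched = int(np.sum(cost[rows, cols] <= max_dist))
    return matched, matched / n_truth, matched / n_det
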