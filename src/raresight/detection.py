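"""Event detection on 4-channel immunofluorescence frames.

A frame is a registered stack of four fluorescence channels (DAPI, CK,
Vim, CD45/CD31).  Detection proceeds in three stages:

1. nucleated objects are segmented on the DAPI channel (threshold +
   watershed split of touching nuclei),
2. a cell body is grown around every nucleus over the pixel-wise maximum
   of the CK and Vim channels (falling back to a fixed-radius dilation
   for cells with no cytoplasmic signal),
3. DAPI-negative CK-positive connected components in a configurable size
   window are reported separately as large-extracellular-vesicle (LEV)
   candidates, flagged as cell-attached when their boundary lies within
   a proximity radius of any cell mask.

Every detected object is summarised as an :class:`EventRecord` carrying
the morphometric and intensity features used by the downstream
classification, enumeration and morphometric-clustering stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import disk
from skimage.segmentation import watershed

from .categories import ROLES

__all__ = [
    "ChannelStack",
    "EventRecord",
    "DetectionParams",
    "Mask",
    "estimate_background",
    "segment_nuclei",
    "segment_cell_bodies",
    "extract_features",
    "detect_lev_candidates",
    "detect_events",
]


@dataclass(frozen=True)
class Mask:
    """A pixel set stored as a bounding-box offset plus a boolean grid.

    Coordinates are 0-based (row, col); the bounding box is half-open.
    """

    offset: tuple[int, int]
    grid: np.ndarray  # 2-D bool

    def __post_init__(self) -> None:
        if self.grid.ndim != 2 or self.grid.dtype != bool:
            raise ValueError("mask grid must be a 2-D boolean array")

    @property
    def area(self) -> int:
        return int(self.grid.sum())

    @property
    def is_empty(self) -> bool:
        return self.area == 0

    def pixels(self) -> np.ndarray:
        """(n, 2) array of global (row, col) pixel coordinates."""
        rr, cc = np.nonzero(self.grid)
        return np.column_stack([rr + self.offset[0], cc + self.offset[1]])

    def to_full(self, shape: tuple[int, int]) -> np.ndarray:
        full = np.zeros(shape, dtype=bool)
        r0, c0 = self.offset
        h, w = self.grid.shape
        full[r0 : r0 + h, c0 : c0 + w] = self.grid
        return full

    def values(self, image: np.ndarray) -> np.ndarray:
        """Image values over the mask pixels."""
        r0, c0 = self.offset
        h, w = self.grid.shape
        return image[r0 : r0 + h, c0 : c0 + w][self.grid]

    def contains(self, other: "Mask") -> bool:
        mine = set(map(tuple, self.pixels()))
        return all(tuple(p) in mine for p in other.pixels())

    @staticmethod
    def from_full(full: np.ndarray) -> "Mask":
        if not full.any():
            return Mask((0, 0), np.zeros((0, 0), dtype=bool))
        rr, cc = np.nonzero(full)
        r0, r1 = rr.min(), rr.max() + 1
        c0, c1 = cc.min(), cc.max() + 1
        return Mask((int(r0), int(c0)), full[r0:r1, c0:c1].astype(bool))


EMPTY_MASK = Mask((0, 0), np.zeros((0, 0), dtype=bool))


@dataclass
class ChannelStack:
    """One frame's registered 4-channel image set.

    ``channel_roles`` maps each marker role (DAPI, CK, Vim, CD45/CD31)
    to its page index in ``images``.
    """

    frame_id: str
    images: np.ndarray  # (4, H, W)
    channel_roles: dict[str, int]

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        if self.images.ndim != 3 or self.images.shape[0] != 4:
            raise ValueError("images must be a (4, H, W) array")
        if sorted(self.channel_roles) != sorted(ROLES):
            raise ValueError(f"channel_roles must map exactly {ROLES}")
        idx = sorted(self.channel_roles.values())
        if idx != [0, 1, 2, 3]:
            raise ValueError("channel_roles must use each page index once")

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1:]

    def channel(self, role: str) -> np.ndarray:
        return self.images[self.channel_roles[role]]


@dataclass
class EventRecord:
    """One detected object (cell or LEV candidate) with its features."""

    event_id: int
    frame_id: str
    centroid: tuple[float, float]
    cell_mask: Mask
    nucleus_mask: Mask
    cell_area: int = 0
    nucleus_area: int = 0
    cell_eccentricity: float = float("nan")
    nucleus_eccentricity: float = float("nan")
    median_intensity: dict[str, float] = field(default_factory=dict)
    positivity: dict[str, bool] = field(default_factory=dict)
    is_dapi_positive: bool = False
    attached_flag: bool = False
    solidity: float = float("nan")
    annularity: float = float("nan")
    label: str | None = None
    is_rare: bool | None = None


@dataclass
class DetectionParams:
    """Tunable detection thresholds.

    Intensity thresholds are expressed as ``background + k * sigma``
    where background and sigma are the per-channel median and robust
    (MAD-based) standard deviation of off-object pixels.
    """

    k_sigma: float = 5.0  # positivity threshold multiple for CK/Vim/CD
    k_sigma_dapi: float = 5.0
    nucleus_threshold: str = "sigma"  # "sigma" or "otsu"
    min_nucleus_area: int = 12
    watershed_min_distance: int = 4
    fallback_dilation_radius: int = 2
    min_lev_area: int = 6
    max_lev_area: int = 400
    proximity_radius: int = 5


def _robust_background(image: np.ndarray, exclude: np.ndarray | None = None):
    """Median and MAD-derived sigma of (optionally off-object) pixels."""
    vals = image if exclude is None else image[~exclude]
    if vals.size == 0:
        vals = image
    med = float(np.median(vals))
    sigma = float(1.4826 * np.median(np.abs(vals - med)))
    return med, max(sigma, 1e-12)


def estimate_background(
    stack: ChannelStack, masks: list[Mask] | None = None
) -> dict[str, tuple[float, float]]:
    """Per-role (median, robust sigma) over pixels outside all masks."""
    exclude = None
    if masks:
        exclude = np.zeros(stack.shape, dtype=bool)
        for m in masks:
            if not m.is_empty:
                exclude |= m.to_full(stack.shape)
    return {
        role: _robust_background(stack.channel(role).astype(float), exclude)
        for role in ROLES
    }


def segment_nuclei(
    stack: ChannelStack, params: DetectionParams | None = None
) -> list[Mask]:
    """Segment nuclei on the DAPI channel.

    Thresholds the background-corrected DAPI image (robust-sigma
    multiple by default, global Otsu optionally), splits touching
    components by watershed on the distance transform, and discards
    components below ``min_nucleus_area``.
    """
    params = params or DetectionParams()
    dapi = stack.channel("DAPI").astype(float)
    bg, sigma = _robust_background(dapi)
    if params.nucleus_threshold == "otsu":
        thr = threshold_otsu(dapi) if dapi.max() > dapi.min() else np.inf
    else:
        thr = bg + params.k_sigma_dapi * sigma
    binary = dapi > thr
    if not binary.any():
        return []
    # split touching nuclei on the distance transform
    distance = ndi.distance_transform_edt(binary)
    coords = peak_local_max(
        distance,
        min_distance=params.watershed_min_distance,
        labels=binary,
        exclude_border=False,
    )
    if len(coords) == 0:
        return []
    markers = np.zeros(binary.shape, dtype=int)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    labels = watershed(-distance, markers, mask=binary)
    masks = []
    for lab in range(1, labels.max() + 1):
        full = labels == lab
        if full.sum() >= params.min_nucleus_area:
            masks.append(Mask.from_full(full))
    return masks


def segment_cell_bodies(
    nucleus_masks: list[Mask],
    stack: ChannelStack,
    params: DetectionParams | None = None,
) -> list[Mask]:
    """Grow one cell mask around each nucleus.

    Cells are grown over the pixel-wise maximum of the
    background-subtracted CK and Vim channels by a marker-based
    watershed, so no pixel ever belongs to two cells.  Nuclei with no
    cytoplasmic signal fall back to a fixed-radius dilation.
    """
    params = params or DetectionParams()
    if not nucleus_masks:
        return []
    shape = stack.shape
    ck = stack.channel("CK").astype(float)
    vim = stack.channel("Vim").astype(float)
    bg_ck, s_ck = _robust_background(ck)
    bg_vim, s_vim = _robust_background(vim)
    comp = np.maximum(ck - bg_ck, vim - bg_vim)
    signal = comp > params.k_sigma * max(s_ck, s_vim)

    markers = np.zeros(shape, dtype=int)
    nuc_union = np.zeros(shape, dtype=bool)
    for i, nm in enumerate(nucleus_masks, start=1):
        full = nm.to_full(shape)
        markers[full] = i
        nuc_union |= full

    # cytoplasm must surround a nucleus: signal components that touch no
    # nucleus are anucleate objects (LEV candidates, debris) and must
    # not be absorbed into a neighboring cell body
    sig_labels, n_sig = ndi.label(signal)
    if n_sig:
        keep = np.unique(sig_labels[nuc_union])
        signal = np.isin(sig_labels, keep[keep > 0])
    fallback = ndi.binary_dilation(
        nuc_union, structure=disk(params.fallback_dilation_radius)
    )
    region = signal | fallback
    labels = watershed(-comp, markers, mask=region)

    cells = []
    for i, nm in enumerate(nucleus_masks, start=1):
        full = labels == i
        full |= nm.to_full(shape)  # a cell always contains its nucleus
        # keep only the connected component holding the nucleus
        lab, _ = ndi.label(full)
        seed = nm.pixels()[0]
        full = lab == lab[seed[0], seed[1]]
        cells.append(Mask.from_full(full))
    return cells


def _mask_shape_features(mask: Mask) -> tuple[tuple[float, float], float, float]:
    """(centroid, eccentricity, solidity) from second-order mask moments."""
    props = regionprops(mask.grid.astype(int))[0]
    r, c = props.centroid
    centroid = (r + mask.offset[0], c + mask.offset[1])
    return centroid, float(props.eccentricity), float(props.solidity)


def extract_features(
    cell_mask: Mask,
    nucleus_mask: Mask,
    stack: ChannelStack,
    background: dict[str, tuple[float, float]] | None = None,
    event_id: int = 0,
) -> EventRecord:
    """Fill an :class:`EventRecord` for one object.

    Median intensities are computed per channel role after subtracting
    the frame background estimate (median of off-object pixels):
    cytoplasmic markers (CK, Vim, CD45/CD31) over the cell mask, the
    nuclear DNA stain (DAPI) over the nucleus mask when one exists —
    otherwise the cell mask would dilute the nuclear signal for cells
    whose cytoplasm dwarfs the nucleus.  Eccentricities come from
    second-order mask moments.
    """
    if cell_mask.is_empty:
        raise ValueError("cannot extract features from an empty cell mask")
    background = background or estimate_background(stack)
    centroid, cell_ecc, solidity = _mask_shape_features(cell_mask)
    if not nucleus_mask.is_empty:
        _, nuc_ecc, _ = _mask_shape_features(nucleus_mask)
    else:
        nuc_ecc = float("nan")
    medians = {}
    for role in ROLES:
        src = cell_mask
        if role == "DAPI" and not nucleus_mask.is_empty:
            src = nucleus_mask
        vals = src.values(stack.channel(role).astype(float))
        medians[role] = float(np.median(vals)) - background[role][0]
    return EventRecord(
        event_id=event_id,
        frame_id=stack.frame_id,
        centroid=centroid,
        cell_mask=cell_mask,
        nucleus_mask=nucleus_mask,
        cell_area=cell_mask.area,
        nucleus_area=nucleus_mask.area,
        cell_eccentricity=cell_ecc,
        nucleus_eccentricity=nuc_ecc,
        median_intensity=medians,
        is_dapi_positive=not nucleus_mask.is_empty,
        solidity=solidity,
    )


def _annularity(mask: Mask) -> float:
    """Fraction of the filled component occupied by interior holes.

    Bright rings with dark interiors (halo/bubble artifacts) score
    high; solid membranous vesicles score near zero.
    """
    filled = ndi.binary_fill_holes(mask.grid)
    filled_area = int(filled.sum())
    if filled_area == 0:
        return 0.0
    return float((filled_area - mask.area) / filled_area)


def detect_lev_candidates(
    stack: ChannelStack,
    cell_masks: list[Mask],
    nucleus_masks: list[Mask],
    params: DetectionParams | None = None,
    background: dict[str, tuple[float, float]] | None = None,
    start_id: int = 0,
) -> list[EventRecord]:
    """Detect DAPI-negative CK-positive LEV candidates.

    Connected components of the thresholded CK channel are kept when
    they do not overlap any nucleus (those belong to cells), their DAPI
    median is below the DAPI positivity threshold, and their area falls
    within the configured LEV size window.  Each candidate is flagged
    ``attached_flag`` when its mask, dilated by the proximity radius,
    touches any cell mask.
    """
    params = params or DetectionParams()
    shape = stack.shape
    ck = stack.channel("CK").astype(float)
    bg_ck, s_ck = _robust_background(ck)
    binary = (ck - bg_ck) > params.k_sigma * s_ck
    if not binary.any():
        return []

    nuc_union = np.zeros(shape, dtype=bool)
    for nm in nucleus_masks:
        nuc_union |= nm.to_full(shape)
    cell_union = np.zeros(shape, dtype=bool)
    for cm in cell_masks:
        cell_union |= cm.to_full(shape)

    dapi = stack.channel("DAPI").astype(float)
    bg_dapi, s_dapi = _robust_background(dapi)
    dapi_thr = params.k_sigma_dapi * s_dapi

    background = background or estimate_background(stack)
    labels, n = ndi.label(binary)
    records = []
    eid = start_id
    struct = disk(params.proximity_radius)
    for lab in range(1, n + 1):
        full = labels == lab
        if (full & nuc_union).any():
            continue  # belongs to a nucleated cell
        area = int(full.sum())
        if not (params.min_lev_area <= area <= params.max_lev_area):
            continue
        mask = Mask.from_full(full)
        if np.median(mask.values(dapi)) - bg_dapi >= dapi_thr:
            continue  # DAPI-positive: not an LEV
        rec = extract_features(mask, EMPTY_MASK, stack, background, event_id=eid)
        rec.annularity = _annularity(mask)
        near = ndi.binary_dilation(full, structure=struct)
        rec.attached_flag = bool((near & cell_union).any())
        records.append(rec)
        eid += 1
    return records


def detect_events(
    stack: ChannelStack, params: DetectionParams | None = None
) -> tuple[list[EventRecord], list[EventRecord]]:
    """Run the full detection stage on one frame.

    Returns ``(cells, lev_candidates)``; features are extracted against
    a shared background estimate taken outside all detected masks.
    """
    params = params or DetectionParams()
    nuclei = segment_nuclei(stack, params)
    cells = segment_cell_bodies(nuclei, stack, params)
    background = estimate_background(stack, cells)
    cell_records = [
        extract_features(cm, nm, stack, background, event_id=i)
        for i, (cm, nm) in enumerate(zip(cells, nuclei))
    ]
    lev_records = detect_lev_candidates(
        stack, cells, nuclei, params, background, start_id=len(cell_records)
    )
    return cell_records, lev_records
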