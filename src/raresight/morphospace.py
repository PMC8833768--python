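"""Morphometric embedding and clustering of rare cellular events.

Rare nucleated events are summarised by eight measures — median DAPI,
CK, Vim and CD45/CD31 intensity plus area and eccentricity of the cell
and of the nucleus — z-scored by column, embedded in 2-D with tSNE for
visualisation, and grouped by Ward/Euclidean agglomerative clustering
(five clusters by default) to expose morphological subpopulations that
cut across the marker-defined categories.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.cluster import AgglomerativeClustering
from sklearn.manifold import TSNE

from .classification import MORPHO_FEATURES
from .detection import EventRecord

__all__ = [
    "MORPHO_FEATURES",
    "build_morpho_matrix",
    "standardize",
    "embed_tsne",
    "cluster_agglomerative",
    "density_profiles",
]

# Fig-style density summaries are produced for these five measures.
DENSITY_FEATURES = (
    "cell_area",
    "cell_eccentricity",
    "median_CK",
    "median_Vim",
    "median_CD45/CD31",
)


def build_morpho_matrix(events: list[EventRecord]) -> pd.DataFrame:
    """8-column morphometric matrix for rare cellular events.

    Rows are the DAPI-positive rare events (LEVs have no nuclear
    morphology and are excluded); the ``label`` column carries each
    row's channel-type category.
    """
    rows = []
    for e in events:
        if not e.is_dapi_positive or not e.is_rare:
            continue
        rows.append(
            {
                "median_DAPI": e.median_intensity["DAPI"],
                "median_CK": e.median_intensity["CK"],
                "median_Vim": e.median_intensity["Vim"],
                "median_CD45/CD31": e.median_intensity["CD45/CD31"],
                "cell_area": e.cell_area,
                "nucleus_area": e.nucleus_area,
                "cell_eccentricity": e.cell_eccentricity,
                "nucleus_eccentricity": e.nucleus_eccentricity,
                "label": e.label,
            }
        )
    df = pd.DataFrame(rows, columns=list(MORPHO_FEATURES) + ["label"])
    if df[list(MORPHO_FEATURES)].isna().any().any():
        raise ValueError("morphometric matrix contains missing values")
    return df


def standardize(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Column z-scores; constant columns map to zero."""
    x = np.asarray(
        matrix[list(MORPHO_FEATURES)] if isinstance(matrix, pd.DataFrame) else matrix,
        dtype=float,
    )
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    return (x - mean) / std


def embed_tsne(
    matrix: pd.DataFrame | np.ndarray,
    perplexity: float = 30.0,
    seed: int = 0,
) -> np.ndarray:
    """2-D tSNE embedding of the standardized morphometric matrix.

    Deterministic for a fixed seed (PCA initialisation, single
    worker).  Requires at least ``3 * perplexity`` rows for the
    perplexity to be meaningful.
    """
    x = standardize(matrix)
    if len(x) < 3 * perplexity:
        raise ValueError(
            f"{len(x)} rows is too few for perplexity {perplexity}; "
            "need at least 3x perplexity"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        random_state=seed,
        n_jobs=1,
    )
    return tsne.fit_transform(x)


def cluster_agglomerative(
    matrix: pd.DataFrame | np.ndarray, k: int = 5
) -> np.ndarray:
    """Ward/Euclidean agglomerative clustering into ``k`` clusters.

    Features are standardized first; labels are 1..k and deterministic
    (Ward agglomeration has no random component).
    """
    x = standardize(matrix)
    if len(x) < k:
        raise ValueError(f"cannot form {k} clusters from {len(x)} rows")
    model = AgglomerativeClustering(n_clusters=k, linkage="ward")
    return model.fit_predict(x) + 1


def density_profiles(
    matrix: pd.DataFrame,
    features: tuple[str, ...] = DENSITY_FEATURES,
    grid_points: int = 256,
) -> dict[str, dict[str, dict]]:
    """Per-category 1-D kernel density estimates for selected features.

    Returns ``{feature: {label: {"grid", "density", "degenerate"}}}``.
    Categories with fewer than two rows are skipped with a warning;
    constant features are flagged degenerate (a point mass has no
    finite-bandwidth KDE) with their spike location reported.
    """
    out: dict[str, dict[str, dict]] = {}
    for feat in features:
        out[feat] = {}
        for label, sub in matrix.groupby("label"):
            vals = sub[feat].to_numpy(dtype=float)
            if len(vals) < 2:
                warnings.warn(
                    f"category {label!r} has <2 rows; skipped for {feat}",
                    stacklevel=2,
                )
                continue
            if np.ptp(vals) == 0:
                out[feat][label] = {
                    "grid": np.array([vals[0]]),
                    "density": np.array([np.inf]),
                    "degenerate": True,
                }
                continue
            kde = gaussian_kde(vals)
            pad = 3 * vals.std()
            grid = np.linspace(vals.min() - pad, vals.max() + pad, grid_points)
            out[feat][label] = {
                "grid": grid,
                "density": kde(grid),
                "degenerate": False,
            }
    return out


def density_overlap(profile_a: dict, profile_b: dict) -> float:
    """Overlap coefficient of two density summaries on a common grid."""
    if profile_a.get("degenerate") or profile_b.get("degenerate"):
        ga, gb = profile_a["grid"], profile_b["grid"]
        return 1.0 if np.array_equal(ga, gb) else 0.0
    lo = min(profile_a["grid"][0], profile_b["grid"][0])
    hi = max(profile_a["grid"][-1], profile_b["grid"][-1])
    grid = np.linspace(lo, hi, 1024)
    da = np.interp(grid, profile_a["grid"], profile_a["density"], left=0, right=0)
    db = np.interp(grid, profile_b["grid"], profile_b["density"], left=0, right=0)
    return float(np.trapezoid(np.minimum(da, db), grid))
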