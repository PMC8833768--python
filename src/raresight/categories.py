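"""Canonical rare-event taxonomy.

Events detected on a slide are assigned one of 12 rare categories (8
cellular, 4 LEV) by their DAPI / CK / Vim / CD45-CD31 positivity pattern,
or fall through to ``common cell`` (ordinary leukocytes and endothelial
cells) or ``excluded`` (DAPI-negative, CK-negative objects that are not
analytes of this assay).

The category strings defined here are the single source of truth for
column names in enumeration tables, cohort profiles and design matrices.
"""

from __future__ import annotations

# Marker roles, in canonical order.
ROLES = ("DAPI", "CK", "Vim", "CD45/CD31")

# 8 nucleated (DAPI+) rare-cell categories.
EPI_CTC = "epi.CTC"
MES_CTC = "mes.CTC"
CK_CD = "CK|CD45/CD31"
CK_VIM_CD = "CK|Vim|CD45/CD31"
VIM_CD = "Vim|CD45/CD31"
VIM_ONLY = "Vim only"
CD_ONLY = "CD45/CD31 only"
DAPI_ONLY = "DAPI only"

CELL_CATEGORIES = (
    EPI_CTC,
    MES_CTC,
    CK_CD,
    CK_VIM_CD,
    VIM_CD,
    VIM_ONLY,
    CD_ONLY,
    DAPI_ONLY,
)

# 4 anucleate (DAPI-, CK+) large extracellular vesicle categories.
LEV_CK = "LEV CK only"
LEV_CK_VIM = "LEV CK|Vim"
LEV_CK_CD = "LEV CK|CD45/CD31"
LEV_CK_VIM_CD = "LEV CK|Vim|CD45/CD31"

LEV_CATEGORIES = (LEV_CK, LEV_CK_VIM, LEV_CK_CD, LEV_CK_VIM_CD)

RARE_CATEGORIES = CELL_CATEGORIES + LEV_CATEGORIES

COMMON_CELL = "common cell"
EXCLUDED = "excluded"

# Derived totals reported alongside the 12 categories.
TOTAL_CELLS = "total rare cells"
TOTAL_LEVS = "total LEVs"
TOTAL_EVENTS = "total rare events"
TOTAL_CK_CELLS = "total CK+ cells"

TOTAL_COLUMNS = (TOTAL_CELLS, TOTAL_LEVS, TOTAL_EVENTS, TOTAL_CK_CELLS)

# All DAPI+ CK+ cellular categories count toward "total CK+ cells".
CK_POSITIVE_CELL_CATEGORIES = (EPI_CTC, MES_CTC, CK_CD, CK_VIM_CD)

# Positivity pattern (DAPI, CK, Vim, CD45/CD31) -> category.  Total over
# all 16 combinations; DAPI-negative CK-negative objects are excluded.
PATTERN_TO_LABEL: dict[tuple[bool, bool, bool, bool], str] = {
    # DAPI-positive (nucleated) patterns
    (True, True, False, False): EPI_CTC,
    (True, True, True, False): MES_CTC,
    (True, True, False, True): CK_CD,
    (True, True, True, True): CK_VIM_CD,
    (True, False, True, True): VIM_CD,
    (True, False, True, False): VIM_ONLY,
    (True, False, False, True): CD_ONLY,
    (True, False, False, False): DAPI_ONLY,
    # DAPI-negative CK-positive patterns: LEVs
    (False, True, False, False): LEV_CK,
    (False, True, True, False): LEV_CK_VIM,
    (False, True, False, True): LEV_CK_CD,
    (False, True, True, True): LEV_CK_VIM_CD,
    # DAPI-negative CK-negative: not an analyte
    (False, False, False, False): EXCLUDED,
    (False, False, True, False): EXCLUDED,
    (False, False, False, True): EXCLUDED,
    (False, False, True, True): EXCLUDED,
}

# Expected positive roles per category (used by the synthetic generator
# and by ground-truth checks).
LABEL_TO_PATTERN: dict[str, tuple[bool, bool, bool, bool]] = {
    label: pattern
    for pattern, label in PATTERN_TO_LABEL.items()
    if label != EXCLUDED
}


def is_lev_category(label: str) -> bool:
    return label in LEV_CATEGORIES


def is_cell_category(label: str) -> bool:
    return label in CELL_CATEGORIES
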