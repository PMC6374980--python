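"""Catalogue of the 15 major white matter tracts used throughout the pipeline.

Twelve tracts are bilateral (left/right hemisphere values) and three are
unilateral midline structures, giving 27 tract-averaged measures per
diffusion modality (FA or MD).  Each tract belongs to one of three
categories: association fibers, thalamic radiations, or projection fibers.
"""

from __future__ import annotations

from dataclasses import dataclass

ASSOCIATION = "association"
THALAMIC = "thalamic"
PROJECTION = "projection"

CATEGORIES = (ASSOCIATION, THALAMIC, PROJECTION)

LEFT = "left"
RIGHT = "right"
MIDLINE = ""  # hemisphere label for unilateral tracts


@dataclass(frozen=True)
class Tract:
    name: str
    category: str
    bilateral: bool


TRACTS: tuple[Tract, ...] = (
    # association fibers (all bilateral)
    Tract("inferior fronto-occipital fasciculus", ASSOCIATION, True),
    Tract("uncinate fasciculus", ASSOCIATION, True),
    Tract("cingulate gyrus part of cingulum", ASSOCIATION, True),
    Tract("parahippocampal part of cingulum", ASSOCIATION, True),
    Tract("superior longitudinal fasciculus", ASSOCIATION, True),
    Tract("inferior longitudinal fasciculus", ASSOCIATION, True),
    # thalamic radiations (all bilateral)
    Tract("anterior thalamic radiation", THALAMIC, True),
    Tract("superior thalamic radiation", THALAMIC, True),
    Tract("posterior thalamic radiation", THALAMIC, True),
    # projection fibers (three unilateral midline tracts)
    Tract("corticospinal tract", PROJECTION, True),
    Tract("acoustic radiation", PROJECTION, True),
    Tract("medial lemniscus", PROJECTION, True),
    Tract("forceps major", PROJECTION, False),
    Tract("forceps minor", PROJECTION, False),
    Tract("middle cerebellar peduncle", PROJECTION, False),
)

TRACT_BY_NAME: dict[str, Tract] = {t.name: t for t in TRACTS}

MEASURES = ("FA", "MD")


def tract_columns(category: str | None = None) -> list[tuple[str, str]]:
    """(tract, hemisphere) column labels, optionally restricted to a category.

    Bilateral tracts contribute a left and a right column; unilateral tracts a
    single midline column.  The full catalogue yields 27 columns.
    """
    cols: list[tuple[str, str]] = []
    for t in TRACTS:
        if category is not None and t.category != category:
            continue
        if t.bilateral:
            cols.append((t.name, LEFT))
            cols.append((t.name, RIGHT))
        else:
            cols.append((t.name, MIDLINE))
    return cols


def bilateral_tracts() -> list[Tract]:
    return [t for t in TRACTS if t.bilateral]


def unilateral_tracts() -> list[Tract]:
    return [t for t in TRACTS if not t.bilateral]
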