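"""Microglia shape descriptors and morphotype classification.

Input is a segmented binary mask per cell (any segmenter, or the synthetic
shape generator).  Three descriptors drive a fixed decision tree, applied
in order:

1. circularity <= ``circ_max`` (default 1.03)  ->  RAMIFIED
2. otherwise, ``n_processes`` < ``min_processes`` (default 3)  ->  AMOEBOID
3. otherwise  ->  HYPERTROPHIC

Circularity is defined as ``perimeter**2 / (4 * pi * area)`` so a perfect
disc scores exactly 1 and boundary irregularity raises the score; the 1.03
ceiling therefore selects near-circular somata.  The perimeter uses the
Crofton estimator, whose discretisation error vanishes as cells grow, so a
rasterised disc converges to circularity 1.

Processes are counted as skeleton branches that leave the soma, the soma
being the maximal inscribed disc of the mask (centre and radius from the
Euclidean distance transform).  Skeleton fragments shorter than
``min_branch_px`` outside the soma are treated as discretisation spurs,
not processes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as sk_label
from skimage.measure import perimeter_crofton
from skimage.morphology import skeletonize

__all__ = [
    "MorphClass",
    "circularity_index",
    "CellRecord",
    "shape_descriptors",
    "count_processes",
    "classify_cell",
    "cells_from_labeled_image",
    "cells_from_descriptor_table",
    "summarize_regions",
]

REGIONS = ("PrL", "IL", "CA1", "CA3", "DG", "MEC")


class MorphClass(str, Enum):
    RAMIFIED = "RAMIFIED"
    AMOEBOID = "AMOEBOID"
    HYPERTROPHIC = "HYPERTROPHIC"


@dataclass(frozen=True)
class CellRecord:
    """One segmented microglia with its descriptors and assigned class."""

    cell_id: str
    rat_id: str
    strain: str
    sex: str
    region: str
    area: float          # µm²
    perimeter: float     # µm
    circularity: float
    n_processes: int
    morph_class: MorphClass


def circularity_index(perimeter: float, area: float) -> float:
    """``perimeter**2 / (4*pi*area)``: 1 for a disc, 4/pi for a square,
    larger for any irregular boundary (isoperimetric inequality)."""
    if area <= 0 or perimeter <= 0:
        raise ValueError("perimeter and area must be positive")
    return perimeter**2 / (4.0 * math.pi * area)


def shape_descriptors(
    mask: np.ndarray, pixel_size: float = 1.0
) -> tuple[float, float, float]:
    """(area µm², perimeter µm, circularity) of a single-component mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    n_comp = sk_label(mask, connectivity=2).max()
    if n_comp != 1:
        raise ValueError(f"mask must be a single connected component, got {n_comp}")
    area_px = float(mask.sum())
    perim_px = float(perimeter_crofton(mask, directions=4))
    area = area_px * pixel_size**2
    perimeter = perim_px * pixel_size
    return area, perimeter, circularity_index(perimeter, area)


def count_processes(mask: np.ndarray, min_branch_px: int = 4) -> int:
    """Number of skeleton branches exiting the maximal inscribed soma disc."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 3:
        raise ValueError("mask too small to analyse")
    edt = ndimage.distance_transform_edt(mask)
    centre = np.unravel_index(np.argmax(edt), edt.shape)
    r_soma = float(edt[centre])
    yy, xx = np.indices(mask.shape)
    outside = (yy - centre[0]) ** 2 + (xx - centre[1]) ** 2 > r_soma**2
    skel = skeletonize(mask)
    branches = skel & outside
    lab, n = ndimage.label(branches, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return 0
    sizes = ndimage.sum_labels(branches, lab, index=np.arange(1, n + 1))
    return int((sizes >= min_branch_px).sum())


def classify_cell(
    circularity: float,
    n_processes: int,
    circ_max: float = 1.03,
    min_processes: int = 3,
) -> MorphClass:
    """Apply the three-way morphotype decision tree."""
    if circularity <= circ_max:
        return MorphClass.RAMIFIED
    if n_processes < min_processes:
        return MorphClass.AMOEBOID
    return MorphClass.HYPERTROPHIC


def _touches_border(mask: np.ndarray) -> bool:
    return bool(
        mask[0, :].any() or mask[-1, :].any()
        or mask[:, 0].any() or mask[:, -1].any()
    )


def cells_from_labeled_image(
    labels: np.ndarray,
    metadata: pd.DataFrame,
    pixel_size: float | None = None,
    circ_max: float = 1.03,
    min_processes: int = 3,
    exclude_border: bool = True,
) -> list[CellRecord]:
    """Build classified cell records from an integer-labelled mask image.

    ``metadata`` has one row per label with columns ``label, cell_id,
    rat_id, strain, sex, region`` and optionally ``pixel_size_um`` (used
    when ``pixel_size`` is not given).  Cells touching the image border are
    excluded by default — truncated processes bias the class.
    """
    labels = np.asarray(labels)
    records: list[CellRecord] = []
    for row in metadata.itertuples():
        mask = labels == int(row.label)
        if not mask.any():
            raise ValueError(f"label {row.label} absent from image")
        if exclude_border and _touches_border(mask):
            continue
        px = pixel_size
        if px is None:
            px = float(getattr(row, "pixel_size_um", 1.0))
        area, perim, circ = shape_descriptors(mask, px)
        n_proc = count_processes(mask)
        records.append(
            CellRecord(
                cell_id=str(row.cell_id),
                rat_id=str(row.rat_id),
                strain=str(row.strain),
                sex=str(row.sex),
                region=str(row.region),
                area=area,
                perimeter=perim,
                circularity=circ,
                n_processes=n_proc,
                morph_class=classify_cell(circ, n_proc, circ_max, min_processes),
            )
        )
    return records


def cells_from_descriptor_table(
    table: pd.DataFrame,
    circ_max: float = 1.03,
    min_processes: int = 3,
) -> list[CellRecord]:
    """Classify cells from a precomputed descriptor table (mask bypass).

    Columns: ``cell_id, rat_id, strain, sex, region, area, perimeter,
    circularity, n_processes``.
    """
    records = []
    for row in table.itertuples():
        records.append(
            CellRecord(
                cell_id=str(row.cell_id),
                rat_id=str(row.rat_id),
                strain=str(row.strain),
                sex=str(row.sex),
                region=str(row.region),
                area=float(row.area),
                perimeter=float(row.perimeter),
                circularity=float(row.circularity),
                n_processes=int(row.n_processes),
                morph_class=classify_cell(
                    float(row.circularity), int(row.n_processes),
                    circ_max, min_processes,
                ),
            )
        )
    return records


def cells_table(cells: Iterable[CellRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(c) for c in cells])
    if not df.empty:
        df["morph_class"] = df["morph_class"].map(lambda m: m.value)
    return df


def summarize_regions(cells: Sequence[CellRecord]) -> pd.DataFrame:
    """Per (rat, region) class counts and percent hypertrophic of total."""
    if not cells:
        raise ValueError("no cells to summarise")
    df = cells_table(cells)
    rows = []
    for (rat, region), sub in df.groupby(["rat_id", "region"], sort=True):
        counts = {
            m.value: int((sub["morph_class"] == m.value).sum())
            for m in MorphClass
        }
        total = len(sub)
        rows.append(
            {
                "rat_id": rat,
                "strain": sub["strain"].iloc[0],
                "sex": sub["sex"].iloc[0],
                "region": region,
                "n_ramified": counts["RAMIFIED"],
                "n_amoeboid": counts["AMOEBOID"],
                "n_hypertrophic": counts["HYPERTROPHIC"],
                "n_total": total,
                "pct_hypertrophic": 100.0 * counts["HYPERTROPHIC"] / total,
            }
        )
    return pd.DataFrame(rows)
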