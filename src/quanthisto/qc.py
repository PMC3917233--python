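"""Mask-based quality control of classified feature tables.

Two manually created (or synthetically generated) masks drive the QC: the
whole-section mask filters out objects beyond the section's outline — dirt,
shed epidermal or cortex cells, mis-segmented debris — and the xylem-area
mask corrects the frequent classifier confusion between xylem
vessels/parenchyma and phloem parenchyma, whose outlines converge late in
secondary growth.  Membership is tested on the cell centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import CellClass

XYLEM_CLASSES = (CellClass.XYLEM_VESSEL_PARENCHYMA.value,
                 CellClass.XYLEM_FIBER.value)


@dataclass
class MaskPair:
    """Whole-section and xylem-area binary masks in the label-map frame."""

    section_mask: np.ndarray
    xylem_mask: np.ndarray
    provenance: str = "manual"

    def __post_init__(self) -> None:
        self.section_mask = np.asarray(self.section_mask).astype(bool)
        self.xylem_mask = np.asarray(self.xylem_mask).astype(bool)
        if self.section_mask.shape != self.xylem_mask.shape:
            raise ValueError("masks must share one image frame")
        if (self.xylem_mask & ~self.section_mask).any():
            raise ValueError("xylem mask must lie inside the section mask")


def _inside(mask: np.ndarray, xs, ys) -> np.ndarray:
    h, w = mask.shape
    xi = np.clip(np.round(xs).astype(int), 0, w - 1)
    yi = np.clip(np.round(ys).astype(int), 0, h - 1)
    inb = (np.round(xs) >= 0) & (np.round(xs) < w) & \
          (np.round(ys) >= 0) & (np.round(ys) < h)
    return inb & mask[yi, xi]


def filter_outside(table: pd.DataFrame, masks: MaskPair):
    """Drop cells whose centroid falls outside the section mask.

    Returns ``(kept_table, dropped_ids)``.
    """
    if not masks.section_mask.any():
        raise ValueError("section mask is empty")
    inside = _inside(masks.section_mask, table["centroid_x"].to_numpy(),
                     table["centroid_y"].to_numpy())
    dropped = table.loc[~inside, "cell_id"].tolist()
    return table.loc[inside].reset_index(drop=True), dropped


def correct_xylem(table: pd.DataFrame, masks: MaskPair,
                  bidirectional: bool = True):
    """Reconcile xylem-related class labels with the xylem-area mask.

    Cells labeled as a xylem class with their centroid outside the xylem
    mask become phloem parenchyma (the class they are typically confused
    with); with ``bidirectional`` (default), phloem parenchyma inside the
    mask becomes xylem vessel/parenchyma.  Returns ``(corrected, change_log)``
    where the log is a DataFrame of (cell_id, old_class, new_class).  After
    correction no xylem-class centroid lies outside the xylem mask.  The
    operation is idempotent and never adds or removes rows.
    """
    if "class" not in table:
        raise ValueError("table lacks a 'class' column")
    out = table.copy()
    inside = _inside(masks.xylem_mask, out["centroid_x"].to_numpy(),
                     out["centroid_y"].to_numpy())
    cls = out["class"].astype(str)
    changes = []

    to_phloem = cls.isin(XYLEM_CLASSES).to_numpy() & ~inside
    for idx in out.index[to_phloem]:
        changes.append((out.at[idx, "cell_id"], out.at[idx, "class"],
                        CellClass.PHLOEM_PARENCHYMA.value))
    out.loc[to_phloem, "class"] = CellClass.PHLOEM_PARENCHYMA.value

    if bidirectional:
        to_xylem = (cls == CellClass.PHLOEM_PARENCHYMA.value).to_numpy() & inside
        for idx in out.index[to_xylem]:
            changes.append((out.at[idx, "cell_id"], out.at[idx, "class"],
                            CellClass.XYLEM_VESSEL_PARENCHYMA.value))
        out.loc[to_xylem, "class"] = CellClass.XYLEM_VESSEL_PARENCHYMA.value

    log = pd.DataFrame(changes, columns=["cell_id", "old_class", "new_class"])
    return out, log


def run_qc(table: pd.DataFrame, masks: MaskPair, bidirectional: bool = True):
    """filter_outside followed by correct_xylem; returns (table, report)."""
    kept, dropped = filter_outside(table, masks)
    if "class" in kept:
        corrected, log = correct_xylem(kept, masks, bidirectional=bidirectional)
    else:
        corrected, log = kept, pd.DataFrame(
            columns=["cell_id", "old_class", "new_class"])
    return corrected, {"dropped_ids": dropped, "change_log": log}
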