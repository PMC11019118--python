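"""Ratiometric quantification for CaLexA calcium and mito-roGFP redox imaging.

CaLexA: per-cell signal is (GFP/background on that slice)/(RFP/background on
that slice); per-brain summaries average the cells of one class (l-LNv and
s-LNv are never pooled).  roGFP: a per-slice automatic intensity threshold
(Otsu on the 488 channel by default, with an upper cap excluding saturating
trachea-like structures) selects mitochondrial pixels; the brain's redox
ratio is mean(405)/mean(488) within the mask, normalized per imaging run to
the average ratio of that run's control brains pooled across timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .synth import ImageStack

__all__ = [
    "ROIRecord",
    "CalexaBrainSummary",
    "RoGFPResult",
    "calexa_cell_signal",
    "calexa_brain_summary",
    "rogfp_mask",
    "rogfp_brain_ratio",
    "normalize_rogfp_run",
]

CELL_CLASSES = ("l-LNv", "s-LNv")


@dataclass
class ROIRecord:
    brain_id: str
    cell_class: str
    slice_index: int
    gfp: float
    rfp: float
    bg_gfp: float
    bg_rfp: float
    genotype: str = ""
    zt: float = 0.0

    def __post_init__(self) -> None:
        if self.cell_class not in CELL_CLASSES:
            raise ValueError(f"cell class must be one of {CELL_CLASSES}")
        if min(self.gfp, self.rfp, self.bg_gfp, self.bg_rfp) < 0:
            raise ValueError("intensities must be nonnegative")


@dataclass
class CalexaBrainSummary:
    brain_id: str
    cell_class: str
    mean_ratio: float   # A.U.
    n_cells: int


@dataclass
class RoGFPResult:
    brain_id: str
    run_id: str
    mask_pixels: int
    raw_ratio: float
    normalized_ratio: float = float("nan")
    is_control: bool = False


def calexa_cell_signal(record: ROIRecord) -> float:
    """(GFP/bg_GFP) / (RFP/bg_RFP) for one hand-drawn cell ROI."""
    if record.bg_gfp <= 0 or record.bg_rfp <= 0:
        raise ValueError(f"{record.brain_id}: background must be positive")
    if record.rfp <= 0:
        raise ValueError(f"{record.brain_id}: RFP must be positive")
    return (record.gfp / record.bg_gfp) / (record.rfp / record.bg_rfp)


def calexa_brain_summary(records: list[ROIRecord], cell_class: str) -> CalexaBrainSummary:
    """Mean per-cell ratio over one brain's cells of one class."""
    if cell_class not in CELL_CLASSES:
        raise ValueError(f"cell class must be one of {CELL_CLASSES}")
    brains = {r.brain_id for r in records}
    if len(brains) != 1:
        raise ValueError("records must come from a single brain")
    sel = [r for r in records if r.cell_class == cell_class]
    if not sel:
        raise ValueError(f"no {cell_class} cells for brain {brains.pop()}")
    ratios = [calexa_cell_signal(r) for r in sel]
    return CalexaBrainSummary(
        brain_id=sel[0].brain_id,
        cell_class=cell_class,
        mean_ratio=float(np.mean(ratios)),
        n_cells=len(sel),
    )


def rogfp_mask(stack: ImageStack, upper_cap: int = 250,
               method: str = "otsu") -> np.ndarray:
    """Per-slice foreground mask on the 488 channel.

    Pixels above the slice's Otsu threshold and below ``upper_cap`` in both
    channels are kept (the cap excludes saturating trachea-like signal).
    Deterministic; raises if the final mask is empty.
    """
    if method != "otsu":
        raise ValueError("only the 'otsu' method is implemented")
    ch488 = stack.ch488
    if ch488.size == 0:
        raise ValueError("empty stack")
    mask = np.zeros(ch488.shape, dtype=bool)
    for k in range(ch488.shape[0]):
        sl = ch488[k]
        if sl.min() == sl.max():
            continue  # flat slice: nothing to segment
        thr = threshold_otsu(sl)
        mask[k] = sl > thr
    mask &= (stack.ch488 < upper_cap) & (stack.ch405 < upper_cap)
    if not mask.any():
        raise ValueError(f"empty mask for brain {stack.brain_id}")
    return mask


def rogfp_brain_ratio(stack: ImageStack, mask: np.ndarray,
                      is_control: bool = False) -> RoGFPResult:
    """Raw redox ratio mean(405)/mean(488) within the mask."""
    if not np.any(mask):
        raise ValueError("mask is empty")
    m488 = float(stack.ch488[mask].mean())
    if m488 == 0:
        raise ValueError(f"zero mean 488 signal for brain {stack.brain_id}")
    m405 = float(stack.ch405[mask].mean())
    return RoGFPResult(
        brain_id=stack.brain_id,
        run_id=stack.run_id,
        mask_pixels=int(mask.sum()),
        raw_ratio=m405 / m488,
        is_control=is_control,
    )


def normalize_rogfp_run(results: list[RoGFPResult],
                        control_brain_ids: set[str] | list[str]) -> list[RoGFPResult]:
    """Divide every brain's raw ratio by the mean raw ratio of its run's
    control brains (pooled across timepoints); runs normalized independently."""
    controls = set(control_brain_ids)
    runs = sorted({r.run_id for r in results})
    out: list[RoGFPResult] = []
    for run in runs:
        in_run = [r for r in results if r.run_id == run]
        ctrl = [r.raw_ratio for r in in_run if r.brain_id in controls]
        if not ctrl:
            raise ValueError(f"run {run!r} has no control brains")
        denom = float(np.mean(ctrl))
        for r in in_run:
            out.append(RoGFPResult(
                brain_id=r.brain_id, run_id=r.run_id,
                mask_pixels=r.mask_pixels, raw_ratio=r.raw_ratio,
                normalized_ratio=r.raw_ratio / denom,
                is_control=r.brain_id in controls,
            ))
    return out
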