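"""Tumor/stroma compartment masks and chromogen scoring.

Given a region of interest drawn around the tumor, and the epithelium
(DAB-positive) mask transferred from the registered serial section, the
tissue inside the ROI splits into two disjoint compartments:

    tumor  = DAB mask AND ROI
    stroma = ROI AND NOT tumor

The chromogenic ISH signal is then summarised per compartment. With
"intensity" defined as blue-chromogen optical density, the headline score

    TBS = blue_area_stroma x mean_blue_od_stroma

is algebraically the integrated blue OD over chromogen-positive stromal
pixels, which is linear in the amount of precipitated chromogen
(Beer-Lambert). TBT is the same quantity in the tumor compartment, and TSA
is the total stroma area. Areas are in pixels; multiply by the squared
physical pixel size for um^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import label

from .stains import BinaryMask, as_mask_array

__all__ = [
    "CompartmentMasks",
    "ScorePanel",
    "OverlapStats",
    "build_compartments",
    "compute_scores",
    "mask_overlap",
]


@dataclass
class CompartmentMasks:
    """ROI / tumor / stroma masks, all in ISH-image coordinates.

    Invariants (checked on construction): tumor is a subset of the ROI,
    stroma is exactly ROI minus tumor.
    """

    roi: BinaryMask
    tumor: BinaryMask
    stroma: BinaryMask

    def __post_init__(self) -> None:
        r, t, s = (as_mask_array(m) for m in (self.roi, self.tumor, self.stroma))
        if not (r.shape == t.shape == s.shape):
            raise ValueError("compartment masks must share one shape")
        if np.any(t & ~r):
            raise ValueError("tumor mask extends outside the ROI")
        if np.any(s != (r & ~t)):
            raise ValueError("stroma must equal roi AND NOT tumor")


@dataclass
class ScorePanel:
    """Compartment chromogen scores: areas, mean ODs and their products."""

    blue_area_stroma: float
    mean_blue_od_stroma: float
    tbs: float
    blue_area_tumor: float
    mean_blue_od_tumor: float
    tbt: float
    tsa: float
    negative_stroma_area: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class OverlapStats:
    dice: float
    frac_a_in_b: float
    frac_b_in_a: float


def build_compartments(roi, dab_mask_warped, min_object_area: int = 0) -> CompartmentMasks:
    """Split the ROI into tumor (warped DAB mask) and stroma compartments.

    ``min_object_area`` optionally removes connected tumor components
    smaller than that many pixels (default 0: no morphological cleanup).
    """
    r = as_mask_array(roi)
    d = as_mask_array(dab_mask_warped)
    if r.shape != d.shape:
        raise ValueError("ROI and DAB mask shapes differ")
    if not r.any():
        raise ValueError("empty ROI")
    tumor = d & r
    if min_object_area > 0 and tumor.any():
        labels, n = label(tumor)
        counts = np.bincount(labels.ravel())
        keep = np.flatnonzero(counts >= min_object_area)
        keep = keep[keep != 0]
        tumor = np.isin(labels, keep)
    stroma = r & ~tumor
    return CompartmentMasks(BinaryMask(r), BinaryMask(tumor), BinaryMask(stroma))


def compute_scores(blue_od: np.ndarray, blue_mask, comp: CompartmentMasks) -> ScorePanel:
    """Score the blue-chromogen map within the tumor and stroma compartments.

    The mean OD over an empty positive set is defined as 0, so TBS (TBT) is
    0 exactly when the compartment holds no chromogen-positive pixel.
    """
    od = np.asarray(blue_od, dtype=float)
    pos = as_mask_array(blue_mask)
    stroma = as_mask_array(comp.stroma)
    tumor = as_mask_array(comp.tumor)
    if not (od.shape == pos.shape == stroma.shape):
        raise ValueError("blue map, blue mask and compartments must share one shape")

    def _compartment(compartment: np.ndarray) -> tuple[float, float, float]:
        sel = pos & compartment
        area = float(sel.sum())
        mean_od = float(od[sel].mean()) if area else 0.0
        return area, mean_od, area * mean_od

    a_s, m_s, tbs = _compartment(stroma)
    a_t, m_t, tbt = _compartment(tumor)
    tsa = float(stroma.sum())
    return ScorePanel(
        blue_area_stroma=a_s,
        mean_blue_od_stroma=m_s,
        tbs=tbs,
        blue_area_tumor=a_t,
        mean_blue_od_tumor=m_t,
        tbt=tbt,
        tsa=tsa,
        negative_stroma_area=tsa - a_s,
    )


def mask_overlap(a, b) -> OverlapStats:
    """Dice and directed overlap fractions between two binary masks.

    Conventions: Dice = 0 when both masks are empty; a directed fraction
    with an empty numerator mask is 0.
    """
    ma, mb = as_mask_array(a), as_mask_array(b)
    if ma.shape != mb.shape:
        raise ValueError("mask shapes differ")
    na, nb = int(ma.sum()), int(mb.sum())
    inter = int((ma & mb).sum())
    dice = 2.0 * inter / (na + nb) if (na + nb) else 0.0
    return OverlapStats(
        dice=dice,
        frac_a_in_b=inter / na if na else 0.0,
        frac_b_in_a=inter / nb if nb else 0.0,
    )
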