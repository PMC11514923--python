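"""Subtraction-map biomarkers of gadolinium leakage.

Two voxelwise subtraction maps summarize blood-brain-barrier dysfunction
per subject:

* ``ni`` — noncontrast minus interictal qT1: interictal enhancement
  (gadolinium still present between seizures shortens T1, so leakage
  shows up as a positive difference);
* ``ip`` — interictal minus postictal qT1: peri-ictal enhancement
  beyond the interictal level.

Because the vascular gadolinium concentration at scan time varies with
injection-to-scan latency and kinetics, each map is divided by its mean
over the superior sagittal sinus (SSS) — an internal vascular reference,
as used for the vascular input function in dynamic contrast-enhanced
MRI.  The normalized biomarker is a dimensionless fraction of the
vascular enhancement, comparable across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantom import BILATERAL_ROIS, ROILabelMap
from .relaxometry import QT1Volume

__all__ = [
    "DeltaQT1Map",
    "NormalizationError",
    "compute_delta",
    "normalize_by_sss",
    "roi_readout",
    "DEFAULT_READOUT_ROIS",
]

#: ROIs read out by default; bilateral names pool left and right voxels.
DEFAULT_READOUT_ROIS = ("cortex", "hippocampus", "amygdala", "piriform")

#: Which session goes first/second in each subtraction.
KIND_OPERANDS = {
    "ni": ("noncontrast", "interictal"),
    "ip": ("interictal", "postictal"),
}


class NormalizationError(RuntimeError):
    """No measurable vascular contrast in the SSS reference."""


@dataclass
class DeltaQT1Map:
    """A voxelwise qT1 subtraction map with its normalization state.

    ``data`` is in milliseconds before normalization and dimensionless
    after; ``sss_mean`` records the reference value used (ms).
    """

    data: np.ndarray
    kind: str
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    mask: np.ndarray | None = None
    normalized: bool = False
    sss_mean: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in KIND_OPERANDS:
            raise ValueError(f"kind must be one of {sorted(KIND_OPERANDS)}, got {self.kind!r}")
        self.data = np.asarray(self.data, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.data)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape:
            raise ValueError("mask and data must share shape")


def compute_delta(first: QT1Volume, second: QT1Volume, kind: str) -> DeltaQT1Map:
    """Voxelwise subtraction ``first - second`` for the given map kind.

    ``kind='ni'`` expects (noncontrast, interictal); ``kind='ip'``
    expects (interictal, postictal).  Session labels and grids are
    checked; the valid mask is the AND of the input masks.
    """
    if kind not in KIND_OPERANDS:
        raise ValueError(f"kind must be one of {sorted(KIND_OPERANDS)}, got {kind!r}")
    want_first, want_second = KIND_OPERANDS[kind]
    if first.session != want_first or second.session != want_second:
        raise ValueError(
            f"kind {kind!r} subtracts {want_first} - {want_second}, "
            f"got {first.session} - {second.session}"
        )
    if first.t1_map.shape != second.t1_map.shape:
        raise ValueError("volumes must share one grid (shape mismatch)")
    if not np.allclose(first.affine, second.affine):
        raise ValueError("volumes must share one grid (affine mismatch)")
    mask = first.mask & second.mask
    data = np.where(mask, first.t1_map - second.t1_map, np.nan)
    return DeltaQT1Map(data, kind, first.affine.copy(), mask)


def normalize_by_sss(
    dmap: DeltaQT1Map,
    labels: ROILabelMap,
    floor_fraction: float = 1e-6,
) -> DeltaQT1Map:
    """Divide the map by its mean over the SSS reference ROI.

    The normalized SSS mean is 1 by construction.  Raises
    ``NormalizationError`` when |SSS mean| falls below ``floor_fraction``
    of the map's dynamic range — i.e. when there is no measurable
    vascular contrast to normalize against.
    """
    if dmap.normalized:
        raise ValueError("map is already normalized")
    sss = labels.mask("sss") & dmap.mask
    if not sss.any():
        raise NormalizationError("SSS reference ROI is empty within the valid mask")
    sss_mean = float(np.mean(dmap.data[sss]))
    valid = dmap.data[dmap.mask]
    dyn = float(np.ptp(valid)) if valid.size else 0.0
    floor = floor_fraction * dyn if dyn > 0 else floor_fraction
    if not np.isfinite(sss_mean) or abs(sss_mean) < floor:
        raise NormalizationError(
            f"SSS mean delta-qT1 {sss_mean!r} below floor {floor!r}: "
            "no measurable vascular contrast"
        )
    return DeltaQT1Map(
        dmap.data / sss_mean, dmap.kind, dmap.affine.copy(), dmap.mask.copy(),
        normalized=True, sss_mean=sss_mean,
    )


def _resolve_roi_masks(
    labels: ROILabelMap, roi: str, hemisphere: str | None
) -> np.ndarray:
    """Mask for one readout ROI, optionally restricted to one hemisphere.

    The phantom's cortex label already excludes hippocampus and
    amygdala, mirroring how the whole-cortex mask is defined.  For the
    unilateral cortex we split the bilateral label at the midline of the
    first (left-right) axis.
    """
    if hemisphere not in (None, "left", "right"):
        raise ValueError(f"hemisphere must be None, 'left' or 'right', got {hemisphere!r}")
    if roi in BILATERAL_ROIS and hemisphere is not None:
        return labels.mask(f"{roi}_{hemisphere[0]}")
    m = labels.mask(roi)
    if hemisphere is not None:  # split a bilateral label at the midline
        half = labels.data.shape[0] // 2
        side = np.zeros_like(m)
        if hemisphere == "left":
            side[:half] = True
        else:
            side[half:] = True
        m = m & side
    return m


def roi_readout(
    dmap: DeltaQT1Map,
    labels: ROILabelMap,
    rois: tuple[str, ...] = DEFAULT_READOUT_ROIS,
    hemisphere: str | None = None,
    subject_id: str | None = None,
    erode_voxels: int = 0,
) -> pd.DataFrame:
    """Mean and sample SD of the map over each requested ROI.

    Only valid voxels contribute; the SD uses the n-1 (sample)
    definition.  ``erode_voxels`` shrinks each ROI mask before readout:
    subtraction maps built from resampled sessions carry trilinear
    partial-volume mixing in the outermost voxel shell of every ROI, and
    eroding by one voxel keeps that shell out of the summary (the SSS
    normalization reference is handled separately and is never eroded).
    An ROI with no valid voxels yields NaN mean/SD with a warning rather
    than a silent zero.  Returns a tidy frame with one row per ROI:
    subject, kind, roi, hemisphere, mean, sd, n_voxels.
    """
    from scipy import ndimage

    rows = []
    for roi in rois:
        m = _resolve_roi_masks(labels, roi, hemisphere)
        if erode_voxels > 0:
            m = ndimage.binary_erosion(m, iterations=erode_voxels)
        m = m & dmap.mask
        n = int(m.sum())
        if n == 0:
            warnings.warn(f"ROI {roi!r} has no valid voxels; recording missing value")
            mean, sd = np.nan, np.nan
        else:
            vals = dmap.data[m]
            mean = float(np.mean(vals))
            sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
        rows.append(
            {
                "subject": subject_id,
                "kind": dmap.kind,
                "roi": roi,
                "hemisphere": hemisphere or "both",
                "mean": mean,
                "sd": sd,
                "n_voxels": n,
                "normalized": dmap.normalized,
                "sss_mean": dmap.sss_mean,
            }
        )
    return pd.DataFrame(rows)
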