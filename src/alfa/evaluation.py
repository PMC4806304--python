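"""Segmentation agreement metrics and cohort error-localisation maps.

Agreement between an automatic mask A and a reference mask M is summarised by
the Dice coefficient (percent), the Hausdorff distance (mm, maximum
surface-to-surface distance), and sensitivity/specificity of the voxel-wise
confusion counts.  Cohort-level error structure is visualised through
projection maps: per-voxel false-positive / false-negative frequencies across
subjects in a common space, projected onto the axial, coronal and sagittal
planes on a 0-1 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .registration import Transform, apply_transform
from .volumes import BinaryMask

__all__ = [
    "EvalReport",
    "ProjectionMaps",
    "dice",
    "hausdorff",
    "sensitivity_specificity",
    "volume_ml",
    "evaluate_case",
    "projection_maps",
    "bland_altman",
]


@dataclass
class EvalReport:
    """Per-case agreement summary between an automatic and a reference mask."""

    case_id: str
    dice_pct: float
    hausdorff_mm: float
    sensitivity_pct: float | None
    specificity_pct: float | None
    tp: int
    tn: int
    fp: int
    fn: int
    auto_volume_ml: float
    ref_volume_ml: float


@dataclass
class ProjectionMaps:
    """FP/FN frequency maps projected on the three anatomical planes, in [0,1]."""

    fp_axial: np.ndarray
    fp_coronal: np.ndarray
    fp_sagittal: np.ndarray
    fn_axial: np.ndarray
    fn_coronal: np.ndarray
    fn_sagittal: np.ndarray
    n_subjects: int


def _check_same_grid(a: BinaryMask, m: BinaryMask) -> None:
    if a.shape != m.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {m.shape}")


def dice(a: BinaryMask, m: BinaryMask) -> float:
    """Dice overlap 2|A∩M| / (|A|+|M|), as a percentage.

    Two empty masks agree perfectly by convention (returns 100.0).
    """
    _check_same_grid(a, m)
    na, nm = int(a.data.sum()), int(m.data.sum())
    if na + nm == 0:
        return 100.0
    inter = int(np.logical_and(a.data, m.data).sum())
    return 200.0 * inter / (na + nm)


def _surface(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with at least one six-connected background neighbour
    (voxels on the array border count as surface)."""
    structure = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~eroded


def hausdorff(a: BinaryMask, m: BinaryMask) -> float:
    """Maximum surface-to-surface Euclidean distance between two masks, in mm."""
    _check_same_grid(a, m)
    if not a.data.any() or not m.data.any():
        raise ValueError("Hausdorff distance undefined for an empty mask")
    sa = _surface(a.data)
    sm = _surface(m.data)
    spacing = a.spacing
    dt_to_m = ndimage.distance_transform_edt(~sm, sampling=spacing)
    dt_to_a = ndimage.distance_transform_edt(~sa, sampling=spacing)
    return float(max(dt_to_m[sa].max(), dt_to_a[sm].max()))


def sensitivity_specificity(a: BinaryMask, m: BinaryMask
                            ) -> tuple[float | None, float | None, dict]:
    """Sensitivity TP/(TP+FN) and specificity TN/(TN+FP) vs reference ``m``.

    A rate whose denominator is zero (reference all-negative or all-positive)
    is reported as ``None`` rather than 0.  Confusion counts are returned as a
    dict with keys tp/tn/fp/fn.
    """
    _check_same_grid(a, m)
    A, M = a.data, m.data
    tp = int(np.sum(A & M))
    tn = int(np.sum(~A & ~M))
    fp = int(np.sum(A & ~M))
    fn = int(np.sum(~A & M))
    sen = 100.0 * tp / (tp + fn) if (tp + fn) > 0 else None
    spe = 100.0 * tn / (tn + fp) if (tn + fp) > 0 else None
    return sen, spe, {"tp": tp, "tn": tn, "fp": fp, "fn": fn}


def volume_ml(mask: BinaryMask) -> float:
    """Mask volume in millilitres: voxel count x voxel volume (mm^3) / 1000."""
    return float(mask.data.sum()) * mask.voxel_volume_mm3 / 1000.0


def evaluate_case(auto: BinaryMask, ref: BinaryMask, case_id: str = "") -> EvalReport:
    """All per-case metrics in one report."""
    sen, spe, counts = sensitivity_specificity(auto, ref)
    try:
        h = hausdorff(auto, ref)
    except ValueError:
        h = math.nan
    return EvalReport(case_id=case_id or auto.id, dice_pct=dice(auto, ref),
                      hausdorff_mm=h, sensitivity_pct=sen, specificity_pct=spe,
                      **counts, auto_volume_ml=volume_ml(auto),
                      ref_volume_ml=volume_ml(ref))


def projection_maps(cases: Sequence[tuple[BinaryMask, BinaryMask, Transform | None]],
                    projection: str = "max") -> ProjectionMaps:
    """Cohort false-positive / false-negative localisation maps.

    Each case is (automatic mask, reference mask, transform to a common space
    or ``None`` for identity).  Per-case FP = A∧¬M and FN = M∧¬A maps are
    warped to the common space, averaged across cases into per-voxel
    frequencies in [0, 1], then projected along each anatomical axis —
    by maximum intensity (default, preserves the 0-1 scale) or by mean.
    """
    if len(cases) == 0:
        raise ValueError("need at least one case")
    if projection not in ("max", "mean"):
        raise ValueError("projection must be 'max' or 'mean'")
    fp_sum = fn_sum = None
    for auto, ref, t in cases:
        _check_same_grid(auto, ref)
        fp = auto.with_data(auto.data & ~ref.data)
        fn = ref.with_data(ref.data & ~auto.data)
        if t is not None:
            fp = apply_transform(t, fp, auto)
            fn = apply_transform(t, fn, auto)
        if fp_sum is None:
            fp_sum = fp.data.astype(np.float64)
            fn_sum = fn.data.astype(np.float64)
        else:
            fp_sum += fp.data
            fn_sum += fn.data
    n = len(cases)
    fp_freq = fp_sum / n
    fn_freq = fn_sum / n
    proj = (lambda f, ax: f.max(axis=ax)) if projection == "max" \
        else (lambda f, ax: f.mean(axis=ax))
    # axial: collapse z (axis 2); coronal: collapse y (axis 1); sagittal: x (0)
    return ProjectionMaps(
        fp_axial=proj(fp_freq, 2), fp_coronal=proj(fp_freq, 1),
        fp_sagittal=proj(fp_freq, 0),
        fn_axial=proj(fn_freq, 2), fn_coronal=proj(fn_freq, 1),
        fn_sagittal=proj(fn_freq, 0), n_subjects=n)


def bland_altman(pairs: Sequence[tuple[float, float]]
                 ) -> tuple[float, tuple[float, float], np.ndarray]:
    """Bland–Altman agreement of paired volumes (auto, reference), in ml.

    Returns the mean difference auto-ref, the 95% limits of agreement
    (mean ± 1.96 x sample SD), and the per-pair differences.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two pairs")
    arr = np.asarray(pairs, dtype=np.float64)
    diffs = arr[:, 0] - arr[:, 1]
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return mean, (mean - 1.96 * sd, mean + 1.96 * sd), diffs
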