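"""Segmentation evaluation: Dice coefficient and 95th-percentile Hausdorff.

Dice is the voxelwise overlap 2·TP / (2·TP + FP + FN) over the whole 3D
volume.  HD95 pools the two directed nearest-surface distance sets

    D = D(P→G) ∪ D(G→P),   D(P→G) = { min_g d(p, g) : p ∈ P }

between the surface-point sets P, G of prediction and ground truth, and
takes the 95th percentile of the pooled set — one percentile of the union,
which makes it symmetric by construction and robust to outlier surface
points (the exact Hausdorff distance is the max of the two directed
maxima).  Surfaces are foreground voxels with at least one background
6-neighbor; voxels on the volume border count out-of-bounds neighbors as
background.  Distances are 3D Euclidean in voxel units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import UndefinedMetricError, ValidationError
from .indices import PERCENTILE_RULES
from .mask_io import LabelVolume

STRUCTURES = ("PV", "LA", "PV_LA")

_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass
class MetricResult:
    """Dice and HD95 for one structure of one predicted/truth volume pair."""

    case_id: str
    structure: str
    dice: float | None
    hd95: float | None
    tp: int
    fp: int
    fn: int

    @property
    def dice_defined(self) -> bool:
        return self.dice is not None

    @property
    def hd95_defined(self) -> bool:
        return self.hd95 is not None


def _masks(pred: LabelVolume, truth: LabelVolume, structure: str):
    if structure not in STRUCTURES:
        raise ValidationError(f"structure must be one of {STRUCTURES}; got {structure!r}")
    if pred.shape != truth.shape:
        raise ValidationError(
            f"shape mismatch: prediction {pred.shape} vs truth {truth.shape}"
        )
    return pred.structure_mask(structure), truth.structure_mask(structure)


def dice_coefficient(pred: LabelVolume, truth: LabelVolume, structure: str = "PV_LA") -> float:
    """Dice = 2·TP / (2·TP + FP + FN); undefined when both masks are empty."""
    p, g = _masks(pred, truth, structure)
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    if tp + fp + fn == 0:
        raise UndefinedMetricError(
            f"{structure}: both masks empty, Dice is 0/0 (undefined)"
        )
    return 2 * tp / (2 * tp + fp + fn)


def surface_points(mask: np.ndarray) -> np.ndarray:
    """(n, 3) coordinates of foreground voxels with a background 6-neighbor."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("surface of an empty mask is undefined")
    interior = ndimage.binary_erosion(mask, structure=_FACE_STRUCTURE, border_value=0)
    return np.argwhere(mask & ~interior)


def hd95(
    pred: LabelVolume, truth: LabelVolume, structure: str = "PV_LA", rule: str = "linear"
) -> float:
    """95th percentile of the pooled directed nearest-surface distances."""
    d = _pooled_surface_distances(pred, truth, structure)
    return float(np.percentile(d, 95, method=PERCENTILE_RULES[rule]))


def hausdorff_distance(pred: LabelVolume, truth: LabelVolume, structure: str = "PV_LA") -> float:
    """Exact (max-of-directed-maxima) Hausdorff distance; upper-bounds HD95."""
    d_pg, d_gp = _directed_surface_distances(pred, truth, structure)
    return float(max(d_pg.max(), d_gp.max()))


def _directed_surface_distances(pred, truth, structure):
    p, g = _masks(pred, truth, structure)
    if not p.any() or not g.any():
        raise UndefinedMetricError(
            f"{structure}: empty mask (pred empty={not p.any()}, truth empty={not g.any()}); "
            "surface distances undefined"
        )
    sp = surface_points(p).astype(float)
    sg = surface_points(g).astype(float)
    d_pg, _ = cKDTree(sg).query(sp, k=1)
    d_gp, _ = cKDTree(sp).query(sg, k=1)
    return d_pg, d_gp


def _pooled_surface_distances(pred, truth, structure):
    d_pg, d_gp = _directed_surface_distances(pred, truth, structure)
    return np.concatenate([d_pg, d_gp])


def evaluate_pair(
    pred: LabelVolume, truth: LabelVolume, case_id: str | None = None
) -> list[MetricResult]:
    """Dice + HD95 for PV, LA and the PV∪LA aggregate of one volume pair.

    Undefined metrics (empty masks) are flagged as ``None`` on the result
    rather than aborting, so batch evaluation over a cohort survives a
    model that misses a structure entirely.
    """
    case = case_id if case_id is not None else (truth.case_id or pred.case_id)
    results = []
    for structure in STRUCTURES:
        p, g = _masks(pred, truth, structure)
        tp = int(np.count_nonzero(p & g))
        fp = int(np.count_nonzero(p & ~g))
        fn = int(np.count_nonzero(~p & g))
        dice = 2 * tp / (2 * tp + fp + fn) if tp + fp + fn else None
        try:
            h = hd95(pred, truth, structure)
        except UndefinedMetricError:
            h = None
        results.append(
            MetricResult(case_id=case, structure=structure, dice=dice, hd95=h, tp=tp, fp=fp, fn=fn)
        )
    return results


def results_table(results: list[MetricResult], model_name: str = "", group: str = "") -> pd.DataFrame:
    """Flatten MetricResults into the batch-report layout."""
    return pd.DataFrame(
        [
            {
                "case_id": r.case_id,
                "model_name": model_name,
                "group": group,
                "structure": r.structure,
                "dice": np.nan if r.dice is None else r.dice,
                "hd95": np.nan if r.hd95 is None else r.hd95,
                "tp": r.tp,
                "fp": r.fp,
                "fn": r.fn,
            }
            for r in results
        ]
    )


def group_metric_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per (model, group) summary with mDice/HD95 reported two ways.

    ``mdice_structures`` averages the PV and LA Dice per video before the
    group mean; ``mdice_aggregate`` uses the PV∪LA-aggregate Dice.  Both
    appear because per-video "mean Dice" can reasonably denote either.
    """
    rows = []
    for (model, group), sub in table.groupby(["model_name", "group"], dropna=False):
        per_structure = sub[sub.structure.isin(["PV", "LA"])]
        agg = sub[sub.structure == "PV_LA"]
        rows.append(
            {
                "model_name": model,
                "group": group,
                "n_videos": agg.case_id.nunique(),
                "mdice_structures": per_structure.groupby("case_id").dice.mean().mean(),
                "mdice_aggregate": agg.dice.mean(),
                "hd95_aggregate": agg.hd95.mean(),
            }
        )
    return pd.DataFrame(rows)
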