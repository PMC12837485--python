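"""PV-LA connection indices: PLD (distance) and PLA (angle).

Both indices quantify the spatial relationship between the pulmonary veins
(PV) and the left atrium (LA) on a labeled sweep volume, slice by slice
along the depth axis, restricted to the slice-support set

    K = { k : slice k contains at least one PV pixel and one LA pixel }.

**PLD** (PV-LA distance, pixels).  For each k in K let d_k be the minimum
in-plane Euclidean distance over all PV×LA pixel pairs.  Let t_q be the
bottom-q% quantile of the distance set D = {d_k}, and D_q = {d in D :
d <= t_q}.  Then PLD is the arithmetic mean of D_q.  Because PV and LA
labels are mutually exclusive on the grid, d_k >= 1 always, so the minimum
PLD is exactly 1.00 — the signature of a connected PV-LA junction; larger
values mean the structures have diverged (the TAPVC geometry).

**PLA** (PV-LA angle, degrees).  For each k in K let G_P and G_L be the
centroids of the PV and LA pixel sets and u the major-axis direction of
the moment-equivalent ellipse of the PV region.  The raw angle theta
between (G_L - G_P) and u lies in [0, 180°]; it is folded to
theta~ = min(theta, 180° - theta) in [0, 90°] because u is an axis, not a
ray.  PLA is the mean of theta~ over the non-degenerate slices of K.
Slices where the PV is isotropic (no unique major axis) or the centroids
coincide are excluded and reported with reasons.

All distances are isotropic in-plane pixel units; slice indices are
0-based internally and 1-based in result records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import NoMeasurableAngleError, NoSharedSliceError, ValidationError
from .mask_io import LabelVolume

#: percentile conventions accepted for t_q (numpy method names)
PERCENTILE_RULES = {"linear": "linear", "nearest": "nearest"}

DEGENERATE_EIGENVALUE_RTOL = 1e-9
CENTROID_COINCIDENCE_TOL = 1e-9


@dataclass
class SlicePair:
    """PV and LA foreground pixel coordinates of one depth slice."""

    k: int  # 0-based depth index
    pv_pixels: np.ndarray  # (n, 2) int (row, col)
    la_pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pv_pixels = np.atleast_2d(np.asarray(self.pv_pixels, dtype=np.int64))
        self.la_pixels = np.atleast_2d(np.asarray(self.la_pixels, dtype=np.int64))


@dataclass
class PLDResult:
    pld: float
    q: float
    t_q: float
    distances: list[tuple[int, float]]  # (1-based k, d_k) for every k in K
    n_used: int
    percentile_rule: str = "linear"
    case_id: str = ""


@dataclass
class PLAResult:
    pla: float
    angles: list[tuple[int, float]]  # (1-based k, folded angle) for used slices
    n_used: int
    excluded: list[tuple[int, str]] = field(default_factory=list)
    case_id: str = ""


def slice_support(volume: LabelVolume, merge_vein: bool = True) -> list[SlicePair]:
    """Slices containing at least one PV pixel and one LA pixel, ascending k."""
    pv = volume.structure_mask("PV", merge_vein=merge_vein)
    la = volume.structure_mask("LA", merge_vein=merge_vein)
    pairs = []
    for k in range(volume.n_slices):
        if pv[k].any() and la[k].any():
            pairs.append(
                SlicePair(k=k, pv_pixels=np.argwhere(pv[k]), la_pixels=np.argwhere(la[k]))
            )
    return pairs


def min_slice_distance(pair: SlicePair) -> float:
    """Minimum in-plane Euclidean distance over all PV×LA pixel pairs."""
    if pair.pv_pixels.size == 0 or pair.la_pixels.size == 0:
        raise ValidationError(f"slice {pair.k}: both PV and LA must be non-empty")
    tree = cKDTree(pair.la_pixels.astype(float))
    d, _ = tree.query(pair.pv_pixels.astype(float), k=1)
    return float(np.min(d))


def quantile_subset(
    distances, q: float, rule: str = "linear", return_threshold: bool = False
):
    """Subset D_q = {d in D : d <= t_q} where t_q is the bottom-q% quantile.

    Inclusion is ``d <= t_q`` (so a constant set is returned whole for any
    q, and q = 100 returns everything).  ``rule`` selects the percentile
    convention used for t_q; the default is linear interpolation between
    order statistics.
    """
    distances = list(distances)
    if not distances:
        raise ValidationError("distance set is empty")
    if not 0 < q <= 100:
        raise ValidationError(f"q must be in (0, 100]; got {q}")
    if rule not in PERCENTILE_RULES:
        raise ValidationError(f"unknown percentile rule {rule!r}; options: {sorted(PERCENTILE_RULES)}")
    t_q = float(np.percentile(distances, q, method=PERCENTILE_RULES[rule]))
    subset = [d for d in distances if d <= t_q]
    if return_threshold:
        return subset, t_q
    return subset


def compute_pld(
    volume: LabelVolume,
    q: float = 100.0,
    rule: str = "linear",
    merge_vein: bool = True,
) -> PLDResult:
    """PLD: mean of the bottom-q% per-slice minimum PV-LA distances."""
    pairs = slice_support(volume, merge_vein=merge_vein)
    if not pairs:
        raise NoSharedSliceError(
            volume.case_id,
            _support_range(volume, "PV", merge_vein),
            _support_range(volume, "LA", merge_vein),
        )
    per_slice = [(p.k + 1, min_slice_distance(p)) for p in pairs]
    subset, t_q = quantile_subset(
        [d for _, d in per_slice], q, rule=rule, return_threshold=True
    )
    return PLDResult(
        pld=float(np.mean(subset)),
        q=float(q),
        t_q=t_q,
        distances=per_slice,
        n_used=len(subset),
        percentile_rule=rule,
        case_id=volume.case_id,
    )


def slice_centroid(pixels: np.ndarray) -> tuple[float, float]:
    """Unweighted centroid (row, col) of a pixel set."""
    pixels = np.atleast_2d(np.asarray(pixels, dtype=float))
    if pixels.size == 0:
        raise ValidationError("cannot take the centroid of an empty pixel set")
    r, c = pixels.mean(axis=0)
    return float(r), float(c)


def major_axis_direction(pixels: np.ndarray) -> np.ndarray | None:
    """Major-axis direction of the moment-equivalent ellipse of a pixel set.

    Returns the unit principal eigenvector (row, col) of the 2×2 second
    central-moment matrix, or ``None`` when the region is degenerate: a
    single pixel, or isotropic moments (equal eigenvalues, hence no unique
    major axis).  The sign of the vector is unspecified — it is an axis.
    """
    pixels = np.atleast_2d(np.asarray(pixels, dtype=float))
    if pixels.size == 0:
        raise ValidationError("cannot orient an empty pixel set")
    if pixels.shape[0] == 1:
        return None
    centered = pixels - pixels.mean(axis=0)
    moments = centered.T @ centered / pixels.shape[0]
    eigvals, eigvecs = np.linalg.eigh(moments)  # ascending
    lam_min, lam_max = float(eigvals[0]), float(eigvals[1])
    if lam_max <= 0 or lam_max <= lam_min * (1 + DEGENERATE_EIGENVALUE_RTOL):
        return None
    v = eigvecs[:, 1]
    return v / np.linalg.norm(v)


def slice_angle(pair: SlicePair) -> tuple[float | None, str | None]:
    """Folded angle between the PV major axis and the PV→LA centroid line.

    Returns ``(angle_degrees, None)`` with the angle in [0, 90], or
    ``(None, reason)`` for a degenerate slice.
    """
    if pair.pv_pixels.size == 0 or pair.la_pixels.size == 0:
        raise ValidationError(f"slice {pair.k}: both PV and LA must be non-empty")
    axis = major_axis_direction(pair.pv_pixels)
    if axis is None:
        return None, "isotropic-pv"
    g_p = np.array(slice_centroid(pair.pv_pixels))
    g_l = np.array(slice_centroid(pair.la_pixels))
    link = g_l - g_p
    norm = np.linalg.norm(link)
    if norm < CENTROID_COINCIDENCE_TOL:
        return None, "coincident-centroids"
    # |cos| folds theta -> min(theta, 180 - theta)
    cos_folded = np.clip(abs(float(np.dot(link / norm, axis))), 0.0, 1.0)
    return float(np.degrees(np.arccos(cos_folded))), None


def compute_pla(volume: LabelVolume, merge_vein: bool = True) -> PLAResult:
    """PLA: mean folded PV-axis/centroid-line angle over non-degenerate slices."""
    pairs = slice_support(volume, merge_vein=merge_vein)
    if not pairs:
        raise NoSharedSliceError(
            volume.case_id,
            _support_range(volume, "PV", merge_vein),
            _support_range(volume, "LA", merge_vein),
        )
    angles: list[tuple[int, float]] = []
    excluded: list[tuple[int, str]] = []
    for p in pairs:
        theta, reason = slice_angle(p)
        if theta is None:
            excluded.append((p.k + 1, reason))
        else:
            angles.append((p.k + 1, theta))
    if not angles:
        raise NoMeasurableAngleError(
            f"case {volume.case_id!r}: every shared slice is degenerate "
            f"({[r for _, r in excluded]})"
        )
    return PLAResult(
        pla=float(np.mean([a for _, a in angles])),
        angles=angles,
        n_used=len(angles),
        excluded=excluded,
        case_id=volume.case_id,
    )


def _support_range(volume: LabelVolume, structure: str, merge_vein: bool):
    mask = volume.structure_mask(structure, merge_vein=merge_vein)
    ks = np.flatnonzero(mask.any(axis=(1, 2)))
    if ks.size == 0:
        return None
    return (int(ks[0]) + 1, int(ks[-1]) + 1)  # 1-based, inclusive
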