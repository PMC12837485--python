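"""Synthetic voxel phantoms of the PV-LA junction geometry.

A phantom emulates the label geometry the indices assume, without any
ultrasound appearance: per slice, the LA is a filled ellipse and the PV an
elongated horizontal bar.  The bar's moment major axis is the column
direction, and the LA ellipse is placed at a configured bearing ``angle``
from the bar centroid, so the per-slice folded PV-axis/centroid-line angle
realizes ``angle`` up to rasterization error.  The nearest PV/LA pixel
pair sits at distance ``gap + 1``: ``gap = 0`` means touching (an
edge-adjacent pair, distance exactly 1 — the normal, connected junction),
positive gaps emulate the diverged TAPVC geometry.  An optional
confluent-vein blob (label 3) is drawn behind (below) the LA, as seen in
TAPVC hearts.

The LA spans every depth slice; the PV (and vein) occupy a centered band
of ``shared_slices`` slices, so the slice-support set K is exactly that
band.  Placement is solved by a small search over the ellipse offset:
candidate positions are rasterized and the actual nearest-pixel distance
measured, because sub-pixel rasterization effects make a closed-form
offset unreliable.  When no candidate yields an exact distance-1 pair for
``gap = 0``, the ellipse is placed minimally overlapping the bar and the
overlap carved out of the LA (PV wins), which guarantees adjacency.

All randomness (boundary jitter, cohort sampling) flows from explicit
seeds; identical config + seed reproduces identical voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.draw import ellipse as draw_ellipse

from .errors import ConfigurationError, ValidationError
from .mask_io import CANONICAL_LABEL_MAP, LA, PV, VEIN, CohortRecord, LabelVolume

_FACE2D = ndimage.generate_binary_structure(2, 1)


@dataclass
class PhantomConfig:
    """Geometry of one synthetic PV-LA volume.

    ``angle`` is the target per-slice folded angle (degrees, [0, 90])
    between the PV bar's major axis and the PV→LA centroid line; ``gap``
    is the in-plane separation in pixels (0 = touching, nearest pair at
    distance 1; g > 0 = nearest pair near g + 1).  ``jitter_sd`` sets the
    per-voxel boundary flip probability (0 = exact geometry).
    """

    shape: tuple[int, int, int] = (12, 96, 96)
    la_center: tuple[float, float] | None = None  # (row, col); None = derived
    la_radii: tuple[float, float] = (13.0, 9.0)
    pv_length: int = 25
    pv_thickness: int = 3
    gap: float = 0.0
    angle: float = 30.0
    shared_slices: int = 8
    vein: bool = False
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gap < 0:
            raise ConfigurationError(f"gap must be >= 0; got {self.gap}")
        if not 0 <= self.angle <= 90:
            raise ConfigurationError(f"angle must be in [0, 90]; got {self.angle}")
        if self.pv_length < 2 or self.pv_thickness < 1:
            raise ConfigurationError(
                f"PV bar needs length >= 2 and thickness >= 1; got "
                f"{self.pv_length}×{self.pv_thickness}"
            )
        if self.pv_thickness >= self.pv_length:
            raise ConfigurationError("PV bar must be elongated: thickness < length")
        if not 1 <= self.shared_slices <= self.shape[0]:
            raise ConfigurationError(
                f"shared_slices={self.shared_slices} must be in [1, depth={self.shape[0]}]"
            )
        if self.jitter_sd < 0:
            raise ConfigurationError("jitter_sd must be >= 0")


@dataclass
class CohortSpec:
    """Generating conditions for a synthetic normal/TAPVC cohort.

    Gap and angle are drawn per case from truncated normal distributions
    given as (mean, sd); sd = 0 gives a constant.  Defaults emulate the
    clinically observed index regimes: normal junctions touch (gap 0) with
    PLA near 38°, TAPVC junctions diverge (PLD ≈ 2.6 ± 0.7 px, i.e. gap
    ≈ 1.6 ± 0.7) with larger, more variable angles and a confluent vein.
    """

    n_normal: int = 6
    n_tapvc: int = 6
    normal_gap: tuple[float, float] = (0.0, 0.0)
    normal_angle: tuple[float, float] = (37.8, 7.72)
    tapvc_gap: tuple[float, float] = (1.64, 0.667)
    tapvc_angle: tuple[float, float] = (55.1, 14.5)
    tapvc_vein: bool = True
    base_config: PhantomConfig = field(default_factory=PhantomConfig)
    master_seed: int = 0

    GAP_CLIP: tuple[float, float] = (0.0, 12.0)
    ANGLE_CLIP: tuple[float, float] = (0.0, 90.0)


def _bar_mask(shape2d, centroid, length, thickness):
    """Horizontal bar whose centroid is the rounded-corner approximation of
    ``centroid``; returns (mask, actual centroid)."""
    h, w = shape2d
    r0 = int(round(centroid[0] - (thickness - 1) / 2))
    c0 = int(round(centroid[1] - (length - 1) / 2))
    if r0 < 0 or c0 < 0 or r0 + thickness > h or c0 + length > w:
        raise ConfigurationError(
            f"PV bar rows [{r0}, {r0 + thickness}) cols [{c0}, {c0 + length}) "
            f"does not fit in slice {shape2d}"
        )
    mask = np.zeros(shape2d, dtype=bool)
    mask[r0 : r0 + thickness, c0 : c0 + length] = True
    g = (r0 + (thickness - 1) / 2, c0 + (length - 1) / 2)
    return mask, g


def _ellipse_mask(shape2d, center, radii):
    h, w = shape2d
    if (
        center[0] - radii[0] < -0.5
        or center[1] - radii[1] < -0.5
        or center[0] + radii[0] > h - 0.5
        or center[1] + radii[1] > w - 0.5
    ):
        raise ConfigurationError(
            f"LA ellipse center {center} radii {radii} does not fit in slice {shape2d}"
        )
    rr, cc = draw_ellipse(center[0], center[1], radii[0], radii[1], shape=shape2d)
    if rr.size == 0:
        raise ConfigurationError(f"LA ellipse at {center} rasterizes to zero pixels")
    mask = np.zeros(shape2d, dtype=bool)
    mask[rr, cc] = True
    return mask


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    pa, pb = np.argwhere(a).astype(float), np.argwhere(b).astype(float)
    d, _ = cKDTree(pb).query(pa, k=1)
    return float(d.min())


def _layout_slice(config: PhantomConfig):
    """Solve the 2D layout shared by every slice of the band.

    Returns (pv_mask, la_mask).  The PV bar is fixed; candidate LA ellipse
    centers are scanned along the bearing direction and the one whose
    rasterized nearest-pixel distance best matches gap + 1 is kept.
    """
    h, w = config.shape[1], config.shape[2]
    alpha = np.radians(config.angle)
    u = np.array([np.sin(alpha), np.cos(alpha)])  # (row, col) bearing PV -> LA

    # Anchor the bar so bar + ellipse + gap fit along the bearing.
    ell_ext = float(np.hypot(config.la_radii[0] * u[0], config.la_radii[1] * u[1]))
    bar_ext = abs((config.pv_length - 1) / 2 * u[1]) + abs(
        (config.pv_thickness - 1) / 2 * u[0]
    )
    target = config.gap + 1.0
    reach = ell_ext + bar_ext + target

    if config.la_center is not None:
        g_nominal = np.asarray(config.la_center, dtype=float) - reach * u
    else:
        # center the whole construct: bar centroid sits `reach/2` before center
        g_nominal = np.array([(h - 1) / 2, (w - 1) / 2]) - (reach / 2) * u
    pv, g_p = _bar_mask((h, w), g_nominal, config.pv_length, config.pv_thickness)
    g_p = np.asarray(g_p)

    best = None  # (|d - target|, -R, la_mask)
    overlap_best = None  # (overlap_count, -R, la_mask)
    r_lo = max(0.5, reach - 4.0)
    for radius in np.arange(r_lo, reach + 4.0 + 1e-9, 0.25):
        center = g_p + radius * u
        try:
            la = _ellipse_mask((h, w), tuple(center), config.la_radii)
        except ConfigurationError:
            break  # moved out of bounds; larger R only gets worse
        if (la & pv).any():
            count = int(np.count_nonzero(la & pv))
            cand = (count, -radius, la)
            if overlap_best is None or cand[:2] < overlap_best[:2]:
                overlap_best = cand
            continue
        d = _min_dist(pv, la)
        cand = (abs(d - target), -radius, la)
        if best is None or cand[:2] < best[:2]:
            best = cand
        if d > target + 3:
            break

    if config.gap == 0:
        if best is not None and best[0] == 0.0:  # exact distance-1 pair found
            return pv, best[2]
        if overlap_best is None:
            raise ConfigurationError(
                "gap=0 layout failed: no touching or overlapping LA placement found"
            )
        la = overlap_best[2] & ~pv  # carve: PV wins, leaving a 4-adjacent seam
        if not la.any():
            raise ConfigurationError("gap=0 layout failed: LA fully swallowed by PV")
        return pv, la
    if best is None:
        raise ConfigurationError(
            f"no LA placement realizes gap={config.gap} within slice {h}×{w}"
        )
    return pv, best[2]


def _vein_mask(shape2d, la: np.ndarray, gap: float, la_radii):
    rows = np.flatnonzero(la.any(axis=1))
    cols = np.flatnonzero(la.any(axis=0))
    la_bottom = int(rows[-1])
    center_col = float(cols.mean())
    radii = (max(2.0, la_radii[0] / 3), max(3.0, la_radii[1] / 2))
    top = la_bottom + max(1, int(round(gap)) + 1)
    center = (top + radii[0], center_col)
    vein = _ellipse_mask(shape2d, center, radii)
    if (vein & la).any():
        raise ConfigurationError("confluent vein overlaps the LA; enlarge the slice")
    return vein


def _jitter_structure(mask: np.ndarray, other: np.ndarray, p: float, rng) -> np.ndarray:
    """Flip boundary pixels: remove foreground boundary / add adjacent
    background with equal probability p/2 each, never entering ``other``."""
    boundary = mask & ~ndimage.binary_erosion(mask, structure=_FACE2D, border_value=0)
    halo = ndimage.binary_dilation(mask, structure=_FACE2D) & ~mask & ~other
    out = mask.copy()
    remove = boundary & (rng.random(mask.shape) < p / 2)
    add = halo & (rng.random(mask.shape) < p / 2)
    out[remove] = False
    out[add] = True
    if not out.any():  # never empty a structure entirely
        return mask
    return out


def generate_phantom(config: PhantomConfig, case_id: str = "phantom") -> LabelVolume:
    """Render one phantom volume from a config; deterministic in (config, seed)."""
    depth, h, w = config.shape
    pv2d, la2d = _layout_slice(config)
    vein2d = _vein_mask((h, w), la2d, config.gap, config.la_radii) if config.vein else None

    first = (depth - config.shared_slices) // 2
    band = range(first, first + config.shared_slices)
    rng = np.random.default_rng(config.seed)
    p = min(1.0, config.jitter_sd)

    voxels = np.zeros(config.shape, dtype=np.uint8)
    for k in range(depth):
        la_k = la2d
        if p > 0:
            la_k = _jitter_structure(la2d, pv2d if k in band else np.zeros_like(la2d), p, rng)
        voxels[k][la_k] = LA
        if k in band:
            pv_k = _jitter_structure(pv2d, la_k, p, rng) if p > 0 else pv2d
            voxels[k][pv_k] = PV
            if vein2d is not None:
                vein_k = (
                    _jitter_structure(vein2d, la_k | pv_k, p, rng) if p > 0 else vein2d
                )
                voxels[k][vein_k & (voxels[k] == 0)] = VEIN
    return LabelVolume(
        voxels=voxels,
        label_map=dict(CANONICAL_LABEL_MAP),
        case_id=case_id,
        source_path="",
    )


def _truncated_normal(rng, mean_sd, clip):
    mean, sd = mean_sd
    if sd == 0:
        return float(np.clip(mean, *clip))
    return float(np.clip(rng.normal(mean, sd), *clip))


def generate_cohort(spec: CohortSpec) -> list[tuple[LabelVolume, CohortRecord]]:
    """Sample a reproducible normal/TAPVC cohort of phantom volumes.

    Per-case seeds are spawned deterministically from the master seed, so
    the cohort is byte-identical across runs and insensitive to iteration
    order.  Volume refs are relative NIfTI filenames; use
    :func:`write_cohort` to materialize them on disk.
    """
    seeds = np.random.SeedSequence(spec.master_seed).spawn(spec.n_normal + spec.n_tapvc)
    items: list[tuple[LabelVolume, CohortRecord]] = []
    plan = [("normal", i) for i in range(spec.n_normal)] + [
        ("TAPVC", i) for i in range(spec.n_tapvc)
    ]
    for (group, i), seq in zip(plan, seeds):
        rng = np.random.default_rng(seq)
        if group == "normal":
            gap = _truncated_normal(rng, spec.normal_gap, spec.GAP_CLIP)
            angle = _truncated_normal(rng, spec.normal_angle, spec.ANGLE_CLIP)
            vein = False
        else:
            gap = _truncated_normal(rng, spec.tapvc_gap, spec.GAP_CLIP)
            angle = _truncated_normal(rng, spec.tapvc_angle, spec.ANGLE_CLIP)
            vein = spec.tapvc_vein
        case_id = f"{group.lower()}_{i + 1:02d}"
        config = replace(
            spec.base_config,
            gap=gap,
            angle=angle,
            vein=vein,
            seed=int(seq.generate_state(1, np.uint32)[0] % (2**31)),
        )
        volume = generate_phantom(config, case_id=case_id)
        record = CohortRecord(
            case_id=case_id,
            volume_ref=f"{case_id}.nii.gz",
            group=group,
            role="ground_truth",
            model_name=None,
        )
        items.append((volume, record))
    return items


def write_cohort(items, out_dir) -> str:
    """Write cohort volumes as NIfTI plus the cohort CSV; returns the CSV path."""
    from pathlib import Path

    from .mask_io import write_cohort_csv, write_label_volume

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for volume, record in items:
        write_label_volume(volume, out_dir / record.volume_ref)
    csv_path = out_dir / "cohort.csv"
    write_cohort_csv([r for _, r in items], csv_path)
    return str(csv_path)


PERTURB_MODES = ("erode", "dilate", "translate", "drop_slices")


def perturb_mask(
    volume: LabelVolume,
    mode: str,
    magnitude: int,
    seed: int = 0,
    structure: str = "PV",
    direction: tuple[int, int] | None = None,
) -> LabelVolume:
    """Deterministic seeded degradation of one structure of a volume.

    Modes: ``erode``/``dilate`` (6-connected morphology, ``magnitude``
    iterations; dilation never overwrites other labels), ``translate``
    (in-plane shift by ``magnitude`` pixels; ``direction`` defaults to a
    seeded choice among the four axis directions), ``drop_slices`` (clear
    the structure from ``magnitude`` seeded slices).  A perturbation that
    empties the structure warns and returns the emptied volume.
    """
    if mode not in PERTURB_MODES:
        raise ValidationError(f"mode must be one of {PERTURB_MODES}; got {mode!r}")
    if magnitude < 1:
        raise ValidationError(f"magnitude must be >= 1; got {magnitude}")
    label = volume.label_map[structure]
    mask = volume.voxels == label
    if not mask.any():
        raise ValidationError(f"structure {structure} is empty; nothing to perturb")
    rng = np.random.default_rng(seed)
    voxels = volume.voxels.copy()
    struct3d = ndimage.generate_binary_structure(3, 1)

    if mode == "erode":
        new = ndimage.binary_erosion(mask, structure=struct3d, iterations=magnitude, border_value=0)
        voxels[mask & ~new] = 0
    elif mode == "dilate":
        new = ndimage.binary_dilation(mask, structure=struct3d, iterations=magnitude)
        voxels[new & (voxels == 0)] = label
    elif mode == "translate":
        if direction is None:
            direction = [(1, 0), (-1, 0), (0, 1), (0, -1)][rng.integers(4)]
        dr, dc = direction[0] * magnitude, direction[1] * magnitude
        new = np.zeros_like(mask)
        src = np.argwhere(mask)
        dst = src + np.array([0, dr, dc])
        shape = np.array(volume.shape)
        keep = np.all((dst >= 0) & (dst < shape), axis=1)
        dst = dst[keep]
        new[tuple(dst.T)] = True
        voxels[mask] = 0
        voxels[new & (voxels == 0)] = label
    else:  # drop_slices
        present = np.flatnonzero(mask.any(axis=(1, 2)))
        n_drop = min(magnitude, present.size)
        drop = rng.choice(present, size=n_drop, replace=False)
        for k in drop:
            voxels[k][mask[k]] = 0

    if not np.any(voxels == label):
        warnings.warn(
            f"perturbation {mode}(magnitude={magnitude}) emptied structure {structure}",
            stacklevel=2,
        )
    return LabelVolume(
        voxels=voxels,
        label_map=dict(volume.label_map),
        case_id=volume.case_id,
        source_path=volume.source_path,
    )
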