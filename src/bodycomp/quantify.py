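"""Post-segmentation quantification: volumes, circumference, K-means IMAT.

Compartment volumes are voxel counts times voxel volume, with no
morphological refinement.  Bone circumference is measured per slice as the
perimeter of the sub-pixel marching-squares contour (iso-level 0.5) around
the largest connected component, scaled by in-plane spacing, and averaged
over the slices containing the compartment.

Intermuscular adipose tissue (IMAT) is quantified by 2-cluster K-means on
the fat-channel intensities inside the muscle compartment (core muscle for
the abdomen, thigh muscle for the thigh): k-means++ seeding, convergence
when the Frobenius norm of the relative centre movement drops below 1e-4 or
after 300 iterations, higher-mean cluster labelled IMAT.  Clustering runs on
raw (pre-normalization) intensities.  The IMAT percentage is IMAT volume
over total muscle volume, which reduces to a voxel-count ratio at uniform
spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage import measure

from .imgio import DualVolume, LabelMask
from .schema import LabelSchema

KMEANS_RTOL = 1e-4
KMEANS_MAX_ITER = 300


# ---------------------------------------------------------------------------
# volumes


def volume_of(mask: LabelMask, compartment: Iterable[int]) -> float:
    """Volume in mL: voxel count x dz*dy*dx (mm^3), divided by 1000."""
    ids = list(compartment)
    dz, dy, dx = mask.spacing
    count = int(np.isin(mask.labels, ids).sum())
    return count * dz * dy * dx / 1000.0


def background_volume(mask: LabelMask) -> float:
    dz, dy, dx = mask.spacing
    return int((mask.labels == 0).sum()) * dz * dy * dx / 1000.0


# ---------------------------------------------------------------------------
# circumference


CONTOUR_SMOOTH_SIGMA = 1.0  # px; suppresses marching-squares staircase bias


def _slice_perimeter(binary: np.ndarray, dy: float, dx: float) -> Optional[float]:
    """Perimeter (mm) of the outer contour of the largest component.

    The binary blob is Gaussian-smoothed (sigma 1 px) before the iso-0.5
    contour is traced: the raw marching-squares polyline on binary data
    overestimates arc length by ~5% (staircase bias); the smoothed contour
    tracks the underlying shape to well under 1% on discs, at the cost of
    rounding sharp corners by about the smoothing radius.
    """
    if not binary.any():
        return None
    comps = measure.label(binary)
    largest = np.argmax(np.bincount(comps.ravel())[1:]) + 1
    blob = ndimage.gaussian_filter(np.pad((comps == largest).astype(float), 4),
                                   CONTOUR_SMOOTH_SIGMA)
    contours = measure.find_contours(blob, 0.5)
    if not contours:
        return None
    # outer boundary = longest contour
    best, best_len = None, -1.0
    for c in contours:
        d = np.diff(c, axis=0)
        length = float(np.sqrt((d[:, 0] * dy) ** 2 + (d[:, 1] * dx) ** 2).sum())
        if length > best_len:
            best, best_len = c, length
    return best_len


def circumference_of(mask: LabelMask, compartment: Iterable[int],
                     slice_index: Optional[int] = None) -> float:
    """Mean over-slices perimeter (mm); ``slice_index`` selects one slice."""
    ids = list(compartment)
    binary = np.isin(mask.labels, ids)
    if not binary.any():
        raise ValueError("compartment is empty; no circumference to measure")
    _, dy, dx = mask.spacing
    if slice_index is not None:
        p = _slice_perimeter(binary[slice_index], dy, dx)
        if p is None:
            raise ValueError(f"compartment empty on slice {slice_index}")
        return p
    perims = [p for k in range(binary.shape[0])
              if (p := _slice_perimeter(binary[k], dy, dx)) is not None]
    if not perims:  # fragments too small to carry an iso-0.5 contour
        return float("nan")
    return float(np.mean(perims))


# ---------------------------------------------------------------------------
# K-means IMAT


@dataclass
class KMeansResult:
    centers: np.ndarray          # two intensity means, ascending order
    assignments: np.ndarray      # per masked voxel: 0 = low, 1 = high cluster
    n_iter: int
    converged: bool
    degenerate: bool = False
    wcss_history: Tuple[float, ...] = ()  # within-cluster SS per iteration


def _kmeanspp_init(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding for k=2 on a 1D sample."""
    c0 = values[rng.integers(len(values))]
    d2 = (values - c0) ** 2
    total = d2.sum()
    if total == 0:
        return np.array([c0, c0])
    c1 = values[rng.choice(len(values), p=d2 / total)]
    return np.array([c0, c1])


def kmeans_imat(
    fat_image: np.ndarray,
    muscle_mask: np.ndarray,
    seed: int = 0,
    rtol: float = KMEANS_RTOL,
    max_iter: int = KMEANS_MAX_ITER,
) -> Tuple[KMeansResult, np.ndarray]:
    """2-cluster K-means on fat intensities within the muscle mask.

    Returns the clustering result and the boolean IMAT mask (higher-mean
    cluster), a subset of ``muscle_mask``.  Constant intensities are flagged
    degenerate and yield an empty IMAT mask.
    """
    muscle_mask = np.asarray(muscle_mask, dtype=bool)
    if not muscle_mask.any():
        raise ValueError("muscle mask is empty")
    values = np.asarray(fat_image, dtype=np.float64)[muscle_mask]
    imat = np.zeros(muscle_mask.shape, dtype=bool)
    if np.ptp(values) == 0:
        res = KMeansResult(np.array([values[0], values[0]]),
                           np.zeros(len(values), dtype=np.int8), 0, True,
                           degenerate=True)
        return res, imat

    rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))
    centers = _kmeanspp_init(values, rng)
    if centers[0] == centers[1]:  # unlucky duplicate seed: spread to extremes
        centers = np.array([values.min(), values.max()])
    converged = False
    n_iter = 0
    wcss: list = []
    for n_iter in range(1, max_iter + 1):
        assign = (np.abs(values[:, None] - centers[None, :])).argmin(axis=1)
        new = centers.copy()
        for j in (0, 1):
            sel = values[assign == j]
            if len(sel):
                new[j] = sel.mean()
        wcss.append(float(sum(((values[assign == j] - new[j]) ** 2).sum()
                              for j in (0, 1))))
        move = np.linalg.norm(new - centers)
        scale = np.linalg.norm(new)
        centers = new
        if move <= rtol * (scale if scale > 0 else 1.0):
            converged = True
            break
    assign = (np.abs(values[:, None] - centers[None, :])).argmin(axis=1)
    # order clusters ascending; IMAT = the higher-mean cluster
    if centers[0] > centers[1]:
        centers = centers[::-1].copy()
        assign = 1 - assign
    imat[muscle_mask] = assign == 1
    res = KMeansResult(centers, assign.astype(np.int8), n_iter, converged,
                       wcss_history=tuple(wcss))
    return res, imat


def threshold_search_1d(values: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Exact optimal 2-means partition of 1D data by sorted threshold search.

    The optimal 2-cluster partition of scalars is a cut of the sorted sample;
    this enumerates every cut and minimizes within-cluster sum of squares.
    Returns (centers ascending, assignments with 1 = upper cluster).
    Deterministic; doubles as an oracle for the iterative clustering.
    """
    v = np.asarray(values, dtype=np.float64)
    order = np.argsort(v, kind="stable")
    s = v[order]
    n = len(s)
    if n < 2 or s[0] == s[-1]:
        return np.array([v.mean(), v.mean()]), np.zeros(n, dtype=np.int8)
    csum = np.cumsum(s)
    csq = np.cumsum(s ** 2)
    best_cut, best_cost = 1, np.inf
    for cut in range(1, n):
        left_cost = csq[cut - 1] - csum[cut - 1] ** 2 / cut
        rs, rq = csum[-1] - csum[cut - 1], csq[-1] - csq[cut - 1]
        right_cost = rq - rs ** 2 / (n - cut)
        cost = left_cost + right_cost
        if cost < best_cost:
            best_cut, best_cost = cut, cost
    assign_sorted = (np.arange(n) >= best_cut).astype(np.int8)
    assign = np.empty(n, dtype=np.int8)
    assign[order] = assign_sorted
    centers = np.array([s[:best_cut].mean(), s[best_cut:].mean()])
    return centers, assign


def imat_percentage(result: KMeansResult, muscle_mask: np.ndarray,
                    spacing: Tuple[float, float, float] | None = None) -> float:
    """100 x IMAT voxels / muscle voxels (volumes cancel at uniform spacing)."""
    n_muscle = int(np.count_nonzero(muscle_mask))
    if n_muscle == 0:
        raise ValueError("muscle mask is empty")
    if result.degenerate:
        return 0.0
    return 100.0 * int((result.assignments == 1).sum()) / n_muscle


def grade_bins(percent: float, cut_points: Tuple[float, float] = (5.0, 25.0)) -> int:
    """Map an IMAT percentage onto the 3-level fatty-infiltration scale.

    Stage 0 (none/mild), 1 (streaks/moderate), 2 (severe).  Cut points are a
    configuration choice; the grading standard itself gives no numeric map.
    """
    g01, g12 = cut_points
    if not g01 < g12:
        raise ValueError("cut points must be increasing")
    if percent < g01:
        return 0
    if percent < g12:
        return 1
    return 2


# ---------------------------------------------------------------------------
# composition profile


@dataclass
class CompositionProfile:
    """The per-case quantitative report (volumes in mL, circumference in mm)."""

    region: str
    volumes_ml: Dict[str, float]
    circumference_mm: float
    imat_fraction: float           # IMAT volume / muscle volume, in [0, 1]
    imat_percent: float            # 100 * imat_fraction
    imat_mask: Optional[np.ndarray] = None

    def as_dict(self) -> dict:
        return {
            "region": self.region,
            "volumes_ml": dict(self.volumes_ml),
            "circumference_mm": self.circumference_mm,
            "imat_fraction": self.imat_fraction,
            "imat_percent": self.imat_percent,
        }


def composition_profile(
    volume: DualVolume,
    mask: LabelMask,
    seed: int = 0,
    keep_imat_mask: bool = False,
) -> CompositionProfile:
    """Assemble the full component report from a segmentation.

    Abdomen: VB, PM, CM, sSAT, dSAT, SAT, IPAT, RPAT, VAT volumes, vertebral
    bone circumference, and IMAT within the core muscle.  Thigh: femur,
    vessel, SAT, muscle volumes, femur circumference, and IMAT within thigh
    muscle.  Missing compartments are reported as zero volume.
    """
    schema = mask.schema
    volumes = {name: volume_of(mask, ids)
               for name, ids in schema.compartments().items()}
    circ_ids = schema.ids_of(schema.circumference_label)
    if np.isin(mask.labels, list(circ_ids)).any():
        circ = circumference_of(mask, circ_ids)
    else:
        circ = float("nan")
    muscle = mask.labels == schema.id_of(schema.muscle_for_imat)
    if muscle.any() and np.ptp(np.asarray(volume.fat)[muscle]) > 0:
        res, imat_mask = kmeans_imat(volume.fat, muscle, seed=seed)
        pct = imat_percentage(res, muscle)
    else:
        imat_mask = np.zeros(mask.shape, dtype=bool)
        pct = 0.0
    dz, dy, dx = mask.spacing
    volumes["IMAT"] = int(imat_mask.sum()) * dz * dy * dx / 1000.0
    return CompositionProfile(
        region=schema.region, volumes_ml=volumes, circumference_mm=circ,
        imat_fraction=pct / 100.0, imat_percent=pct,
        imat_mask=imat_mask if keep_imat_mask else None,
    )


def profile_from_truth(case) -> CompositionProfile:
    """Exact profile from a phantom's ground-truth masks (recovery oracle)."""
    schema = case.truth.schema
    volumes = {name: volume_of(case.truth, ids)
               for name, ids in schema.compartments().items()}
    dz, dy, dx = case.truth.spacing
    n_imat = int(case.imat_truth.sum())
    volumes["IMAT"] = n_imat * dz * dy * dx / 1000.0
    muscle = case.muscle_mask()
    n_muscle = int(muscle.sum())
    frac = n_imat / n_muscle if n_muscle else 0.0
    circ = circumference_of(case.truth, schema.ids_of(schema.circumference_label))
    return CompositionProfile(
        region=schema.region, volumes_ml=volumes, circumference_mm=circ,
        imat_fraction=frac, imat_percent=100.0 * frac,
    )
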