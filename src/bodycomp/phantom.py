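"""Seeded synthetic dual-sequence phantoms with exact ground truth.

The generator emulates the geometry and contrast of paired fat/water
abdominal and thigh MR acquisitions at desk scale: anisotropic spacing
(thick slices, sub-millimetre in-plane), an abdominal slice built from
nested rings (skin -> superficial SAT -> deep SAT -> core-muscle wall ->
visceral cavity split into intraperitoneal and retroperitoneal fat, with a
vertebral body and paired psoas muscles posteriorly) and a thigh slice built
from a subcutaneous fat ring, muscle, a central femur and small vessels.
Intermuscular fat (IMAT) is planted as seeded 1-3 voxel speckle clusters
inside the muscle compartment at a controllable fraction; the planted voxels
are recorded exactly in ``imat_truth`` so parameter-recovery tests have an
oracle.  Geometry is procedural (ellipses/annuli with seeded jitter), not
anatomically realistic; intensities are arbitrary units with the fat channel
bright in adipose tissue and the water channel bright in muscle.

Noise and geometry use independent seeded streams, so changing ``noise_sd``
never changes the truth masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .imgio import DualVolume, LabelMask
from .schema import ABDOMEN, THIGH, LabelSchema

# Per-tissue mean intensities, arbitrary units.  Fat-channel adipose modes sit
# well above muscle (>= 5 default noise SDs apart) so 2-cluster intensity
# K-means inside muscle is separable by construction.
DEFAULT_CONTRAST: Dict[str, Dict[str, float]] = {
    "fat": {
        "background": 0.0, "adipose": 800.0, "muscle": 100.0,
        "bone": 300.0, "vessel": 60.0, "imat": 800.0,
    },
    "water": {
        "background": 0.0, "adipose": 120.0, "muscle": 800.0,
        "bone": 250.0, "vessel": 600.0, "imat": 120.0,
    },
}

_TISSUE_OF_LABEL = {
    "abdomen": {
        "VB": "bone", "PM": "muscle", "CM": "muscle",
        "sSAT": "adipose", "dSAT": "adipose", "IPAT": "adipose", "RPAT": "adipose",
    },
    "thigh": {"femur": "bone", "vessel": "vessel", "SAT": "adipose", "muscle": "muscle"},
}


@dataclass(frozen=True)
class PhantomParams:
    """Study-condition knobs for one synthetic case."""

    region: str = "thigh"
    grid_shape: Tuple[int, int, int] = (8, 64, 64)
    spacing: Tuple[float, float, float] = (10.0, 1.0, 1.0)
    imat_fraction: float = 0.10
    contrast: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CONTRAST.items()})
    noise_sd: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region not in ("abdomen", "thigh"):
            raise ValueError(f"unknown region {self.region!r}")
        if any(s < 8 for s in self.grid_shape):
            raise ValueError("grid_shape must be >= 8 along every axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if not (0.0 <= self.imat_fraction < 1.0):
            raise ValueError("imat_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.contrast["fat"]["adipose"] <= self.contrast["fat"]["muscle"]:
            raise ValueError("fat-channel adipose intensity must exceed muscle "
                             "(K-means separability guarantee)")

    @property
    def schema(self) -> LabelSchema:
        return ABDOMEN if self.region == "abdomen" else THIGH


@dataclass
class PhantomCase:
    volume: DualVolume
    truth: LabelMask
    imat_truth: np.ndarray  # boolean, subset of the muscle compartment
    params: PhantomParams

    def muscle_mask(self) -> np.ndarray:
        name = self.params.schema.muscle_for_imat
        return self.truth.labels == self.params.schema.id_of(name)


def _ellipse(rr: np.ndarray, cc: np.ndarray, center: Tuple[float, float],
             radii: Tuple[float, float]) -> np.ndarray:
    return ((rr - center[0]) / radii[0]) ** 2 + ((cc - center[1]) / radii[1]) ** 2 <= 1.0


def _paint_abdomen(nr: int, nc: int, g: np.random.Generator) -> np.ndarray:
    s = ABDOMEN.names
    rr, cc = np.mgrid[0:nr, 0:nc].astype(np.float64)
    cy, cx = nr / 2.0, nc / 2.0
    jit = lambda lo, hi: float(g.uniform(lo, hi))
    # outer body ellipse and the nested rings, as fractions of the grid
    a = (nr / 2.0 - 1.5) * jit(0.93, 1.0)   # row semi-axis
    b = (nc / 2.0 - 1.5) * jit(0.93, 1.0)   # col semi-axis
    body = _ellipse(rr, cc, (cy, cx), (a, b))
    fascia = _ellipse(rr, cc, (cy, cx), (a * 0.88, b * 0.88))
    wall_out = _ellipse(rr, cc, (cy, cx), (a * 0.76, b * 0.76))
    wall_in = _ellipse(rr, cc, (cy, cx), (a * 0.64, b * 0.64))

    lab = np.zeros((nr, nc), dtype=np.int32)
    lab[body & ~fascia] = s["sSAT"]
    lab[fascia & ~wall_out] = s["dSAT"]
    lab[wall_out & ~wall_in] = s["CM"]

    # visceral cavity: retroperitoneal strip posteriorly (high row index),
    # intraperitoneal fat elsewhere
    cavity = wall_in
    post_boundary = cy + a * 0.22
    lab[cavity & (rr <= post_boundary)] = s["IPAT"]
    lab[cavity & (rr > post_boundary)] = s["RPAT"]

    # vertebral body posterior-central, paired psoas flanking it
    vb_r = max(2.0, a * jit(0.13, 0.16))
    vb_cy = cy + a * 0.40
    vb = _ellipse(rr, cc, (vb_cy, cx), (vb_r, vb_r))
    lab[vb & cavity] = s["VB"]
    ps_r = max(1.5, a * jit(0.09, 0.12))
    for side in (-1.0, 1.0):
        ps = _ellipse(rr, cc, (vb_cy, cx + side * b * 0.28), (ps_r, ps_r * 1.2))
        lab[ps & cavity & (lab != s["VB"])] = s["PM"]
    return lab


def _paint_thigh(nr: int, nc: int, g: np.random.Generator) -> np.ndarray:
    s = THIGH.names
    rr, cc = np.mgrid[0:nr, 0:nc].astype(np.float64)
    cy, cx = nr / 2.0, nc / 2.0
    jit = lambda lo, hi: float(g.uniform(lo, hi))
    a = (nr / 2.0 - 1.5) * jit(0.93, 1.0)
    b = (nc / 2.0 - 1.5) * jit(0.93, 1.0)
    body = _ellipse(rr, cc, (cy, cx), (a, b))
    musc_out = _ellipse(rr, cc, (cy, cx), (a * jit(0.76, 0.84), b * jit(0.76, 0.84)))
    lab = np.zeros((nr, nc), dtype=np.int32)
    lab[body & ~musc_out] = s["SAT"]
    lab[musc_out] = s["muscle"]
    fem_r = max(2.0, min(a, b) * jit(0.16, 0.22))
    off = (float(g.uniform(-1.5, 1.5)), float(g.uniform(-1.5, 1.5)))
    femur = _ellipse(rr, cc, (cy + off[0], cx + off[1]), (fem_r, fem_r))
    lab[femur & musc_out] = s["femur"]
    # two or three small vessel discs inside the muscle ring
    n_vessels = int(g.integers(2, 4))
    placed = 0
    for _ in range(40):
        if placed >= n_vessels:
            break
        ang = float(g.uniform(0, 2 * np.pi))
        rad = float(g.uniform(0.45, 0.62))
        vy, vx = cy + np.sin(ang) * a * rad, cx + np.cos(ang) * b * rad
        vr = max(1.2, min(a, b) * 0.05)
        disc = _ellipse(rr, cc, (vy, vx), (vr, vr))
        if np.all(lab[disc] == s["muscle"]) and disc.sum() >= 2:
            lab[disc] = s["vessel"]
            placed += 1
    return lab


def _plant_imat(labels: np.ndarray, schema: LabelSchema, fraction: float,
                g: np.random.Generator) -> np.ndarray:
    """Plant speckle clusters of 1-3 voxels in the IMAT host muscle."""
    imat = np.zeros(labels.shape, dtype=bool)
    if fraction <= 0.0:
        return imat
    host = labels == schema.id_of(schema.muscle_for_imat)
    n_host = int(host.sum())
    target = int(round(fraction * n_host))
    if target == 0:
        return imat
    coords = np.argwhere(host)
    order = g.permutation(len(coords))
    offsets = np.array([(0, 0, 0), (0, 0, 1), (0, 1, 0), (0, 0, -1), (0, -1, 0)])
    planted = 0
    shape = labels.shape
    for idx in order:
        if planted >= target:
            break
        size = int(g.integers(1, 4))
        size = min(size, target - planted)
        seedv = coords[idx]
        cluster = [tuple(seedv)]
        g.shuffle(offsets[1:])
        for off in offsets[1:]:
            if len(cluster) >= size:
                break
            cand = tuple(seedv + off)
            if all(0 <= cand[i] < shape[i] for i in range(3)) and host[cand] and not imat[cand]:
                cluster.append(cand)
        for v in cluster:
            if not imat[v]:
                imat[v] = True
                planted += 1
    return imat


def generate_phantom(params: PhantomParams) -> PhantomCase:
    """Generate one seeded phantom with exact masks and planted IMAT.

    The same ``params`` (including seed) always yields bit-identical output.
    """
    ns, nr, nc = params.grid_shape
    geom_rng = np.random.default_rng(np.random.SeedSequence([params.seed, 17]))
    noise_rng = np.random.default_rng(np.random.SeedSequence([params.seed, 31]))

    paint = _paint_abdomen if params.region == "abdomen" else _paint_thigh
    slice_lab = paint(nr, nc, geom_rng)
    labels = np.repeat(slice_lab[None], ns, axis=0).copy()

    schema = params.schema
    present = set(np.unique(labels)) - {0}
    missing = [n for i, n in schema.label_ids.items() if i not in present]
    if missing:
        raise ValueError(
            f"grid {params.grid_shape} too small to place compartments: {missing}")

    imat = _plant_imat(labels, schema, params.imat_fraction, geom_rng)

    tissue_of = _TISSUE_OF_LABEL[params.region]
    fat = np.full(labels.shape, params.contrast["fat"]["background"], dtype=np.float32)
    water = np.full(labels.shape, params.contrast["water"]["background"], dtype=np.float32)
    for lid, name in schema.label_ids.items():
        t = tissue_of[name]
        fat[labels == lid] = params.contrast["fat"][t]
        water[labels == lid] = params.contrast["water"][t]
    fat[imat] = params.contrast["fat"]["imat"]
    water[imat] = params.contrast["water"]["imat"]

    # noise drawn from its own stream: masks are invariant to noise_sd
    if params.noise_sd >= 0:
        fat = fat + params.noise_sd * noise_rng.standard_normal(fat.shape).astype(np.float32)
        water = water + params.noise_sd * noise_rng.standard_normal(water.shape).astype(np.float32)

    vol = DualVolume(fat, water, params.spacing)
    truth = LabelMask(labels, schema, params.spacing)
    return PhantomCase(vol, truth, imat, params)


def make_cohort(
    n: int,
    base: PhantomParams,
    seed: int,
    imat_sd: float = 0.04,
) -> Tuple[List[PhantomCase], pd.DataFrame]:
    """Generate ``n`` seeded phantoms with varied IMAT plus a covariate table.

    Per-case IMAT fractions are drawn from a Beta distribution with mean
    ``base.imat_fraction``; the synthetic BMI-like covariate is lognormal
    (median ~25 kg/m^2) and loosely linked to case geometry, giving the
    stratified split something real to stratify on.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 97]))
    cases, rows = [], []
    mean_f = base.imat_fraction
    for i in range(n):
        if mean_f > 0 and imat_sd > 0:
            var = min(imat_sd ** 2, 0.9 * mean_f * (1 - mean_f))
            conc = mean_f * (1 - mean_f) / var - 1.0
            f = float(rng.beta(mean_f * conc, (1 - mean_f) * conc))
            f = min(f, 0.95)
        else:
            f = mean_f
        case_seed = int(rng.integers(0, 2**31 - 1))
        p = replace(base, imat_fraction=f, seed=case_seed)
        case = generate_phantom(p)
        cases.append(case)
        # BMI-like covariate: lognormal, loosely tied to the realized
        # subcutaneous-fat ring thickness of the case
        sat_ids = case.truth.schema.ids_of("SAT")
        sat_frac = float(np.isin(case.truth.labels, list(sat_ids)).mean())
        bmi = float(np.exp(rng.normal(np.log(18.0 + 60.0 * sat_frac), 0.08)))
        rows.append({"case_id": f"case_{i:03d}", "bmi": bmi,
                     "imat_fraction": f, "seed": case_seed})
    return cases, pd.DataFrame(rows)


def reference_profile(case: PhantomCase):
    """Ground-truth composition profile straight from the exact masks."""
    from .quantify import profile_from_truth

    return profile_from_truth(case)
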