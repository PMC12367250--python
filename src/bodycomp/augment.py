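"""Stochastic training-time augmentation applied jointly to image and mask.

Six transforms — rotation, scaling, Gaussian noise, Gaussian blur, gamma
correction, and mirroring — each fire independently with probability 0.5 by
default.  Geometric transforms apply identically to the image (third-order
spline) and the mask (nearest neighbour); intensity transforms touch the
image only, so the mask is bit-identical under them.  Default parameter
ranges follow the nnU-Net conventions: rotation +/-30 degrees, scale
0.7-1.4, additive noise variance 0-0.1, blur sigma 0.5-1.0, gamma 0.7-1.5,
mirroring along both in-plane axes.  Operates per 2D slice, matching
slice-wise training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class AugmentConfig:
    apply_probability: float = 0.5
    rotation_deg: Tuple[float, float] = (-30.0, 30.0)
    scale: Tuple[float, float] = (0.7, 1.4)
    gaussian_noise_var: Tuple[float, float] = (0.0, 0.1)
    blur_sigma: Tuple[float, float] = (0.5, 1.0)
    gamma: Tuple[float, float] = (0.7, 1.5)
    mirror_axes: Tuple[int, ...] = (0, 1)
    enabled: Tuple[str, ...] = ("rotation", "scale", "noise", "blur",
                                "gamma", "mirror")

    def __post_init__(self) -> None:
        if not 0.0 <= self.apply_probability <= 1.0:
            raise ValueError("apply_probability must be in [0, 1]")


def _affine_about_center(img: np.ndarray, matrix: np.ndarray, order: int,
                         cval: float = 0.0) -> np.ndarray:
    center = (np.asarray(img.shape) - 1) / 2.0
    offset = center - matrix @ center
    return ndimage.affine_transform(img, matrix, offset=offset, order=order,
                                    mode="constant", cval=cval,
                                    prefilter=(order > 1))


def augment_pair(
    image_slice: np.ndarray,
    mask_slice: np.ndarray,
    config: AugmentConfig,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Augment one (channels, H, W) image slice and its (H, W) label slice.

    Every transform draws its fire/skip decision and parameters from ``rng``,
    so a seeded generator reproduces the output exactly.
    """
    image_slice = np.asarray(image_slice, dtype=np.float32)
    mask_slice = np.asarray(mask_slice)
    if image_slice.ndim != 3:
        raise ValueError("image slice must be (channels, H, W)")
    if image_slice.shape[1:] != mask_slice.shape:
        raise ValueError(
            f"in-plane shape mismatch: {image_slice.shape[1:]} vs {mask_slice.shape}")

    img = image_slice.copy()
    msk = mask_slice.copy()
    p = config.apply_probability
    fire = {t: (t in config.enabled) and (rng.random() < p)
            for t in ("rotation", "scale", "noise", "blur", "gamma", "mirror")}

    # geometric: build one affine (rotation o scale) so image and mask warp once
    matrix = np.eye(2)
    do_geom = False
    if fire["rotation"]:
        theta = np.deg2rad(rng.uniform(*config.rotation_deg))
        c, s = np.cos(theta), np.sin(theta)
        matrix = matrix @ np.array([[c, -s], [s, c]])
        do_geom = True
    if fire["scale"]:
        # zoom factor f enlarges content by f; inverse map scales coords by 1/f
        f = rng.uniform(*config.scale)
        matrix = matrix @ (np.eye(2) / f)
        do_geom = True
    if do_geom:
        img = np.stack([_affine_about_center(ch, matrix, order=3) for ch in img])
        msk = _affine_about_center(msk.astype(np.float64), matrix, order=0
                                   ).astype(mask_slice.dtype)
    if fire["mirror"]:
        # all configured axes flip together, so firing twice is the identity
        for ax in config.mirror_axes:
            img = np.flip(img, axis=ax + 1)
            msk = np.flip(msk, axis=ax)

    # intensity transforms: image only
    if fire["noise"]:
        var = rng.uniform(*config.gaussian_noise_var)
        img = img + rng.normal(0.0, np.sqrt(var), size=img.shape).astype(np.float32)
    if fire["blur"]:
        sigma = rng.uniform(*config.blur_sigma)
        img = np.stack([ndimage.gaussian_filter(ch, sigma) for ch in img])
    if fire["gamma"]:
        g = rng.uniform(*config.gamma)
        lo, hi = img.min(), img.max()
        if hi > lo:  # gamma on the [0, 1]-rescaled range, then map back
            img = ((img - lo) / (hi - lo)) ** g * (hi - lo) + lo

    return np.ascontiguousarray(img, dtype=np.float32), np.ascontiguousarray(msk)
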