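"""Serial-section registration.

Aligns the epithelium-marker IHC section to the chromogenic ISH section so
the tumor mask derived from the IHC slide can be transferred onto the ISH
slide ("virtual double staining"). Serial sections a few micrometres apart
differ by slide placement — translation, rotation and a small isotropic
scale — so the default transform family is a similarity transform; affine
is available for shear-prone material. Registration is fully deterministic:
a coarse-to-fine pyramid with an exhaustive rotation/scale multi-start
(translation initialised by FFT cross-correlation) followed by Powell
refinement of a normalized-cross-correlation objective.

The similarity metric is NCC on the unmixed *counterstain* OD maps
(hematoxylin on the IHC slide, nuclear fast red on the ISH slide) rather
than on total OD: the two chromogens label different compartments with
opposite contrast, so total-OD correlation is inverted at the true
alignment, whereas the counterstains label all tissue on both sections and
share cell-density structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation

from .stains import (
    DEFAULT_IHC_STAINS,
    DEFAULT_ISH_STAINS,
    BinaryMask,
    StainMatrix,
    as_mask_array,
    rgb_to_od,
    unmix,
)

__all__ = [
    "AffineTransform2D",
    "RegistrationResult",
    "NoTissueError",
    "register",
    "warp_mask",
    "warp_image",
]

MODELS = ("translation", "rigid", "similarity", "affine")


class NoTissueError(ValueError):
    """Raised when an image carries no tissue signal (total OD ~ 0 everywhere)."""


@dataclass(frozen=True)
class AffineTransform2D:
    """2D affine map q = A @ p + b in 0-based (row, col) pixel coordinates.

    ``matrix`` is the 2x3 array [A | b]. By convention the transform maps
    IHC (moving) pixel coordinates to ISH (fixed) pixel coordinates.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValueError("affine matrix must be 2x3")
        if abs(np.linalg.det(m[:, :2])) <= 1e-6:
            raise ValueError("linear part of affine transform is not invertible")
        object.__setattr__(self, "matrix", m)

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def offset(self) -> np.ndarray:
        return self.matrix[:, 2]

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @classmethod
    def similarity(
        cls,
        angle_deg: float = 0.0,
        scale: float = 1.0,
        translation: tuple[float, float] = (0.0, 0.0),
        center: tuple[float, float] = (0.0, 0.0),
    ) -> "AffineTransform2D":
        """q = scale * R(angle) @ (p - center) + center + translation."""
        th = np.deg2rad(angle_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        lin = scale * rot
        c = np.asarray(center, dtype=float)
        off = c + np.asarray(translation, dtype=float) - lin @ c
        return cls(np.column_stack([lin, off]))

    def inverse(self) -> "AffineTransform2D":
        inv = np.linalg.inv(self.linear)
        return AffineTransform2D(np.column_stack([inv, -inv @ self.offset]))

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """Return self o other (apply ``other`` first)."""
        lin = self.linear @ other.linear
        off = self.linear @ other.offset + self.offset
        return AffineTransform2D(np.column_stack([lin, off]))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.linear.T + self.offset

    def decompose(self, center: tuple[float, float] = (0.0, 0.0)):
        """Similarity-part parameters: (angle_deg, scale, translation at center)."""
        a = self.linear
        scale = float(np.sqrt(abs(np.linalg.det(a))))
        angle = float(np.rad2deg(np.arctan2(a[1, 0], a[0, 0])))
        c = np.asarray(center, dtype=float)
        translation = self.apply(c)[0] - c
        return angle, scale, translation

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "matrix_2x3_row_major": [float(x) for x in self.matrix.ravel()],
                    "convention": "q_rowcol = A @ p_rowcol + b, 0-based pixels, "
                    "moving (IHC) -> fixed (ISH)",
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "AffineTransform2D":
        payload = json.loads(Path(path).read_text())
        return cls(np.array(payload["matrix_2x3_row_major"], dtype=float).reshape(2, 3))


@dataclass
class RegistrationResult:
    transform: AffineTransform2D
    similarity_final: float
    similarity_init: float
    n_levels: int
    converged: bool
    model: str


def warp_image(
    image: np.ndarray,
    transform: AffineTransform2D,
    output_shape: tuple[int, int],
    order: int = 1,
    cval: float = 0.0,
) -> np.ndarray:
    """Resample ``image`` into the target frame: out[q] = image[T^-1 q]."""
    inv = transform.inverse()
    return ndimage.affine_transform(
        np.asarray(image, dtype=float),
        inv.linear,
        offset=inv.offset,
        output_shape=output_shape,
        order=order,
        mode="constant",
        cval=cval,
    )


def warp_mask(
    mask,
    transform: AffineTransform2D,
    target_shape: tuple[int, int],
) -> BinaryMask:
    """Nearest-neighbor warp of a binary mask; out-of-source pixels are false."""
    m = as_mask_array(mask)
    warped = warp_image(m.astype(float), transform, target_shape, order=0, cval=0.0)
    return BinaryMask(warped > 0.5)


def _feature_map(rgb: np.ndarray, stains: StainMatrix, counterstain: str) -> np.ndarray:
    """Lightly smoothed counterstain OD map (shared tissue signal)."""
    od = unmix(rgb_to_od(rgb), stains)[counterstain]
    return ndimage.gaussian_filter(od, 1.0)


def _downsample(img: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return img
    return ndimage.zoom(ndimage.gaussian_filter(img, factor / 2.0), 1.0 / factor, order=1)


def _ncc(warped: np.ndarray, fixed: np.ndarray, valid: np.ndarray) -> float:
    if valid.sum() < 32:
        return -1.0
    a = warped[valid]
    b = fixed[valid]
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return -1.0
    return float((a * b).sum() / denom)


def _score(params, model, moving, fixed, center, ones) -> float:
    t = _params_to_transform(params, model, center)
    inv = t.inverse()
    warped = ndimage.affine_transform(
        moving, inv.linear, offset=inv.offset, output_shape=fixed.shape, order=1
    )
    valid = (
        ndimage.affine_transform(
            ones, inv.linear, offset=inv.offset, output_shape=fixed.shape, order=0
        )
        > 0.5
    )
    return _ncc(warped, fixed, valid)


def _params_to_transform(params, model, center) -> AffineTransform2D:
    if model == "translation":
        return AffineTransform2D.similarity(0.0, 1.0, (params[0], params[1]), center)
    if model == "rigid":
        return AffineTransform2D.similarity(params[2], 1.0, (params[0], params[1]), center)
    if model == "similarity":
        return AffineTransform2D.similarity(
            params[2], 1.0 + params[3] / 100.0, (params[0], params[1]), center
        )
    # affine: 6 raw entries, parameterized as offsets from identity about center
    lin = np.array([[1.0 + params[2], params[3]], [params[4], 1.0 + params[5]]])
    c = np.asarray(center, dtype=float)
    off = c + np.array([params[0], params[1]]) - lin @ c
    return AffineTransform2D(np.column_stack([lin, off]))


def register(
    moving: np.ndarray,
    fixed: np.ndarray,
    model: str = "similarity",
    n_levels: int = 3,
    max_rotation_deg: float = 6.0,
    scale_range: float = 0.06,
    moving_stains: StainMatrix = DEFAULT_IHC_STAINS,
    fixed_stains: StainMatrix = DEFAULT_ISH_STAINS,
    moving_counterstain: str = "hematoxylin",
    fixed_counterstain: str = "nuclear_fast_red",
) -> RegistrationResult:
    """Estimate the transform mapping ``moving`` (IHC) onto ``fixed`` (ISH).

    Deterministic coarse-to-fine search: at the coarsest pyramid level every
    rotation/scale grid point is initialised with an FFT cross-correlation
    translation estimate; the best candidates are refined by Powell's method
    at successively finer levels against the NCC objective.
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    if min(moving.shape[:2]) < 64 or min(fixed.shape[:2]) < 64:
        raise ValueError("images must be at least 64x64")

    feat_m = _feature_map(moving, moving_stains, moving_counterstain)
    feat_f = _feature_map(fixed, fixed_stains, fixed_counterstain)
    if rgb_to_od(moving).sum() / moving[..., 0].size < 1e-3:
        raise NoTissueError("no tissue signal in moving image")
    if rgb_to_od(fixed).sum() / fixed[..., 0].size < 1e-3:
        raise NoTissueError("no tissue signal in fixed image")

    center = ((fixed.shape[0] - 1) / 2.0, (fixed.shape[1] - 1) / 2.0)
    factors = [2 ** (n_levels - 1 - i) for i in range(n_levels)]  # e.g. [4, 2, 1]
    factors[0] = max(factors[0], 1)
    pyr_m = [_downsample(feat_m, f) for f in factors]
    pyr_f = [_downsample(feat_f, f) for f in factors]

    # --- coarse multi-start over rotation x scale, translation by FFT ---
    f0 = factors[0]
    m0, fx0 = pyr_m[0], pyr_f[0]
    c0 = ((fx0.shape[0] - 1) / 2.0, (fx0.shape[1] - 1) / 2.0)
    ones0 = np.ones_like(m0)
    if model == "translation":
        angles, scales = [0.0], [0.0]
    elif model == "rigid":
        angles = list(np.arange(-max_rotation_deg, max_rotation_deg + 0.5, 1.0))
        scales = [0.0]
    else:
        angles = list(np.arange(-max_rotation_deg, max_rotation_deg + 0.5, 1.0))
        scales = list(np.arange(-100 * scale_range, 100 * scale_range + 0.1, 2.0))
    candidates = []
    for ang in angles:
        for s_pct in scales:
            pre = AffineTransform2D.similarity(ang, 1.0 + s_pct / 100.0, (0, 0), c0)
            inv = pre.inverse()
            rot = ndimage.affine_transform(
                m0, inv.linear, offset=inv.offset, output_shape=fx0.shape, order=1
            )
            shift, _, _ = phase_cross_correlation(
                fx0, rot, upsample_factor=4, normalization=None
            )
            params = [shift[0], shift[1], ang, s_pct]
            if model == "translation":
                p = params[:2]
            elif model == "rigid":
                p = params[:3]
            else:
                p = params
            score = _score(p, "similarity" if model == "affine" else model, m0, fx0, c0, ones0)
            candidates.append((score, p))
    candidates.sort(key=lambda c: -c[0])
    init_score_full = None

    # --- refine top candidates through the pyramid ---
    fit_model = "similarity" if model == "affine" else model
    survivors = candidates[:3]
    for li in range(1, n_levels):
        f = factors[li]
        mv, fx = pyr_m[li], pyr_f[li]
        c = ((fx.shape[0] - 1) / 2.0, (fx.shape[1] - 1) / 2.0)
        ones = np.ones_like(mv)
        rescale = factors[li - 1] / f
        refined = []
        for score, p in survivors:
            p = list(p)
            p[0] *= rescale
            p[1] *= rescale
            res = optimize.minimize(
                lambda q: -_score(q, fit_model, mv, fx, c, ones),
                np.asarray(p, dtype=float),
                method="Powell",
                options={"xtol": 1e-3, "ftol": 1e-7, "maxiter": 400},
            )
            refined.append((-res.fun, list(res.x), bool(res.success)))
        refined.sort(key=lambda r: -r[0])
        survivors = [(r[0], r[1]) for r in refined[: (2 if li < n_levels - 1 else 1)]]
        converged = refined[0][2]

    best_score, best_p = survivors[0]
    mv, fx = pyr_m[-1], pyr_f[-1]
    c = ((fx.shape[0] - 1) / 2.0, (fx.shape[1] - 1) / 2.0)
    ones = np.ones_like(mv)
    init_score_full = _score(
        [0.0] * len(best_p), fit_model, mv, fx, c, ones
    )

    if model == "affine":
        sim = _params_to_transform(best_p, "similarity", c)
        lin = sim.linear
        p6 = [
            best_p[0],
            best_p[1],
            lin[0, 0] - 1.0,
            lin[0, 1],
            lin[1, 0],
            lin[1, 1] - 1.0,
        ]
        # translation component must be re-derived in the 6-param chart
        t_at_c = sim.apply(np.asarray(c))[0] - np.asarray(c)
        p6[0], p6[1] = t_at_c[0], t_at_c[1]
        res = optimize.minimize(
            lambda q: -_score(q, "affine", mv, fx, c, ones),
            np.asarray(p6, dtype=float),
            method="Powell",
            options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 600},
        )
        best_score, best_p = -res.fun, list(res.x)
        converged = bool(res.success)
        transform = _params_to_transform(best_p, "affine", c)
    else:
        transform = _params_to_transform(best_p, fit_model, c)

    return RegistrationResult(
        transform=transform,
        similarity_final=float(best_score),
        similarity_init=float(init_score_full),
        n_levels=n_levels,
        converged=bool(converged),
        model=model,
    )
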