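"""Stain separation for brightfield histology images.

Converts 8-bit RGB transmitted-light images to optical density (OD) via
Beer-Lambert, unmixes OD into per-stain concentration maps against a named
stain matrix, and binarizes a chromogen map by Otsu or a fixed OD threshold.

The two default stain matrices cover the slide pair this package analyses:
an epithelium-marker IHC slide (brown DAB chromogen on a hematoxylin
counterstain) and a chromogenic ISH slide (blue NBT/BCIP precipitate on a
nuclear-fast-red counterstain). DAB and hematoxylin vectors are the
Ruifrok-Johnston values; NBT/BCIP colorimetry is not standardized, so its
vector (and nuclear fast red's) defaults to the rendering matrix of the
synthetic generator and is user-configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from skimage.filters import threshold_otsu, threshold_triangle

__all__ = [
    "StainMatrix",
    "StainODMaps",
    "BinaryMask",
    "SingularStainError",
    "DEFAULT_IHC_STAINS",
    "DEFAULT_ISH_STAINS",
    "rgb_to_od",
    "od_to_rgb",
    "unmix",
    "threshold_stain",
]


class SingularStainError(ValueError):
    """Raised when stain vectors are collinear (unmixing is singular)."""


def _as_unit_rows(vectors: np.ndarray) -> np.ndarray:
    v = np.asarray(vectors, dtype=float)
    if v.ndim != 2 or v.shape[1] != 3:
        raise ValueError("stain vectors must be an (n_stains, 3) array")
    if np.any(v < 0):
        raise ValueError("stain OD vectors must be non-negative")
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms == 0):
        raise ValueError("stain OD vectors must be non-zero")
    return v / norms[:, None]


@dataclass(frozen=True)
class StainMatrix:
    """Named unit vectors in 3-channel OD space, one row per stain."""

    names: tuple[str, ...]
    vectors: np.ndarray  # (n_stains, 3), unit L2 rows

    def __init__(self, stains: Mapping[str, Sequence[float]]):
        if not 1 <= len(stains) <= 3:
            raise ValueError("a stain matrix holds 1-3 stains")
        names = tuple(stains.keys())
        vectors = _as_unit_rows(np.array([stains[n] for n in names]))
        if len(names) > 1:
            s = np.linalg.svd(vectors, compute_uv=False)
            if s[-1] < 1e-6 * s[0]:
                raise SingularStainError(
                    "stain vectors are collinear; unmixing would be singular"
                )
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "vectors", vectors)

    def __len__(self) -> int:
        return len(self.names)

    def vector(self, name: str) -> np.ndarray:
        return self.vectors[self.names.index(name)]

    def to_json(self, path: str | Path) -> None:
        payload = {n: [float(x) for x in v] for n, v in zip(self.names, self.vectors)}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "StainMatrix":
        return cls(json.loads(Path(path).read_text()))


# Ruifrok & Johnston OD vectors for hematoxylin and DAB.
_HEMATOXYLIN = (0.650, 0.704, 0.286)
_DAB = (0.268, 0.570, 0.776)
# Blue alkaline-phosphatase (NBT/BCIP) precipitate: absorbs red/green, transmits blue.
_NBT_BCIP = (0.780, 0.569, 0.261)
# Nuclear fast red counterstain (fast-red-like vector).
_NUCLEAR_FAST_RED = (0.214, 0.851, 0.478)

DEFAULT_IHC_STAINS = StainMatrix({"hematoxylin": _HEMATOXYLIN, "dab": _DAB})
DEFAULT_ISH_STAINS = StainMatrix(
    {"nuclear_fast_red": _NUCLEAR_FAST_RED, "nbt_bcip": _NBT_BCIP}
)


@dataclass
class StainODMaps:
    """Per-stain 2D optical-density maps from a single unmixed image."""

    maps: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.maps.values()}
        if len(shapes) > 1:
            raise ValueError("all stain maps must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.maps.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.maps[name]

    def total(self) -> np.ndarray:
        return np.sum(list(self.maps.values()), axis=0)


@dataclass
class BinaryMask:
    """2D boolean mask with optional physical pixel size and provenance metadata."""

    data: np.ndarray
    pixel_size_um: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 2:
            raise ValueError("mask must be 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def __array__(self, dtype=None, copy=None):
        return self.data.astype(dtype) if dtype is not None else self.data


def as_mask_array(mask) -> np.ndarray:
    """Coerce a BinaryMask or array-like to a 2D bool ndarray."""
    if isinstance(mask, BinaryMask):
        return mask.data
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError("mask must be 2D")
    return arr.astype(bool)


def rgb_to_od(image: np.ndarray) -> np.ndarray:
    """Beer-Lambert conversion of an 8-bit RGB image to optical density.

    OD_c = -log10((I_c + 1) / 256) per channel; the +1/256 offset avoids
    log(0) and makes the transform exactly invertible on integer inputs.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    return -np.log10((img.astype(float) + 1.0) / 256.0)


def od_to_rgb(od: np.ndarray, quantize: bool = True) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`: I_c = 256 * 10**(-OD_c) - 1."""
    intensity = 256.0 * np.power(10.0, -np.asarray(od, dtype=float)) - 1.0
    intensity = np.clip(intensity, 0.0, 255.0)
    if quantize:
        return np.round(intensity).astype(np.uint8)
    return intensity


def unmix(od: np.ndarray, stains: StainMatrix) -> StainODMaps:
    """Least-squares projection of per-pixel OD vectors onto the stain basis.

    Concentrations minimise ||S^T c - od|| per pixel (pseudo-inverse of the
    stain matrix); negative concentrations are clamped to zero.
    """
    od = np.asarray(od, dtype=float)
    if od.ndim != 3 or od.shape[2] != 3:
        raise ValueError("expected a 3-channel OD array of shape (H, W, 3)")
    pinv = np.linalg.pinv(stains.vectors.T)  # (n_stains, 3)
    conc = od.reshape(-1, 3) @ pinv.T
    conc = np.clip(conc, 0.0, None).reshape(od.shape[:2] + (len(stains),))
    return StainODMaps({n: conc[..., i] for i, n in enumerate(stains.names)})


def threshold_stain(
    stain_map: np.ndarray,
    method: str = "triangle",
    fixed_value: float | None = None,
) -> BinaryMask:
    """Binarize one stain-OD map; positive where OD >= the chosen threshold.

    The default triangle method suits chromogen OD maps, whose histogram is
    a large near-zero background spike plus a skewed positive tail: it puts
    the threshold at the foot of the background peak. Otsu is offered but
    biases high on such zero-inflated distributions (it balances class
    variances, clipping the low tail of the positive class). The threshold
    actually used is recorded in the returned mask's metadata.
    """
    stain_map = np.asarray(stain_map, dtype=float)
    if not np.all(np.isfinite(stain_map)):
        raise ValueError("stain map contains non-finite values")
    if method == "fixed":
        if fixed_value is None or fixed_value <= 0:
            raise ValueError("method='fixed' requires fixed_value > 0")
        thresh = float(fixed_value)
    elif method in ("otsu", "triangle"):
        if np.ptp(stain_map) == 0:
            raise ValueError(
                f"constant-valued map: {method} is undefined; use method='fixed' "
                "with an explicit OD threshold"
            )
        fn = threshold_otsu if method == "otsu" else threshold_triangle
        thresh = float(fn(stain_map))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return BinaryMask(stain_map >= thresh, meta={"threshold": thresh, "method": method})
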