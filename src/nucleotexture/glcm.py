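"""Gray-level co-occurrence matrices and the six texture features.

For a quantized ROI the co-occurrence matrix p(i, j) is the normalized
joint distribution of gray levels at pixel pairs separated by a fixed
displacement (distance d, angle θ). Only pairs with BOTH endpoints inside
the ROI mask are counted ("Clear Outside" semantics: cleared background
never contaminates nuclear texture). From p(i, j) six classical features
are derived:

    ASM  = Σ p(i,j)²                       angular second moment (uniformity)
    IDM  = Σ p(i,j) / (1 + (i−j)²)         inverse difference moment (homogeneity)
    CON  = Σ (i−j)^k · p(i,j)^n            contrast (k=2, n=1 by default)
    COR  = (Σ ij·p(i,j) − μxμy) / (σxσy)   correlation (gray-level linear dependency)
    SA   = Σ s·p_{x+y}(s)                  sum average
    SVAR = Σ (s − SA)²·p_{x+y}(s)          sum variance

where p_{x+y}(s) = Σ_{i+j=s} p(i,j) is the gray-level sum distribution.
By default one matrix is built per angle in {0°, 45°, 90°, 135°} at d=1
and the features are averaged over angles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ingest import GrayPatch

__all__ = [
    "GLCMatrix",
    "GLCMMarginals",
    "GLCMFeatureConfig",
    "GLCMFeatures",
    "FEATURE_NAMES",
    "angle_to_offset",
    "compute_glcm",
    "glcm_features",
    "patch_glcm_features",
]

FEATURE_NAMES = ("ASM", "IDM", "CON", "COR", "SA", "SVAR")

DEFAULT_ANGLES = (0, 45, 90, 135)

#: displacement (dy, dx) per unit distance for the four standard angles,
#: with rows increasing downward (so 45° points up-right).
_ANGLE_STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def angle_to_offset(angle: int, distance: int = 1) -> tuple[int, int]:
    """Map an angle in {0, 45, 90, 135} degrees and a distance to (dy, dx)."""
    if angle not in _ANGLE_STEPS:
        raise ValueError(f"angle must be one of {sorted(_ANGLE_STEPS)}, got {angle}")
    dy, dx = _ANGLE_STEPS[angle]
    return dy * distance, dx * distance


@dataclass(frozen=True)
class GLCMFeatureConfig:
    """Offset and feature policy for co-occurrence analysis.

    ``contrast_k``/``contrast_n`` are the exponents of the generalized
    contrast Σ (i−j)^k p^n; (2, 1) is the classical Haralick contrast.
    """

    distance: int = 1
    angles: tuple[int, ...] = DEFAULT_ANGLES
    direction_averaging: bool = True
    contrast_k: int = 2
    contrast_n: int = 1
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.distance < 1:
            raise ValueError("distance must be ≥ 1")
        if self.contrast_k < 1 or self.contrast_n < 1:
            raise ValueError("contrast exponents must be ≥ 1")
        for a in self.angles:
            if a not in _ANGLE_STEPS:
                raise ValueError(f"unsupported angle {a}")


@dataclass
class GLCMatrix:
    """A normalized co-occurrence matrix with its offset metadata."""

    p: np.ndarray
    levels: int
    offsets: tuple[tuple[int, int], ...]
    symmetric: bool
    pair_count: int

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        if self.p.shape != (self.levels, self.levels):
            raise ValueError("matrix shape must be G×G")
        total = self.p.sum()
        if not math.isclose(total, 1.0, abs_tol=1e-12):
            raise ValueError(f"matrix must be normalized to 1, sums to {total}")

    def marginals(self) -> "GLCMMarginals":
        return GLCMMarginals.from_matrix(self)


@dataclass
class GLCMMarginals:
    """Row/column marginals and the gray-level sum distribution of a GLCM."""

    p_x: np.ndarray
    p_y: np.ndarray
    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float
    p_sum: np.ndarray  # p_{x+y}(s), s in [0, 2G−2]

    @classmethod
    def from_matrix(cls, m: GLCMatrix) -> "GLCMMarginals":
        g = m.levels
        p_x = m.p.sum(axis=1)
        p_y = m.p.sum(axis=0)
        idx = np.arange(g, dtype=np.float64)
        mu_x = float(idx @ p_x)
        mu_y = float(idx @ p_y)
        sigma_x = float(np.sqrt(max(((idx - mu_x) ** 2) @ p_x, 0.0)))
        sigma_y = float(np.sqrt(max(((idx - mu_y) ** 2) @ p_y, 0.0)))
        ii, jj = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
        p_sum = np.bincount((ii + jj).ravel(), weights=m.p.ravel(), minlength=2 * g - 1)
        return cls(p_x, p_y, mu_x, mu_y, sigma_x, sigma_y, p_sum)


@dataclass(frozen=True)
class GLCMFeatures:
    """The six GLCM feature values of one matrix (or an angle average).

    ``cor`` is NaN when the matrix is degenerate (σx·σy = 0), e.g. for a
    constant ROI; downstream statistics must treat NaN as "undefined".
    """

    asm: float
    idm: float
    con: float
    cor: float
    sa: float
    svar: float

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, (self.asm, self.idm, self.con, self.cor, self.sa, self.svar)))


def compute_glcm(patch: GrayPatch, config: GLCMFeatureConfig = GLCMFeatureConfig()) -> list[GLCMatrix]:
    """Accumulate one normalized co-occurrence matrix per configured angle.

    Counts run over all pixel pairs ``(r, c) → (r+dy, c+dx)`` whose both
    endpoints lie inside the mask; with ``symmetric`` each pair is counted
    in both orders. Raises ``ValueError`` (naming the offset) when an
    offset admits no valid pair.
    """
    g = patch.levels
    img = np.asarray(patch.intensities, dtype=np.int64)
    mask = patch.mask
    h, w = img.shape
    out: list[GLCMatrix] = []
    for angle in config.angles:
        dy, dx = angle_to_offset(angle, config.distance)
        r0, r1 = max(0, -dy), min(h, h - dy)
        c0, c1 = max(0, -dx), min(w, w - dx)
        if r0 >= r1 or c0 >= c1:
            raise ValueError(f"no valid pixel pairs for offset (dy={dy}, dx={dx})")
        a = img[r0:r1, c0:c1]
        b = img[r0 + dy : r1 + dy, c0 + dx : c1 + dx]
        valid = mask[r0:r1, c0:c1] & mask[r0 + dy : r1 + dy, c0 + dx : c1 + dx]
        if not valid.any():
            raise ValueError(f"no valid pixel pairs for offset (dy={dy}, dx={dx})")
        counts = np.bincount(
            (a[valid] * g + b[valid]).ravel(), minlength=g * g
        ).reshape(g, g).astype(np.float64)
        if config.symmetric:
            counts = counts + counts.T
        pair_count = int(counts.sum())
        out.append(
            GLCMatrix(
                p=counts / counts.sum(),
                levels=g,
                offsets=((dy, dx),),
                symmetric=config.symmetric,
                pair_count=pair_count,
            )
        )
    return out


def _features_single(m: GLCMatrix, config: GLCMFeatureConfig) -> GLCMFeatures:
    g = m.levels
    p = m.p
    ii, jj = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
    diff = ii - jj

    asm = float(np.sum(p * p))
    idm = float(np.sum(p / (1.0 + diff.astype(np.float64) ** 2)))
    con = float(np.sum((diff.astype(np.float64) ** config.contrast_k) * (p**config.contrast_n)))

    marg = m.marginals()
    if marg.sigma_x * marg.sigma_y == 0.0:
        cor = float("nan")
    else:
        cor = float((np.sum(ii * jj * p) - marg.mu_x * marg.mu_y) / (marg.sigma_x * marg.sigma_y))

    s = np.arange(2 * g - 1, dtype=np.float64)
    sa = float(s @ marg.p_sum)
    svar = float(((s - sa) ** 2) @ marg.p_sum)
    return GLCMFeatures(asm=asm, idm=idm, con=con, cor=cor, sa=sa, svar=svar)


def glcm_features(
    matrices: GLCMatrix | Sequence[GLCMatrix],
    config: GLCMFeatureConfig = GLCMFeatureConfig(),
) -> GLCMFeatures:
    """Compute the six features; with direction averaging, the arithmetic
    mean over the per-angle matrices (NaN COR propagates: a ROI degenerate
    in any direction has undefined correlation)."""
    if isinstance(matrices, GLCMatrix):
        matrices = [matrices]
    per_angle = [_features_single(m, config) for m in matrices]
    if len(per_angle) == 1 or not config.direction_averaging:
        if len(per_angle) == 1:
            return per_angle[0]
        raise ValueError("direction_averaging is off but several matrices were given")
    arr = np.array([[f.asm, f.idm, f.con, f.cor, f.sa, f.svar] for f in per_angle])
    mean = arr.mean(axis=0)  # NaN COR propagates deliberately
    return GLCMFeatures(*map(float, mean))


def patch_glcm_features(
    patch: GrayPatch, config: GLCMFeatureConfig = GLCMFeatureConfig()
) -> GLCMFeatures:
    """Convenience: accumulate the per-angle matrices and average features."""
    return glcm_features(compute_glcm(patch, config), config)
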