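"""Shared fixtures and independent oracles.

The brute-force co-occurrence oracle enumerates every pixel pair with an
explicit double loop and computes the six features directly from their
defining sums — deliberately naive and independent of the vectorized
implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from nucleotexture.ingest import GrayPatch
from nucleotexture.synthetic import _ellipse_mask


def brute_force_glcm(
    img: np.ndarray, mask: np.ndarray, dy: int, dx: int, levels: int, symmetric: bool = True
) -> np.ndarray:
    """Pixel-pair enumeration by double loop; normalized G×G matrix."""
    counts = np.zeros((levels, levels))
    h, w = img.shape
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dy, c + dx
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                counts[img[r, c], img[r2, c2]] += 1
                if symmetric:
                    counts[img[r2, c2], img[r, c]] += 1
    total = counts.sum()
    assert total > 0, "oracle: no valid pairs"
    return counts / total


def brute_force_features(p: np.ndarray, k: int = 2, n: int = 1) -> dict[str, float]:
    """Six features straight from their defining sums over p(i, j)."""
    g = p.shape[0]
    asm = idm = con = sij = 0.0
    p_x = p.sum(axis=1)
    p_y = p.sum(axis=0)
    mu_x = sum(i * p_x[i] for i in range(g))
    mu_y = sum(j * p_y[j] for j in range(g))
    sig_x = math.sqrt(sum((i - mu_x) ** 2 * p_x[i] for i in range(g)))
    sig_y = math.sqrt(sum((j - mu_y) ** 2 * p_y[j] for j in range(g)))
    p_sum = np.zeros(2 * g - 1)
    for i in range(g):
        for j in range(g):
            asm += p[i, j] ** 2
            idm += p[i, j] / (1 + (i - j) ** 2)
            con += (i - j) ** k * p[i, j] ** n
            sij += i * j * p[i, j]
            p_sum[i + j] += p[i, j]
    cor = float("nan") if sig_x * sig_y == 0 else (sij - mu_x * mu_y) / (sig_x * sig_y)
    sa = sum(s * p_sum[s] for s in range(2 * g - 1))
    svar = sum((s - sa) ** 2 * p_sum[s] for s in range(2 * g - 1))
    return {"ASM": asm, "IDM": idm, "CON": con, "COR": cor, "SA": sa, "SVAR": svar}


def random_masked_patch(
    rng: np.random.Generator, size: int = 16, levels: int = 8
) -> GrayPatch:
    """A random quantized patch with a random elliptical mask."""
    while True:
        a = rng.uniform(3.0, size / 2 - 1)
        b = rng.uniform(3.0, size / 2 - 1)
        theta = rng.uniform(0, np.pi)
        mask = _ellipse_mask(size, a, b, theta)
        if mask.sum() >= 16:
            break
    img = rng.integers(0, levels, (size, size))
    return GrayPatch(intensities=img, mask=mask, levels=levels)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231003)
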