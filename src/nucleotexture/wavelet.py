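"""First-level 2-D Haar subband energies over masked ROIs.

The ROI's raw (unquantized) 8-bit grayscale patch is decomposed with an
orthonormal Haar analysis on non-overlapping 2×2 blocks. For a block

    [[a, b],
     [c, d]]        (x rightward, y downward)

the four subband coefficients are

    LL = (a+b+c+d)/2    LH = (a−b+c−d)/2
    HL = (a+b−c−d)/2    HH = (a−b−c+d)/2

Subband naming: first letter = filter along y (rows), second = filter
along x (columns); LH therefore responds to variation along x, HL along
y, HH to diagonal/checkerboard structure. The transform is orthonormal,
so Σ pixel² equals the total coefficient energy over all four subbands
(Parseval).

Per-subband energy is the mean squared coefficient over the coefficients
whose 2×2 support touches the ROI:

    E = Σ_included d² / n,    n = number of included coefficients.

Pixels outside the mask are filled with the rounded mean of masked-in
pixels before the transform; odd dimensions are padded by edge
replication. A coefficient is included iff its 2×2 support contains at
least one masked-in pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ingest import GrayPatch

__all__ = ["WaveletSubbands", "WaveletEnergies", "haar_decompose", "subband_energies",
           "patch_wavelet_energies", "ENERGY_NAMES"]

ENERGY_NAMES = ("EnLH", "EnHL", "EnHH")
SUBBANDS = ("LL", "LH", "HL", "HH")


@dataclass
class WaveletSubbands:
    """Level-1 Haar coefficients per subband with the inclusion mask."""

    coefficients: dict[str, np.ndarray]  # keys LL, LH, HL, HH
    included: np.ndarray  # boolean, same shape as each subband
    scale: int = 1

    @property
    def n(self) -> int:
        """Number of included coefficients per subband."""
        return int(self.included.sum())


@dataclass(frozen=True)
class WaveletEnergies:
    """Mean squared detail-coefficient magnitude per subband (intensity²)."""

    en_lh: float
    en_hl: float
    en_hh: float

    def as_dict(self) -> dict[str, float]:
        return dict(zip(ENERGY_NAMES, (self.en_lh, self.en_hl, self.en_hh)))


def haar_decompose(patch: GrayPatch, use_raw: bool = True) -> WaveletSubbands:
    """Level-1 orthonormal Haar decomposition of a masked patch.

    ``use_raw`` selects the original 8-bit grayscale values (the default;
    gray-level quantization is a co-occurrence-specific step); pass False
    to transform the quantized levels instead.
    """
    x = np.asarray(patch.raw if use_raw else patch.intensities, dtype=np.float64)
    mask = patch.mask
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("patch must be at least 2×2 for a level-1 decomposition")

    fill = float(np.rint(x[mask].mean()))
    x = np.where(mask, x, fill)

    pad_r = x.shape[0] % 2
    pad_c = x.shape[1] % 2
    if pad_r or pad_c:
        x = np.pad(x, ((0, pad_r), (0, pad_c)), mode="edge")
        mask = np.pad(mask, ((0, pad_r), (0, pad_c)), mode="edge")

    a = x[0::2, 0::2]
    b = x[0::2, 1::2]
    c = x[1::2, 0::2]
    d = x[1::2, 1::2]
    coeffs = {
        "LL": (a + b + c + d) / 2.0,
        "LH": (a - b + c - d) / 2.0,
        "HL": (a + b - c - d) / 2.0,
        "HH": (a - b - c + d) / 2.0,
    }
    blocks = mask[0::2, 0::2] | mask[0::2, 1::2] | mask[1::2, 0::2] | mask[1::2, 1::2]
    return WaveletSubbands(coefficients=coeffs, included=blocks, scale=1)


def subband_energies(sb: WaveletSubbands) -> WaveletEnergies:
    """E = Σ d² / n over included coefficients, for LH, HL and HH."""
    n = sb.n
    if n < 1:
        raise ValueError("no included coefficients in subbands")
    vals = {}
    for name in ("LH", "HL", "HH"):
        d = sb.coefficients[name][sb.included]
        vals[name] = float(np.sum(d * d) / n)
    return WaveletEnergies(en_lh=vals["LH"], en_hl=vals["HL"], en_hh=vals["HH"])


def patch_wavelet_energies(patch: GrayPatch, use_raw: bool = True) -> WaveletEnergies:
    """Convenience: decompose and return the three detail energies."""
    return subband_energies(haar_decompose(patch, use_raw=use_raw))
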