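"""GLCM texture features of QUS parametric maps.

Each map is quantized inside the ROI and 16 grey-level co-occurrence
matrices are built — four interpixel distances (1, 2, 3, 4 pixels) by four
directions (0, 45, 90, 135 degrees) — from which the four Haralick scalars
are computed and averaged:

    CON = sum p(i,j) (i - j)^2
    COR = sum p(i,j) (i - mu_i)(j - mu_j) / (sigma_i sigma_j)
    ENE = sum p(i,j)^2
    HOM = sum p(i,j) / (1 + |i - j|)

Only pixel pairs with both members inside the ROI are counted; matrices are
symmetric (pairs counted in both directions) and normalized to sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GLCM_DISTANCES",
    "GLCM_ANGLES",
    "GLCM",
    "TextureFeatures",
    "quantize_map",
    "compute_glcm",
    "glcm_features",
    "texture_summary",
]

GLCM_DISTANCES = (1, 2, 3, 4)
GLCM_ANGLES = (0, 45, 90, 135)

#: (row, col) unit offsets per angle; diagonal angles move d pixels in both
#: axes (chessboard convention). Angles follow the usual image convention:
#: 0 deg is along a row, 90 deg up a column.
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass
class GLCM:
    """Symmetric normalized co-occurrence matrix at one (distance, angle)."""

    matrix: np.ndarray
    distance: int
    angle: int
    n_levels: int

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (self.n_levels, self.n_levels):
            raise ValueError("GLCM shape does not match n_levels")
        if np.any(m < 0) or not np.isclose(m.sum(), 1.0):
            raise ValueError("GLCM must be a probability matrix")


@dataclass(frozen=True)
class TextureFeatures:
    contrast: float
    correlation: float
    energy: float
    homogeneity: float

    def as_dict(self) -> dict:
        return {"CON": self.contrast, "COR": self.correlation,
                "ENE": self.energy, "HOM": self.homogeneity}


def quantize_map(map_values: np.ndarray, roi: np.ndarray,
                 n_levels: int = 16):
    """Uniform min-max quantization of in-ROI values into n_levels bins.

    Non-finite pixels are dropped from the validity mask. A constant map
    quantizes to level 0 everywhere. Returns (levels image, validity mask).
    """
    valid = roi & np.isfinite(map_values)
    if not np.any(valid):
        raise ValueError("empty ROI")
    vals = map_values[valid]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(map_values.shape, dtype=np.intp)
    if hi > lo:
        scaled = (map_values - lo) / (hi - lo) * n_levels
        levels[valid] = np.clip(scaled[valid].astype(np.intp), 0, n_levels - 1)
    return levels, valid


def compute_glcm(image: np.ndarray, mask: np.ndarray, distance: int,
                 angle: int, n_levels: int | None = None) -> GLCM:
    """Count co-occurring level pairs at one offset, mask-aware.

    A pair contributes only if both pixels are inside the mask; pairs are
    counted bidirectionally, making the matrix symmetric.
    """
    if angle not in _ANGLE_OFFSETS:
        raise ValueError(f"angle must be one of {GLCM_ANGLES}")
    if distance < 1:
        raise ValueError("distance must be >= 1")
    n_levels = n_levels or int(image.max()) + 1
    dr, dc = (distance * o for o in _ANGLE_OFFSETS[angle])
    rows, cols = image.shape
    r0, r1 = max(0, -dr), min(rows, rows - dr)
    c0, c1 = max(0, -dc), min(cols, cols - dc)
    src = np.s_[r0:r1, c0:c1]
    dst = np.s_[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    both = mask[src] & mask[dst]
    if not np.any(both):
        raise ValueError("no co-occurring pairs")
    i = image[src][both]
    j = image[dst][both]
    counts = np.zeros((n_levels, n_levels))
    np.add.at(counts, (i, j), 1.0)
    counts = counts + counts.T
    return GLCM(matrix=counts / counts.sum(), distance=distance, angle=angle,
                n_levels=n_levels)


def glcm_features(glcm: GLCM) -> TextureFeatures:
    """Haralick contrast, correlation, energy, homogeneity of one GLCM.

    Correlation is defined as 0 when either marginal has zero variance
    (e.g. a constant image).
    """
    p = glcm.matrix
    idx = np.arange(glcm.n_levels, dtype=float)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    con = float(np.sum(p * (ii - jj) ** 2))
    ene = float(np.sum(p**2))
    hom = float(np.sum(p / (1.0 + np.abs(ii - jj))))
    pi = p.sum(axis=1)
    mu = float(np.sum(idx * pi))
    var = float(np.sum((idx - mu) ** 2 * pi))
    if var <= 0:
        cor = 0.0
    else:
        cor = float(np.sum(p * (ii - mu) * (jj - mu)) / var)
    return TextureFeatures(contrast=con, correlation=cor, energy=ene,
                           homogeneity=hom)


def glcm_configurations() -> list:
    """The 16 (distance, angle) GLCM configurations."""
    return [(d, a) for d in GLCM_DISTANCES for a in GLCM_ANGLES]


def texture_summary(map_values: np.ndarray, roi: np.ndarray,
                    n_levels: int = 16) -> TextureFeatures:
    """Mean of each Haralick feature over the 16 (distance, angle) GLCMs."""
    levels, valid = quantize_map(map_values, roi, n_levels)
    feats = [
        glcm_features(compute_glcm(levels, valid, d, a, n_levels))
        for d, a in glcm_configurations()
    ]
    return TextureFeatures(
        contrast=float(np.mean([f.contrast for f in feats])),
        correlation=float(np.mean([f.correlation for f in feats])),
        energy=float(np.mean([f.energy for f in feats])),
        homogeneity=float(np.mean([f.homogeneity for f in feats])),
    )
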