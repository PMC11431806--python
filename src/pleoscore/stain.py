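"""H&E stain unmixing in optical-density space.

RGB transmission images are converted to optical density (OD), where
Beer–Lambert absorption makes stain contributions linear.  The two stain
directions are estimated from the data by SVD of the foreground OD cloud
(Macenko-style extreme-angle percentiles), and per-pixel hematoxylin
concentration is recovered by least-squares projection onto the stain
plane.  Chromatin analysis downstream runs on the hematoxylin plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Canonical hematoxylin / eosin OD absorption directions (Ruifrok–Johnston
#: averages); used only to label the two data-derived stain vectors.
HEMATOXYLIN_OD = np.array([0.650, 0.704, 0.286])
EOSIN_OD = np.array([0.072, 0.990, 0.105])


class InsufficientSignalError(ValueError):
    """Raised when a tile has too few stained pixels to estimate a basis."""


@dataclass(frozen=True)
class ODImage:
    """Per-pixel, per-channel optical density of an RGB tile."""

    od: np.ndarray  # (rows, cols, 3), float, >= 0
    source_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.od.ndim != 3 or self.od.shape[2] != 3:
            raise ValueError(f"OD array must be (rows, cols, 3), got {self.od.shape}")
        if not np.all(np.isfinite(self.od)) or self.od.min() < 0:
            raise ValueError("OD values must be finite and non-negative")


@dataclass(frozen=True)
class StainBasis:
    """Unit OD direction vectors for the two stains."""

    h_vector: np.ndarray
    e_vector: np.ndarray

    def __post_init__(self) -> None:
        for name, v in (("h_vector", self.h_vector), ("e_vector", self.e_vector)):
            if v.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
            if not np.isclose(np.linalg.norm(v), 1.0, atol=1e-6):
                raise ValueError(f"{name} must be unit-norm")
            if v.min() < -1e-12:
                raise ValueError(f"{name} components must be non-negative")
        if self.angle() < 1e-6:
            raise ValueError("stain vectors must not be parallel")

    def angle(self) -> float:
        """Angle (rad) between the two stain directions."""
        c = float(np.clip(np.dot(self.h_vector, self.e_vector), -1.0, 1.0))
        return float(np.arccos(c))


def rgb_to_od(rgb: np.ndarray, i0: float = 255.0, floor: float = 1.0) -> ODImage:
    """Convert an 8-bit RGB tile to optical density.

    OD = -log10(I / i0) per channel, with intensities clipped to ``floor``
    so fully black pixels stay finite.  A pixel at ``i0`` maps to OD 0
    exactly.

    Parameters
    ----------
    rgb:
        (rows, cols, 3) array, values in [0, 255].
    i0:
        Maximum transmitted intensity (default 255 for 8-bit input).
    floor:
        Lower intensity clip applied before the log (default 1).
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected a 3-channel RGB image, got shape {rgb.shape}")
    if i0 <= 0:
        raise ValueError("i0 must be positive")
    intensity = np.clip(rgb.astype(np.float64), floor, i0)
    od = -np.log10(intensity / i0)
    od = np.maximum(od, 0.0)
    return ODImage(od=od, source_shape=rgb.shape[:2])


def estimate_stain_basis(
    od: ODImage,
    beta: float = 0.15,
    angle_percentile: float = 1.0,
) -> StainBasis:
    """Estimate H and E stain directions from the OD pixel cloud.

    Foreground pixels (any channel OD above ``beta``) are projected onto
    the plane of their two leading singular directions; the vectors at the
    ``angle_percentile`` / ``100 - angle_percentile`` extremes of the
    in-plane angle distribution are taken as the two stains.  The stain
    closer (in cosine similarity) to the canonical hematoxylin direction
    is returned as ``h_vector``.
    """
    pixels = od.od.reshape(-1, 3)
    fg = pixels[(pixels > beta).any(axis=1)]
    if fg.shape[0] < 2:
        raise InsufficientSignalError(
            f"only {fg.shape[0]} foreground pixels above OD {beta}; "
            "cannot estimate a stain basis"
        )
    # Plane of the two leading right singular vectors of the OD cloud.
    _, _, vt = np.linalg.svd(fg, full_matrices=False)
    plane = vt[:2]
    # Orient plane axes so projections are predominantly positive.
    for i in range(2):
        if plane[i].sum() < 0:
            plane[i] = -plane[i]
    proj = fg @ plane.T
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [angle_percentile, 100.0 - angle_percentile])
    if hi - lo < 1e-3:
        # One stain dominates the tile (e.g. a single-nucleus field): the
        # percentile angles collapse into the majority cluster.  Fall back
        # to the extreme angles.
        lo, hi = phi.min(), phi.max()
    v1 = np.cos(lo) * plane[0] + np.sin(lo) * plane[1]
    v2 = np.cos(hi) * plane[0] + np.sin(hi) * plane[1]

    def _clean(v: np.ndarray) -> np.ndarray:
        v = np.maximum(v, 0.0)
        n = np.linalg.norm(v)
        if n == 0:
            raise InsufficientSignalError("degenerate stain direction (all-negative)")
        return v / n

    v1, v2 = _clean(v1), _clean(v2)
    h_ref = HEMATOXYLIN_OD / np.linalg.norm(HEMATOXYLIN_OD)
    if np.dot(v1, h_ref) >= np.dot(v2, h_ref):
        return StainBasis(h_vector=v1, e_vector=v2)
    return StainBasis(h_vector=v2, e_vector=v1)


def extract_h_channel(od: ODImage, basis: StainBasis) -> np.ndarray:
    """Project OD onto the stain basis and return hematoxylin concentration.

    Per-pixel least squares against the two stain vectors (pseudo-inverse),
    with negative concentrations clamped to zero.  Output has the spatial
    shape of the input tile.
    """
    if basis.angle() < 1e-3:
        raise ValueError("stain basis is degenerate (near-parallel vectors)")
    m = np.stack([basis.h_vector, basis.e_vector], axis=1)  # (3, 2)
    pinv = np.linalg.pinv(m)  # (2, 3)
    conc = od.od.reshape(-1, 3) @ pinv.T
    conc = np.maximum(conc, 0.0)
    return conc[:, 0].reshape(od.source_shape)
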