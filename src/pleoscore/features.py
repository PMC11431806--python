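"""Per-nucleus morphological features: ESize, EShape, EAppearance.

The three elements quantify the Nottingham description of nuclear
pleomorphism:

``EPSize``
    Relative size excess over the benign reference area *k*:
    ``(Ar - k) / k``.  *k* is the mean pixel area of benign epithelial
    nuclei (849 px in the reference calibration).
``ESize``
    Piecewise rule on EPSize mapping the Nottingham size bands:
    0 below 0.5 (nucleus < 1.5x benign), the identity on [0.5, 1)
    (1.5-2x benign), and 1 at or above 1 (> 2x benign).
``EShape``
    Complement of the isoperimetric quotient, ``1 - 4*pi*Ar / Peri**2``,
    clamped to [0, 1]: 0 for a perfect circle, approaching 1 for
    elongated or bizarre outlines.
``EAppearance``
    Enclosed hollow-pixel fraction ``Hol / Ar`` in [0, 1], a proxy for
    vesicular chromatin and prominent nucleoli.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from pleoscore.regions import NucleusGeometry


@dataclass(frozen=True)
class SizeParams:
    """Benign reference area and the EPSize cut points of the size rule.

    ``k`` is in pixel area and therefore magnification-dependent; it must
    be calibrated at (or converted to) the resolution of the images being
    scored.
    """

    k: float = 849.0
    lower_cut: float = 0.5
    upper_cut: float = 1.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if not 0 < self.lower_cut < self.upper_cut:
            raise ValueError("cut points must satisfy 0 < lower_cut < upper_cut")


@dataclass
class FeatureVector:
    """Feature set for one nucleus; ``hm`` is filled by the scoring stage."""

    nucleus_id: int
    ep_size: float
    e_size: float
    e_shape: float
    e_appearance: float
    hm: float | None = None


def ep_size(ar: float, params: SizeParams = SizeParams()) -> float:
    """Relative size excess (Ar - k) / k; negative when smaller than benign."""
    if ar < 1:
        raise ValueError("area must be >= 1 pixel")
    return (ar - params.k) / params.k


def e_size(ep: float, params: SizeParams = SizeParams()) -> float:
    """Piecewise size element: 0 below ``lower_cut``, identity in
    [lower_cut, upper_cut), saturating at 1 from ``upper_cut`` upward."""
    if not math.isfinite(ep):
        raise ValueError("EPSize must be finite")
    if ep >= params.upper_cut:
        return 1.0
    if ep >= params.lower_cut:
        return ep
    return 0.0


def e_shape(ar: float, peri: float) -> float:
    """Shape element 1 - 4*pi*Ar/Peri^2, clamped to [0, 1].

    Discrete perimeter estimators can push the isoperimetric quotient of
    near-circular digital shapes slightly above 1; the clamp keeps the
    element in its stated range.
    """
    if ar < 1:
        raise ValueError("area must be >= 1 pixel")
    if peri <= 0:
        raise ValueError("perimeter must be positive")
    return float(np.clip(1.0 - 4.0 * math.pi * ar / peri**2, 0.0, 1.0))


def e_appearance(hol: int, ar: int) -> float:
    """Appearance element Hol / Ar in [0, 1]."""
    if ar < 1:
        raise ValueError("area must be >= 1 pixel")
    if not 0 <= hol <= ar:
        raise ValueError(f"hollow count {hol} outside [0, area={ar}]")
    return hol / ar


def estimate_k(benign_areas) -> float:
    """Benign reference area: the mean pixel area of benign nuclei."""
    areas = np.asarray(list(benign_areas), dtype=float)
    if areas.size == 0:
        raise ValueError("at least one benign nucleus area is required")
    if (areas < 1).any():
        raise ValueError("areas must be >= 1 pixel")
    return float(areas.mean())


def featurize(
    geoms: list[NucleusGeometry], params: SizeParams = SizeParams()
) -> list[FeatureVector]:
    """Compute the feature vector for each measured nucleus.

    ``hm`` is left unset; apply :func:`pleoscore.hm.score_table` to fill it.
    Geometries must have their hollow count populated.
    """
    out = []
    for g in geoms:
        if g.hol is None:
            raise ValueError(f"nucleus {g.nucleus_id}: hollow count not measured")
        ep = ep_size(g.ar, params)
        out.append(
            FeatureVector(
                nucleus_id=g.nucleus_id,
                ep_size=ep,
                e_size=e_size(ep, params),
                e_shape=e_shape(g.ar, g.peri),
                e_appearance=e_appearance(g.hol, g.ar),
            )
        )
    return out
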