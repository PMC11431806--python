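"""Conditional weighted harmonic-mean aggregation of the three elements.

The HM score combines ESize, EShape and EAppearance into one value in
[0, 1]::

    HM = tau / (w1/ESize + w2/EShape + w3/EAppearance)

with a conditional rule for the size term: when ESize = 0 (nucleus below
1.5x the benign reference) its reciprocal would be infinite, so the term
is dropped — w1 is forced to 0 and tau becomes the sum of the remaining
weights (2 at unit weights, the two-element harmonic mean).  Otherwise
tau is the sum of all included weights (3 at unit weights).  With unit
weights and all elements equal to c, HM = c in both branches.

EShape or EAppearance equal to 0 drives the harmonic mean to its
continuous limit, so HM = 0 in that case.
"""

from __future__ import annotations

from dataclasses import dataclass

from pleoscore.features import FeatureVector


@dataclass(frozen=True)
class HMWeights:
    """Weights of the three elements.

    ``w1`` (size) may be zero to exclude the size element outright; the
    shape and appearance weights must stay positive.  ``tau`` is always
    the sum of the weights actually included, which reduces to the 3-vs-2
    rule at the default unit weights.
    """

    w1: float = 1.0
    w2: float = 1.0
    w3: float = 1.0

    def __post_init__(self) -> None:
        if self.w1 < 0:
            raise ValueError("w1 must be >= 0")
        if self.w2 <= 0 or self.w3 <= 0:
            raise ValueError("w2 and w3 must be > 0")


def harmonic_mean_score(
    e_size: float,
    e_shape: float,
    e_appearance: float,
    weights: HMWeights = HMWeights(),
) -> float:
    """HM score of one nucleus from its three elements.

    The size term participates only when ``e_size > 0`` and ``w1 > 0``;
    tau is the sum of participating weights.  A participating element
    equal to 0 yields HM = 0 (continuous limit of the harmonic mean).
    """
    for name, v in (("e_shape", e_shape), ("e_appearance", e_appearance)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if e_size < 0:
        raise ValueError("e_size must be >= 0")

    terms: list[tuple[float, float]] = []
    if e_size > 0 and weights.w1 > 0:
        terms.append((weights.w1, e_size))
    terms.append((weights.w2, e_shape))
    terms.append((weights.w3, e_appearance))

    tau = sum(w for w, _ in terms)
    if tau <= 0:
        raise ValueError("no positively weighted elements to aggregate")
    if any(v == 0 for _, v in terms):
        return 0.0
    return tau / sum(w / v for w, v in terms)


def score_table(
    features: list[FeatureVector], weights: HMWeights = HMWeights()
) -> list[FeatureVector]:
    """Fill ``hm`` for every feature vector, preserving input order."""
    for fv in features:
        fv.hm = harmonic_mean_score(
            fv.e_size, fv.e_shape, fv.e_appearance, weights
        )
    return features
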