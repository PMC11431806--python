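"""Published worked-example measurements used as a fixed reference.

Nine nuclei (three per pleomorphism score) with their reported component
values: the raw size ratio EPSize, EShape and EAppearance, plus the HM
score reported alongside them.  They exercise both aggregation branches —
the two rows with EPSize < 0.5 route through the size-excluded (tau = 2)
branch — and serve as the regression anchor for the scoring equations.

Note the reported component values are rounded to 4 decimal places, so an
HM recomputed from them can differ from the reported HM by up to about
one unit in the fourth decimal.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class WorkedExample:
    score: int
    ep_size: float
    e_shape: float
    e_appearance: float
    hm_reported: float


WORKED_EXAMPLES: tuple[WorkedExample, ...] = (
    WorkedExample(1, 0.3993, 0.3661, 0.2912, 0.3244),
    WorkedExample(1, 0.5034, 0.3407, 0.3270, 0.3759),
    WorkedExample(1, 0.0863, 0.4715, 0.4093, 0.4382),
    WorkedExample(2, 0.7694, 0.3861, 0.4274, 0.4816),
    WorkedExample(2, 0.5669, 0.4360, 0.5139, 0.4997),
    WorkedExample(2, 0.6449, 0.4153, 0.4855, 0.4985),
    WorkedExample(3, 1.0000, 0.6479, 0.6973, 0.7542),
    WorkedExample(3, 1.0000, 0.5269, 0.5881, 0.6524),
    WorkedExample(3, 1.0000, 0.7049, 0.8687, 0.8404),
)
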