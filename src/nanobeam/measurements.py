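"""Published axial-stiffness measurements used as calibration/comparison data.

Mean +/- SD apparent stiffness (pN) of the four flow-stretched two-helix
constructs, and single literature values for the 6- and 10-helix bundles
measured elsewhere with a different apparatus.  These numbers are inputs to
the calibration pipeline, not outputs of this package.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class MeasuredStiffness:
    construct: str
    mean_pN: float
    sd_pN: float | None  # None where only a single value was reported
    n_replicates: int | None


MEASURED = {
    "C85L": MeasuredStiffness("C85L", 382.0, 227.0, 5),
    "C85N": MeasuredStiffness("C85N", 206.0, 131.0, 5),
    "C170L": MeasuredStiffness("C170L", 181.0, 82.0, 7),
    "C170N": MeasuredStiffness("C170N", 108.0, 47.0, 4),
    "6HB": MeasuredStiffness("6HB", 337.0, None, None),
    "10HB": MeasuredStiffness("10HB", 341.0, None, None),
}

#: Published fitted degradation factors and their confidence intervals, for
#: comparison with this package's calibration (the nick factor is sensitive
#: to the assumed element topology; interval membership is the meaningful
#: comparison).
PUBLISHED_ALPHA = 0.0205
PUBLISHED_ALPHA_CI = (0.011, 0.04)
PUBLISHED_BETA = 0.009
PUBLISHED_BETA_CI = (0.0033, 0.0305)
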