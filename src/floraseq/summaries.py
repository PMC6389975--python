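"""Small quantitative utilities used outside the RNA-seq core: comparative-Ct
relative expression, uncorrected (population-form) standard deviation, and
integrated-density stain quantification."""

from __future__ import annotations

import math
from typing import NamedTuple, Sequence

import numpy as np

from .errors import ContractError


class CtRecord(NamedTuple):
    """Quantitative-PCR cycle thresholds for a target gene and the internal
    control gene in one sample."""

    sample_id: str
    target_ct: float
    control_ct: float


def relative_expression_ddct(sample: CtRecord, calibrator: CtRecord) -> float:
    """Comparative cycle threshold (delta-delta-Ct) relative expression.

    Assumes perfect doubling per cycle: returns 2**(-ddCt) where
    ddCt = (target - control)_sample - (target - control)_calibrator.
    """
    for rec in (sample, calibrator):
        for ct in (rec.target_ct, rec.control_ct):
            if not math.isfinite(ct) or ct <= 0:
                raise ContractError(f"non-finite or non-positive Ct in {rec.sample_id!r}")
    ddct = (sample.target_ct - sample.control_ct) - (
        calibrator.target_ct - calibrator.control_ct
    )
    return float(2.0 ** (-ddct))


def uncorrected_sd(values: Sequence[float]) -> float:
    """Population-form standard deviation: sqrt(sum((x - mean)^2) / n)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ContractError("uncorrected_sd needs at least one value")
    return float(arr.std(ddof=0))


def integrated_density(area: float, mean_gray: float) -> float:
    """IntDen = Area x Mean Gray Value; proxy for nuclear DNA amount in
    Feulgen-stained images."""
    if area <= 0:
        raise ContractError("area must be positive")
    return float(area * mean_gray)
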