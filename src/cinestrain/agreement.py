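"""Method-comparison statistics: Bland-Altman agreement and the coefficient
of variability (COV) used for inter-method and observer agreement.

Limits of agreement use a factor of exactly 2 standard deviations of the
paired differences (not 1.96), and all standard deviations use the sample
(n-1) denominator, as is conventional in small-n observer studies.
COV is defined as 100 * SD(differences) / grand mean of all measurements,
which makes it scale-invariant and zero exactly when the two methods agree
on every pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AgreementReport", "bland_altman", "cov"]


@dataclass
class AgreementReport:
    """Bland-Altman summary for paired measurements (a - b)."""

    n_pairs: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    cov_percent: float

    def as_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "bias": self.bias,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "cov_percent": self.cov_percent,
        }


def _paired(values_a, values_b):
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    return a, b


def bland_altman(values_a, values_b) -> AgreementReport:
    """Bias and limits of agreement for paired measurements.

    bias = mean(a - b); limits = bias +/- 2 * sample SD of the differences.
    ``cov_percent`` is filled in when the grand mean is nonzero (NaN
    otherwise, except for the degenerate all-identical case which is 0).
    """
    a, b = _paired(values_a, values_b)
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    grand_mean = float(np.concatenate([a, b]).mean())
    if sd == 0.0:
        cov_pct = 0.0
    elif grand_mean == 0.0:
        cov_pct = float("nan")
    else:
        cov_pct = abs(100.0 * sd / grand_mean)
    return AgreementReport(
        n_pairs=len(a),
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 2.0 * sd,
        loa_high=bias + 2.0 * sd,
        cov_percent=cov_pct,
    )


def cov(values_a, values_b) -> float:
    """Coefficient of variability: 100 * SD(a - b) / mean of all 2n values.

    Zero iff every pair agrees; invariant to multiplying all measurements by
    a common positive factor.  Undefined (raises) when the grand mean is 0.
    """
    a, b = _paired(values_a, values_b)
    sd = float((a - b).std(ddof=1))
    if sd == 0.0:
        return 0.0
    grand_mean = float(np.concatenate([a, b]).mean())
    if grand_mean == 0.0:
        raise ValueError("COV undefined: grand mean of measurements is 0")
    return abs(100.0 * sd / grand_mean)
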