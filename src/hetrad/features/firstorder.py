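"""First-order intensity-histogram statistics of raw ROI intensities.

Seven features: mean, variance, skewness, kurtosis, mean absolute
deviation, hyperskewness and hyperflatness.  All moments are population
moments (divide by N); kurtosis is the raw 4th standardized moment
(Gaussian = 3), and hyperskewness/hyperflatness are the 5th and 6th
standardized central moments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FirstOrderStats:
    mean: float
    variance: float
    skewness: float
    kurtosis: float
    mad: float
    hyperskewness: float
    hyperflatness: float
    undefined: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {
            "Intensity_Mean": self.mean,
            "Intensity_Variance": self.variance,
            "Intensity_Skewness": self.skewness,
            "Intensity_Kurtosis": self.kurtosis,
            "Intensity_MAD": self.mad,
            "Intensity_Hyperskewness": self.hyperskewness,
            "Intensity_Hyperflatness": self.hyperflatness,
        }


def first_order_features(intensities: np.ndarray) -> FirstOrderStats:
    """Population moments of an intensity multiset (>= 2 voxels).

    A constant input has zero variance; its standardized moments are
    undefined and returned as NaN with a recorded reason.
    """
    x = np.asarray(intensities, dtype=np.float64).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 voxels for first-order statistics")
    mu = float(x.mean())
    c = x - mu
    var = float(np.mean(c**2))
    mad = float(np.mean(np.abs(c)))
    undefined: dict[str, str] = {}
    if var == 0.0:
        nan = float("nan")
        reason = "constant intensities: standardized moments undefined"
        for name in (
            "Intensity_Skewness",
            "Intensity_Kurtosis",
            "Intensity_Hyperskewness",
            "Intensity_Hyperflatness",
        ):
            undefined[name] = reason
        return FirstOrderStats(mu, 0.0, nan, nan, 0.0, nan, nan, undefined)
    sd = np.sqrt(var)
    z = c / sd
    return FirstOrderStats(
        mean=mu,
        variance=var,
        skewness=float(np.mean(z**3)),
        kurtosis=float(np.mean(z**4)),
        mad=mad,
        hyperskewness=float(np.mean(z**5)),
        hyperflatness=float(np.mean(z**6)),
        undefined=undefined,
    )
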