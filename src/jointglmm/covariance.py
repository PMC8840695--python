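"""The 2x2 random-effect covariance shared by simulator and estimator."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class CovarianceMatrix:
    """Unstructured covariance of the paired cluster random intercepts.

    sigma11: variance of the stunting intercept; sigma22: variance of the
    anaemia intercept; sigma12: their covariance.  Symmetry is structural
    (sigma21 == sigma12); positive semidefiniteness is enforced.
    """

    sigma11: float
    sigma22: float
    sigma12: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma11 < 0 or self.sigma22 < 0:
            raise ValueError("variances must be nonnegative")
        # small slack for round-tripping matrices at the PSD boundary
        if self.sigma12**2 > self.sigma11 * self.sigma22 * (1 + 1e-12) + 1e-15:
            raise ValueError(
                f"covariance {self.sigma12} violates positive semidefiniteness "
                f"given variances ({self.sigma11}, {self.sigma22})"
            )

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [[self.sigma11, self.sigma12], [self.sigma12, self.sigma22]]
        )

    @property
    def correlation(self) -> float:
        denom = np.sqrt(self.sigma11 * self.sigma22)
        return float(self.sigma12 / denom) if denom > 0 else 0.0

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "CovarianceMatrix":
        m = np.asarray(m, dtype=float)
        if m.shape != (2, 2) or abs(m[0, 1] - m[1, 0]) > 1e-10:
            raise ValueError("expected a symmetric 2x2 matrix")
        return cls(sigma11=float(m[0, 0]), sigma22=float(m[1, 1]),
                   sigma12=float(m[0, 1]))
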