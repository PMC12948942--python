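"""Variance-component parameters for the trio model.

The phenotype of a focal family member is decomposed into a direct genetic
component (their own genotype), two indirect genetic components (the two
other trio members' genotypes), the covariances among those three, and a
residual:

    Var(Y) = sigma2_o + sigma2_m + sigma2_p + sigma_om + sigma_op + sigma2_e

where the ``o`` slot always denotes the focal person's own (direct) effect
and ``m``/``p`` the two non-focal roles.  ``sigma_mp`` (covariance between
the two indirect components) is estimated but does not contribute to the
phenotypic variance under random mating.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

__all__ = ["VCParams", "COMPONENT_NAMES"]

#: canonical ordering of the seven components
COMPONENT_NAMES = (
    "sigma2_o",
    "sigma2_m",
    "sigma2_p",
    "sigma_om",
    "sigma_op",
    "sigma_mp",
    "sigma2_e",
)


@dataclass(frozen=True)
class VCParams:
    """The seven parameters of the trio variance decomposition.

    Variances are on the (standardized) focal-phenotype scale; covariances
    may take either sign but the implied 3x3 genetic covariance matrix must
    be positive semidefinite.
    """

    sigma2_o: float = 0.0
    sigma2_m: float = 0.0
    sigma2_p: float = 0.0
    sigma_om: float = 0.0
    sigma_op: float = 0.0
    sigma_mp: float = 0.0
    sigma2_e: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma2_e < 0:
            raise ValueError(f"residual variance must be >= 0, got {self.sigma2_e}")
        for name in ("sigma2_o", "sigma2_m", "sigma2_p"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        w = np.linalg.eigvalsh(self.genetic_block())
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise ValueError(
                "genetic covariance block is not positive semidefinite "
                f"(smallest eigenvalue {w.min():.3e})"
            )

    def genetic_block(self) -> np.ndarray:
        """3x3 covariance of the (direct, indirect-1, indirect-2) effects."""
        return np.array(
            [
                [self.sigma2_o, self.sigma_om, self.sigma_op],
                [self.sigma_om, self.sigma2_m, self.sigma_mp],
                [self.sigma_op, self.sigma_mp, self.sigma2_p],
            ]
        )

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "VCParams":
        return cls(**{k: float(v) for k, v in d.items()})

    def as_array(self) -> np.ndarray:
        """The seven components in :data:`COMPONENT_NAMES` order."""
        return np.array([getattr(self, n) for n in COMPONENT_NAMES], dtype=float)
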