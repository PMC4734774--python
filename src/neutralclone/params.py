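"""Core parameters of the branching-process model of clonal expansion.

The tumor is modelled as a supercritical birth–death branching process:
every cell divides at rate ``b`` (per day) and dies at rate ``d``, with
``d < b``.  At each division one daughter acquires a new, never-seen-before
passenger mutation with probability ``u`` (infinite-allele model).  The
dimensionless death–birth ratio ``delta = d/b`` is the extinction
probability of a single cell's lineage and controls essentially all
observable quantities; ``b`` only sets the time scale.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import InvalidParameterError

__all__ = ["BranchingParams", "EstimatorConfig"]

_CONSISTENCY_TOL = 1e-9


@dataclass(frozen=True)
class BranchingParams:
    """Birth rate ``b`` (1/day), death rate ``d`` (1/day), and per-division
    passenger mutation probability ``u``.

    The process must be supercritical: ``0 <= d/b < 1``.  ``delta`` may be
    passed explicitly for self-documentation, but must then agree with
    ``d/b`` to within 1e-9.
    """

    b: float = 0.25
    d: float = 0.0
    u: float = 0.015
    delta: float | None = None

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise InvalidParameterError(f"birth rate b must be > 0, got {self.b}")
        if self.d < 0:
            raise InvalidParameterError(f"death rate d must be >= 0, got {self.d}")
        if not 0 <= self.u < 1:
            raise InvalidParameterError(f"mutation probability u must be in [0, 1), got {self.u}")
        ratio = self.d / self.b
        if ratio >= 1:
            raise InvalidParameterError(
                f"delta = d/b = {ratio:.6g} >= 1: the formulas assume supercritical growth"
            )
        if self.delta is not None and abs(self.delta - ratio) > _CONSISTENCY_TOL:
            raise InvalidParameterError(
                f"inconsistent parameters: delta={self.delta} but d/b={ratio:.12g}"
            )
        object.__setattr__(self, "delta", ratio)

    @classmethod
    def from_delta(cls, delta: float, u: float = 0.015, b: float = 0.25) -> "BranchingParams":
        """Build parameters from the death–birth ratio directly."""
        if not 0 <= delta < 1:
            raise InvalidParameterError(f"delta must be in [0, 1), got {delta}")
        return cls(b=b, d=delta * b, u=u)


@dataclass(frozen=True)
class EstimatorConfig:
    """Prior scale for the MAP origin-size estimator.

    ``v`` is the per-division probability that one *specific* point mutation
    arises and survives; for a single exome position this is ~1e-9, which
    makes the geometric prior on the origin size essentially flat and the
    MAP estimate indistinguishable from the MLE.
    """

    v: float = 1e-9

    def __post_init__(self) -> None:
        if not 0 < self.v < 1:
            raise InvalidParameterError(f"v must be in (0, 1), got {self.v}")
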