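"""The PERT (beta-PERT) distribution.

The PERT distribution expresses expert uncertainty about a quantity from
three elicited values — minimum ``a``, most-likely ``m`` (the mode) and
maximum ``b`` — as a beta distribution rescaled to ``[a, b]``:

.. math::

    \\alpha = 1 + \\lambda \\frac{m - a}{b - a}, \\qquad
    \\beta  = 1 + \\lambda \\frac{b - m}{b - a},

with shape parameter ``lambda`` (conventionally 4, giving the classic
mean ``(a + 4m + b) / 6``).  Compared with a triangular distribution on
the same triple, PERT concentrates mass near the mode and down-weights
the extremes, which is why it is the standard choice for cost elements
in probabilistic sensitivity analysis.

This module provides the parameterization, closed-form moments (used as
test oracles throughout the package) and seeded vectorized sampling.
Degenerate triples (``a == b``) are treated as point masses so that
deterministic cost lines are expressible in the same vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PertParams",
    "BetaShape",
    "pert_to_beta",
    "pert_mean",
    "pert_variance",
    "sample_pert",
]

DEFAULT_SHAPE = 4.0


@dataclass(frozen=True)
class PertParams:
    """A minimum / most-likely / maximum triple with a shape parameter.

    Units are whatever the quantity is measured in (USD for cost
    elements, visits per year for encounter volume); the distribution
    itself is unit-agnostic.

    Parameters
    ----------
    minimum, most_likely, maximum : float
        Elicited bounds and mode; must satisfy
        ``minimum <= most_likely <= maximum``.
    shape : float, default 4.0
        PERT shape parameter ``lambda``; must be positive.
    """

    minimum: float
    most_likely: float
    maximum: float
    shape: float = DEFAULT_SHAPE

    def __post_init__(self) -> None:
        if not (self.minimum <= self.most_likely <= self.maximum):
            raise ValueError(
                "PERT triple must satisfy minimum <= most_likely <= maximum, "
                f"got ({self.minimum}, {self.most_likely}, {self.maximum})"
            )
        if not self.shape > 0:
            raise ValueError(f"PERT shape must be positive, got {self.shape}")

    @property
    def is_point_mass(self) -> bool:
        """True when ``minimum == maximum`` (a degenerate, constant value)."""
        return self.minimum == self.maximum

    def scaled(self, factor: float) -> "PertParams":
        """Return a copy with the whole triple multiplied by ``factor`` (> 0)."""
        if not factor > 0:
            raise ValueError(f"scale factor must be positive, got {factor}")
        return PertParams(
            self.minimum * factor,
            self.most_likely * factor,
            self.maximum * factor,
            self.shape,
        )


@dataclass(frozen=True)
class BetaShape:
    """Shape parameters of the underlying beta distribution."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(f"beta shapes must be positive, got {self}")


def pert_to_beta(p: PertParams) -> BetaShape:
    """Map a PERT triple to the shape parameters of its underlying beta.

    Raises
    ------
    ValueError
        If the triple is degenerate (``minimum == maximum``); callers
        must branch to constant sampling for point masses.
    """
    if p.is_point_mass:
        raise ValueError(
            "degenerate PERT triple (minimum == maximum) is a point mass; "
            "no beta reparameterization exists"
        )
    span = p.maximum - p.minimum
    alpha = 1.0 + p.shape * (p.most_likely - p.minimum) / span
    beta = 1.0 + p.shape * (p.maximum - p.most_likely) / span
    return BetaShape(alpha, beta)


def pert_mean(p: PertParams) -> float:
    """Closed-form mean ``(a + lambda*m + b) / (lambda + 2)``.

    With the default ``lambda = 4`` this is the classic PERT estimate
    ``(a + 4m + b) / 6``.  Point masses return the constant.
    """
    return (p.minimum + p.shape * p.most_likely + p.maximum) / (p.shape + 2.0)


def pert_variance(p: PertParams) -> float:
    """Closed-form variance ``(mu - a)(b - mu) / (lambda + 3)``."""
    mu = pert_mean(p)
    return (mu - p.minimum) * (p.maximum - mu) / (p.shape + 3.0)


def sample_pert(p: PertParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` seeded samples from the PERT distribution.

    Each draw is ``a + (b - a) * B`` with ``B ~ Beta(alpha, beta)`` from
    :func:`pert_to_beta`; point masses return a constant vector.  The
    same generator state and parameters give bit-identical output.

    Parameters
    ----------
    p : PertParams
    n : int
        Number of draws; must be >= 1.
    rng : numpy.random.Generator
        An explicitly seeded generator; the caller owns the stream.
    """
    if n < 1:
        raise ValueError(f"number of draws must be >= 1, got {n}")
    if p.is_point_mass:
        return np.full(n, float(p.minimum))
    shape = pert_to_beta(p)
    b = rng.beta(shape.alpha, shape.beta, size=n)
    return p.minimum + (p.maximum - p.minimum) * b
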