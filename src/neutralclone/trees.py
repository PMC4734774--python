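"""Likelihoods of the six phylogenies of the first three successful mutations.

A phylogeny is determined by who the second and third successful mutations
descend from: ``parent_of_2`` is 0 (the founder lineage) or 1, and
``parent_of_3`` is 0, 1 or 2, where "parent" means the nearest successful
ancestor.  The six topologies are indexed 1..6 in the order

    1: (0,0) star      2: (0,1)          3: (0,2)
    4: (1,0)           5: (1,1)          6: (1,2) linear chain

Closed-form (approximate) probabilities p1..p6 follow from the fixation
probability rho_1, and the mean subclonal fractions of mutations 1 and 2,
using the approximation that "mutation j is offspring of mutation i" has
probability equal to the eventual fraction of cells carrying mutation i.
Fast-growing tumors (delta ~ 0.7) favor the star; slow-growing ones
(delta ~ 0.99) favor the linear chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .analytic import fixation_probability, frequency_pdf
from .exceptions import DomainError, NumericalError
from .params import BranchingParams

__all__ = [
    "TreeTopology",
    "TreeQuantities",
    "classify_tree",
    "offspring_probability",
    "tree_helper_quantities",
    "tree_probabilities",
    "TOPOLOGIES",
]

_INDEX = {(0, 0): 1, (0, 1): 2, (0, 2): 3, (1, 0): 4, (1, 1): 5, (1, 2): 6}


@dataclass(frozen=True)
class TreeTopology:
    """One of the six rooted topologies on clones {0, 1, 2, 3}."""

    index: int
    parent_of_2: int
    parent_of_3: int

    @property
    def newick(self) -> str:
        """Newick string with the founder clone 0 as root, e.g. the linear
        chain (1,2) -> '(((3)2)1)0;'."""
        children: dict[int, list[int]] = {0: [1], 1: [], 2: [], 3: []}
        children[self.parent_of_2].append(2)
        children[self.parent_of_3].append(3)

        def render(node: int) -> str:
            kids = children.get(node, [])
            if not kids:
                return str(node)
            return "(" + ",".join(render(c) for c in kids) + ")" + str(node)

        return render(0) + ";"


TOPOLOGIES: tuple[TreeTopology, ...] = tuple(
    TreeTopology(index=i, parent_of_2=p2, parent_of_3=p3) for (p2, p3), i in _INDEX.items()
)


def classify_tree(parent_of_2: int, parent_of_3: int) -> TreeTopology:
    """Map the parent labels of mutations 2 and 3 to the topology index."""
    key = (parent_of_2, parent_of_3)
    if key not in _INDEX:
        raise DomainError(
            f"parent_of_2 must be in {{0,1}} and parent_of_3 in {{0,1,2}}, got {key}"
        )
    return TOPOLOGIES[_INDEX[key] - 1]


def _mean_subclonal_fraction(k: int, params: BranchingParams) -> float:
    """Integral of alpha * g_k(alpha) over (0, 1) by adaptive quadrature.

    Evaluated after the substitution s = -ln(1 - alpha(1-delta)), which
    maps the (0, 1) integral to a smooth, bounded integrand on
    [0, -ln delta] (infinite for delta = 0, where the original density has
    an integrable singularity at alpha = 1):

        (k / (u (1-delta))) * int (1 - e^{-s}) (1 + s/u)^{-(k+1)} ds.
    """
    u, delta = params.u, params.delta

    def integrand(s: float) -> float:
        return (1.0 - math.exp(-s)) * (1.0 + s / u) ** (-(k + 1))

    upper = np.inf if delta == 0.0 else -math.log(delta)
    value, err = integrate.quad(integrand, 0.0, upper, epsabs=1e-10, limit=200)
    if err > 1e-7:
        raise NumericalError(f"quadrature of alpha*g_{k} did not converge (abserr={err!r})")
    return k / (u * (1.0 - delta)) * value


def offspring_probability(params: BranchingParams) -> float:
    """Probability that the second successful mutation arises inside the
    lineage of the first, approximated by the mean eventual fraction of
    mutation 1: rho_1 + integral of alpha g_1(alpha)."""
    rho1 = fixation_probability(1, params)
    if params.u == 0:
        return rho1
    return rho1 + _mean_subclonal_fraction(1, params)


@dataclass(frozen=True)
class TreeQuantities:
    """Ingredients of the tree probabilities.

    ``sub1``/``sub2``: mean fractions of mutations 1/2 conditioned on
    subclonality.  ``sub21c``: mean fraction of 2 given 1 clonal and 2 not
    (= sub1).  ``sub21nc``: mean fraction of 2 given neither clonal.
    ``sub21nc2nc1``: mean fraction of 2 given 1 subclonal and 2 an
    offspring of 1 but not clonal within it.
    """

    rho1: float
    rho2: float
    sub1: float
    sub2: float
    sub21c: float
    sub21nc: float
    sub21nc2nc1: float


def tree_helper_quantities(params: BranchingParams) -> TreeQuantities:
    rho1 = fixation_probability(1, params)
    rho2 = fixation_probability(2, params)
    sub1 = _mean_subclonal_fraction(1, params) / (1.0 - rho1)
    sub2 = _mean_subclonal_fraction(2, params) / (1.0 - rho2)
    sub21nc = (1.0 + rho1) * sub2 - rho1 * sub1
    sub21nc2nc1 = (sub21nc - rho1 * sub1) / (1.0 - rho1)
    return TreeQuantities(
        rho1=rho1,
        rho2=rho2,
        sub1=sub1,
        sub2=sub2,
        sub21c=sub1,
        sub21nc=sub21nc,
        sub21nc2nc1=sub21nc2nc1,
    )


def tree_probabilities(params: BranchingParams, normalized: bool = False) -> np.ndarray:
    """Approximate probabilities (p1, ..., p6) of the six topologies.

    The closed forms are first-order approximations and do not sum to
    exactly 1; by default they are returned un-normalized (pass
    ``normalized=True`` for a view rescaled to unit sum).
    """
    q = tree_helper_quantities(params)
    rho1, sub1, sub2 = q.rho1, q.sub1, q.sub2
    p1 = (1 - rho1) * (1 - sub1) * (1 - sub1 - q.sub21nc)
    p2 = (1 - rho1) * (1 - sub1) * sub1
    p3 = (1 - rho1) * (1 - sub1) * q.sub21nc
    p4 = p2
    p5 = (1 - rho1) * (rho1 * (1 - sub1) + (1 + rho1) * sub1 * (sub1 - sub2))
    p6 = rho1**2 + rho1 * (1 - rho1) * sub1 * (1 - sub1) + (1 - rho1**2) * sub1 * sub2
    p = np.array([p1, p2, p3, p4, p5, p6])
    if normalized:
        return p / p.sum()
    return p
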