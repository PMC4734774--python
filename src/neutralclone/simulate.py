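"""Exact Gillespie simulation of the multi-type birth–death process.

State is kept as one clone label per live cell.  Because cells within a
clone are exchangeable, picking a uniformly random cell at each event is
exactly equivalent to picking a clone with probability proportional to its
size, at O(1) cost per event.  Each event is a division with probability
b/(b+d), otherwise a death; at a division one daughter founds a new clone
with probability u.  The clone genealogy (parent clone, origin time, and
the number z of other cells present at appearance) is recorded as it grows.

A finished run is post-processed into per-mutation reports: each live cell
is assigned an independent Bernoulli(1 - delta) draw for the eventual
survival of its lineage (the branching property makes the future
independent of the past given the present), from which every mutation's
"successful" flag (some carrier survives, marginal probability
1 - delta^m) and "fixed" flag (no non-carrier survives, marginal
delta^{m_nc}) follow consistently.  Successful mutations are labelled by
order of appearance, and the parent label of each is its nearest
successful ancestor (0 = founder lineage), which is what the tree
topologies of :mod:`neutralclone.trees` are classified from.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError, InvalidParameterError, NumericalError
from .params import BranchingParams
from .trees import TreeTopology, classify_tree

__all__ = [
    "SimulationConfig",
    "CloneGenealogy",
    "MutationReport",
    "simulate",
    "classify_successful",
    "ensemble",
    "EnsembleResult",
]

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


OUTCOME_EXTINCT = 0
OUTCOME_COMPLETE = 1
OUTCOME_TRUNCATED = 2
_OUTCOME_NAMES = {0: "extinct", 1: "complete", 2: "truncated"}


@njit(cache=False)
def _sim_kernel(seed, p_birth, rate_per_cell, u, stop_size, max_events, max_clones):
    """Event loop.  Uses only np.random.random() so the jitted and pure
    Python paths draw the identical MT19937 stream for a given seed."""
    np.random.seed(seed)
    cells = np.zeros(stop_size, dtype=np.int32)
    parent = np.full(max_clones, -1, dtype=np.int32)
    origin_z = np.zeros(max_clones, dtype=np.int64)
    origin_time = np.zeros(max_clones, dtype=np.float64)
    n = 1
    n_clones = 1
    t = 0.0
    events = 0
    outcome = OUTCOME_TRUNCATED
    while events < max_events:
        if n == 0:
            outcome = OUTCOME_EXTINCT
            break
        if n >= stop_size:
            outcome = OUTCOME_COMPLETE
            break
        t -= math.log(1.0 - np.random.random()) / (n * rate_per_cell)
        events += 1
        i = int(np.random.random() * n)
        if np.random.random() < p_birth:
            if u > 0.0 and np.random.random() < u:
                if n_clones >= max_clones:
                    break  # clone table overflow -> truncated
                parent[n_clones] = cells[i]
                origin_z[n_clones] = n
                origin_time[n_clones] = t
                cells[n] = n_clones
                n_clones += 1
            else:
                cells[n] = cells[i]
            n += 1
        else:
            cells[i] = cells[n - 1]
            n -= 1
    return cells[:n].copy(), parent[:n_clones].copy(), origin_z[:n_clones].copy(), origin_time[:n_clones].copy(), t, events, outcome


@njit(cache=False)
def _subtree_sums(parent, own):
    """Sum a per-clone quantity over each clone's subtree (parents precede
    children, so one reverse sweep suffices)."""
    out = own.copy()
    for c in range(len(parent) - 1, 0, -1):
        out[parent[c]] += out[c]
    return out


@njit(cache=False)
def _nearest_successful_ancestor(parent, successful, labels):
    """Label of the nearest successful ancestor of each clone (0 = founder)."""
    n = len(parent)
    out = np.zeros(n, dtype=np.int64)
    for c in range(1, n):
        p = parent[c]
        if p <= 0:
            out[c] = 0
        elif successful[p]:
            out[c] = labels[p]
        else:
            out[c] = out[p]
    return out


@dataclass(frozen=True)
class SimulationConfig:
    """Run controls.

    ``stop_size``: target total cell count M (default 5e4 for delta <= 0.96
    and 5e3 above, where the event count grows like M(1+delta)/(1-delta)).
    ``max_events``: hard safety cap; exceeding it yields outcome
    "truncated", never a silent result.  ``required_successful``: minimum
    number of successful mutations for a run to qualify in an ensemble
    (3 for tree studies).
    """

    stop_size: int | None = None
    max_events: int | None = None
    seed: int | None = None
    condition_on_survival: bool = True
    required_successful: int = 0

    def resolve_stop_size(self, params: BranchingParams) -> int:
        if self.stop_size is not None:
            if self.stop_size < 2:
                raise InvalidParameterError(f"stop_size must be >= 2, got {self.stop_size}")
            return int(self.stop_size)
        return 50_000 if params.delta <= 0.96 else 5_000

    def resolve_max_events(self, params: BranchingParams) -> int:
        if self.max_events is not None:
            return int(self.max_events)
        stop = self.resolve_stop_size(params)
        expected = stop * (1.0 + params.delta) / max(1.0 - params.delta, 1e-6)
        return int(50 * expected + 100_000)


@dataclass
class CloneGenealogy:
    """Rooted genealogy of clones from one run.

    Clone 0 is the founding type; ``parent[c]`` precedes ``c``.
    ``origin_z[c]`` is the number of other cells present when clone c
    appeared (0 for the founder), ``clone_cells[c]`` the number of live
    cells whose most recent mutation is c (own cells, not the subtree).
    """

    parent: np.ndarray
    origin_z: np.ndarray
    origin_time: np.ndarray
    clone_cells: np.ndarray
    n_cells: int
    outcome: str
    t_final: float
    n_events: int
    seed: int | None = None

    @property
    def n_clones(self) -> int:
        return len(self.parent)

    def subtree_cells(self) -> np.ndarray:
        """Live cells carrying each clone's mutation (clone + descendants)."""
        return _subtree_sums(self.parent, self.clone_cells.astype(np.int64))

    def to_newick(self) -> str:
        """Newick export with live-cell counts as branch annotations."""
        children: dict[int, list[int]] = {}
        for c in range(1, self.n_clones):
            children.setdefault(int(self.parent[c]), []).append(c)

        def render(node: int) -> str:
            label = f"{node}:{int(self.clone_cells[node])}"
            kids = children.get(node, [])
            if not kids:
                return label
            return "(" + ",".join(render(c) for c in kids) + ")" + label

        return render(0) + ";"


@dataclass(frozen=True)
class MutationReport:
    """One successful mutation.

    ``frequency`` is a draw from the exact conditional law of the
    *eventual* cell fraction given the survival draws: each surviving
    lineage grows like e^{(b-d)t} times an iid exponential factor, so the
    eventual fraction is Beta(s_carrier, s_noncarrier) (1.0 when no
    non-carrier survives, i.e. the mutation fixes).  ``observed_frequency``
    is the plain carrier fraction at the stop size, which at high delta
    still carries transient spread of order sqrt((1+delta)/((1-delta)M)).
    """

    k: int
    clone: int
    frequency: float
    observed_frequency: float
    fixed: bool
    parent_label: int


def _mutation_capacity(params: BranchingParams, stop: int) -> int:
    """Clone-table size: ~8x the expected number of mutation events in a
    surviving run (births ~ stop/(1-delta)); overflow yields a truncated
    outcome rather than silent loss."""
    expected_births = stop / max(1.0 - params.delta, 1e-6)
    return int(8 * params.u * expected_births) + 1024


def _kernel_seed(seed: int | None, index: int = 0) -> int:
    ss = np.random.SeedSequence((0 if seed is None else int(seed), index))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def simulate(params: BranchingParams, config: SimulationConfig | None = None,
             seed: int | None = None) -> CloneGenealogy:
    """Run one trajectory until extinction, the stop size, or the event cap."""
    config = config or SimulationConfig()
    if seed is None:
        seed = config.seed
    stop = config.resolve_stop_size(params)
    max_events = config.resolve_max_events(params)
    p_birth = params.b / (params.b + params.d) if params.d > 0 else 1.0
    rate_per_cell = params.b + params.d
    mut_cap = _mutation_capacity(params, stop)
    cells, parent, origin_z, origin_time, t, events, outcome = _sim_kernel(
        _kernel_seed(seed), p_birth, rate_per_cell, params.u, stop, max_events, mut_cap
    )
    counts = np.bincount(cells, minlength=len(parent)).astype(np.int64)
    return CloneGenealogy(
        parent=parent,
        origin_z=origin_z,
        origin_time=origin_time,
        clone_cells=counts,
        n_cells=len(cells),
        outcome=_OUTCOME_NAMES[int(outcome)],
        t_final=t,
        n_events=events,
        seed=seed,
    )


def classify_successful(
    genealogy: CloneGenealogy,
    params: BranchingParams,
    rng: np.random.Generator | int | None = None,
) -> list[MutationReport]:
    """Decide which extant mutations are successful (lineage survives
    forever) and which of those fix, by drawing one eventual-survival
    Bernoulli(1 - delta) per live cell; the eventual frequency of each
    successful mutation is then drawn from its exact conditional law
    Beta(s_carrier, s_noncarrier) given those survival draws.

    Success is deterministic when d = 0 (every lineage survives; nothing
    can fix because the founder cell is immortal).
    """
    if genealogy.outcome == "extinct":
        raise DomainError("cannot classify mutations of an extinct run; condition on survival")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    delta = params.delta
    own = genealogy.clone_cells
    if delta == 0.0:
        surv_own = own.copy()
    else:
        surv_own = rng.binomial(own.astype(np.int64), 1.0 - delta)
    sub_cells = _subtree_sums(genealogy.parent, own.astype(np.int64))
    sub_surv = _subtree_sums(genealogy.parent, surv_own.astype(np.int64))
    total_surv = int(surv_own.sum())

    successful = sub_surv > 0
    successful[0] = False  # the founder type is not a mutation
    labels = np.zeros(genealogy.n_clones, dtype=np.int64)
    labels[successful] = np.arange(1, int(successful.sum()) + 1)
    parent_labels = _nearest_successful_ancestor(genealogy.parent, successful, labels)

    reports = []
    total = genealogy.n_cells
    for c in np.nonzero(successful)[0]:
        s_mut = int(sub_surv[c])
        s_other = total_surv - s_mut
        if s_other == 0:
            eventual = 1.0
        else:
            eventual = float(rng.beta(s_mut, s_other))
        reports.append(
            MutationReport(
                k=int(labels[c]),
                clone=int(c),
                frequency=eventual,
                observed_frequency=sub_cells[c] / total,
                fixed=bool(s_other == 0),
                parent_label=int(parent_labels[c]),
            )
        )
    return reports


@dataclass
class EnsembleResult:
    """Summary statistics over surviving (and qualifying) runs."""

    frequencies: np.ndarray  # (n_runs, k_max) cell fractions, NaN if absent
    fixed: np.ndarray  # (n_runs, k_max) booleans
    tree_index: np.ndarray  # (n_runs,) topology 1..6, 0 if < 3 successful
    successful_counts: np.ndarray
    attempts: int
    n_extinct: int
    n_insufficient: int
    metadata: dict = field(default_factory=dict)

    @property
    def n_runs(self) -> int:
        return len(self.successful_counts)

    def ecdf(self, k: int):
        """Empirical CDF of the k-th successful mutation's frequency
        (fixed mutations contribute at frequency 1).  Returns a callable."""
        freq = self.frequencies[:, k - 1]
        fx = self.fixed[:, k - 1]
        obs = np.where(fx, 1.0, freq)
        obs = np.sort(obs[~np.isnan(obs)])

        def cdf(alpha):
            return np.searchsorted(obs, alpha, side="right") / len(obs)

        return cdf

    def fixation_fraction(self, k: int) -> tuple[float, float]:
        """(fraction fixed, Monte Carlo SE) for the k-th mutation."""
        fx = self.fixed[:, k - 1][~np.isnan(self.frequencies[:, k - 1])]
        p = float(np.mean(fx))
        return p, math.sqrt(p * (1 - p) / len(fx))

    def tree_frequencies(self) -> tuple[np.ndarray, np.ndarray]:
        """(relative frequency, SE) of topologies 1..6 among runs with
        at least three successful mutations."""
        idx = self.tree_index[self.tree_index > 0]
        n = len(idx)
        freq = np.bincount(idx, minlength=7)[1:] / n
        se = np.sqrt(freq * (1 - freq) / n)
        return freq, se

    def mean_successful(self) -> float:
        return float(np.mean(self.successful_counts))


def ensemble(
    params: BranchingParams,
    config: SimulationConfig,
    n_surviving_runs: int,
    seed: int | None = None,
    k_max: int = 3,
) -> EnsembleResult:
    """Collect ``n_surviving_runs`` qualifying runs (survival to the stop
    size, and at least ``config.required_successful`` successful mutations),
    discarding the rest.

    Expected attempts are about n/(1-delta); the loop aborts with an error
    if ten times that is exceeded.
    """
    if n_surviving_runs < 1:
        raise DomainError("n_surviving_runs must be >= 1")
    if seed is None:
        seed = config.seed
    stop = config.resolve_stop_size(params)
    max_events = config.resolve_max_events(params)
    p_birth = params.b / (params.b + params.d) if params.d > 0 else 1.0
    rate_per_cell = params.b + params.d
    mut_cap = _mutation_capacity(params, stop)
    max_attempts = int(math.ceil(10.0 * n_surviving_runs / max(1.0 - params.delta, 1e-9)))

    frequencies = np.full((n_surviving_runs, k_max), np.nan)
    fixed = np.zeros((n_surviving_runs, k_max), dtype=bool)
    tree_index = np.zeros(n_surviving_runs, dtype=np.int64)
    successful_counts = np.zeros(n_surviving_runs, dtype=np.int64)

    attempts = n_extinct = n_insufficient = collected = 0
    while collected < n_surviving_runs:
        if attempts >= max_attempts:
            raise NumericalError(
                f"exceeded {max_attempts} attempts for {n_surviving_runs} qualifying runs "
                f"(expected ~{n_surviving_runs / max(1 - params.delta, 1e-9):.0f}); "
                "check parameters"
            )
        ss = np.random.SeedSequence((0 if seed is None else int(seed), attempts))
        state = ss.generate_state(2, dtype=np.uint32)
        attempts += 1
        cells, parent, origin_z, origin_time, t, events, outcome = _sim_kernel(
            int(state[0]), p_birth, rate_per_cell, params.u, stop, max_events, mut_cap
        )
        if outcome == OUTCOME_EXTINCT:
            n_extinct += 1
            continue
        if outcome == OUTCOME_TRUNCATED:
            raise NumericalError(f"run truncated at {events} events; raise max_events")
        counts = np.bincount(cells, minlength=len(parent)).astype(np.int64)
        genealogy = CloneGenealogy(
            parent=parent, origin_z=origin_z, origin_time=origin_time,
            clone_cells=counts, n_cells=len(cells), outcome="complete",
            t_final=t, n_events=events,
        )
        reports = classify_successful(genealogy, params, np.random.default_rng(int(state[1])))
        if len(reports) < config.required_successful:
            n_insufficient += 1
            continue
        for rep in reports[:k_max]:
            frequencies[collected, rep.k - 1] = rep.frequency
            fixed[collected, rep.k - 1] = rep.fixed
        if len(reports) >= 3:
            tree_index[collected] = classify_tree(
                reports[1].parent_label, reports[2].parent_label
            ).index
        successful_counts[collected] = len(reports)
        collected += 1

    return EnsembleResult(
        frequencies=frequencies,
        fixed=fixed,
        tree_index=tree_index,
        successful_counts=successful_counts,
        attempts=attempts,
        n_extinct=n_extinct,
        n_insufficient=n_insufficient,
        metadata={
            "params": {"b": params.b, "d": params.d, "u": params.u, "delta": params.delta},
            "stop_size": stop,
            "seed": seed,
            "time_simulated": True,
            "numba": _HAVE_NUMBA,
        },
    )
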