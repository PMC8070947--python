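"""Pairwise conditional-probability machinery on categorical raster stacks.

The impact-mechanism analysis treats each discretized layer (five indicators
plus the assessment result) as a categorical variable observed per cell, and
builds the complete set of pairwise conditional probability tables (CPTs) from
raster co-occurrence counts over the study area — a Bayesian-network-style
probability graph with no structure learning, since the pairwise tables are
all the downstream analysis uses.

Two kinds of state subsets are derived from the graph:

* the *conditional state subset* (CSS) for result level r: for each indicator
  X the state s maximizing P(X = s | result = r) — the state combination most
  characteristic of that result level;
* the *optimal state subset*: for each indicator X the state s maximizing
  P(result = target | X = s) with target level 1 (the best outcome) — the
  combination of indicator states most favourable to a good result.

Ties are broken toward the lowest state index and recorded on the subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import CategoricalRaster, RegionMask, require_aligned


@dataclass
class ContingencyTable:
    """Joint cell counts of two categorical layers over the analysis mask."""

    var_a: str
    var_b: str
    counts: np.ndarray  # shape (m_a, m_b), nonnegative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D table")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ConditionalProbabilityTable:
    """P(A = i | B = j) for an ordered variable pair.

    ``probs[i, j]`` is the probability of A-state i+1 given B-state j+1;
    columns with zero support are NaN and flagged undefined rather than
    divided.
    """

    var_a: str
    var_b: str
    probs: np.ndarray
    support: np.ndarray  # count of cells per B state

    @property
    def defined(self) -> np.ndarray:
        """Boolean per B state: column has support."""
        return self.support > 0

    def to_frame(self) -> pd.DataFrame:
        m_a, m_b = self.probs.shape
        df = pd.DataFrame(
            self.probs,
            index=[f"{self.var_a}={i}" for i in range(1, m_a + 1)],
            columns=[f"{self.var_b}={j}" for j in range(1, m_b + 1)],
        )
        df.loc["support"] = self.support
        return df


@dataclass
class StateSubset:
    """A per-variable state requirement, e.g. {npp: {1, 2}, steep_slope: {1}}."""

    assignments: dict[str, frozenset[int]]
    label: str = ""
    ties: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.assignments = {
            v: frozenset(int(s) for s in (states if isinstance(states, (set, frozenset, list, tuple)) else [states]))
            for v, states in self.assignments.items()
        }
        for v, states in self.assignments.items():
            if not states or min(states) < 1:
                raise ValueError(f"{v}: states must be positive integers")

    def restricted_to(self, variables: list[str], label: str | None = None) -> "StateSubset":
        missing = [v for v in variables if v not in self.assignments]
        if missing:
            raise KeyError(f"subset does not cover variables {missing}")
        return StateSubset(
            {v: self.assignments[v] for v in variables},
            label if label is not None else self.label,
            {v: t for v, t in self.ties.items() if v in variables},
        )

    def relaxed(self, by: int = 1, n_states: dict[str, int] | None = None) -> "StateSubset":
        """Widen every single-state requirement by ``by`` adjacent upper states.

        Mirrors the re-selection of a first-level subset from {1} to {1 | 2}
        when the strict subset matches nothing.
        """
        out = {}
        for v, states in self.assignments.items():
            widened = set(states)
            cap = None if n_states is None else n_states.get(v)
            for s in states:
                for k in range(1, by + 1):
                    if cap is None or s + k <= cap:
                        widened.add(s + k)
            out[v] = frozenset(widened)
        return StateSubset(out, label=f"{self.label}|relaxed" if self.label else "relaxed")


def joint_counts(
    a: CategoricalRaster, b: CategoricalRaster, domain: RegionMask, var_a: str = "A", var_b: str = "B"
) -> ContingencyTable:
    """Joint state counts of two layers over cells valid in both and in the domain."""
    require_aligned(a.grid, b.grid, domain.grid)
    sel = a.valid & b.valid & domain.member
    if not sel.any():
        raise ValueError("no overlapping valid cells inside the domain")
    idx = (a.levels[sel] - 1) * b.n_states + (b.levels[sel] - 1)
    counts = np.bincount(idx, minlength=a.n_states * b.n_states).reshape(
        a.n_states, b.n_states
    )
    return ContingencyTable(var_a, var_b, counts)


def conditional_probability(t: ContingencyTable) -> ConditionalProbabilityTable:
    """Column-normalize a contingency table into P(A | B)."""
    support = t.counts.sum(axis=0)
    probs = np.full(t.counts.shape, np.nan)
    nz = support > 0
    probs[:, nz] = t.counts[:, nz] / support[nz]
    return ConditionalProbabilityTable(t.var_a, t.var_b, probs, support)


@dataclass
class ProbabilityGraph:
    """Complete pairwise conditional-probability structure over a variable set."""

    variables: list[str]
    result_var: str
    n_states: dict[str, int]
    tables: dict[tuple[str, str], ContingencyTable]  # one per unordered pair, key sorted by variable order
    marginals: dict[str, np.ndarray]
    n_cells: int

    def cpt(self, var_a: str, var_b: str) -> ConditionalProbabilityTable:
        """P(var_a | var_b), derived from the shared joint counts."""
        key = self._key(var_a, var_b)
        t = self.tables[key]
        if key == (var_a, var_b):
            return conditional_probability(t)
        return conditional_probability(ContingencyTable(var_a, var_b, t.counts.T))

    def _key(self, var_a: str, var_b: str) -> tuple[str, str]:
        order = {v: i for i, v in enumerate(self.variables)}
        if var_a not in order or var_b not in order:
            raise KeyError(f"unknown variable in pair ({var_a}, {var_b})")
        return (var_a, var_b) if order[var_a] < order[var_b] else (var_b, var_a)

    def all_cpts(self) -> dict[tuple[str, str], ConditionalProbabilityTable]:
        """CPTs for every ordered pair (n*(n-1) tables for n variables)."""
        return {
            (a, b): self.cpt(a, b)
            for a in self.variables
            for b in self.variables
            if a != b
        }

    def to_frame(self) -> pd.DataFrame:
        """Long-format table of every pairwise conditional probability."""
        rows = []
        for (a, b), cpt in self.all_cpts().items():
            m_a, m_b = cpt.probs.shape
            for i in range(m_a):
                for j in range(m_b):
                    rows.append(
                        {
                            "var_a": a,
                            "state_a": i + 1,
                            "var_b": b,
                            "state_b": j + 1,
                            "p_a_given_b": cpt.probs[i, j],
                            "support_b": int(cpt.support[j]),
                        }
                    )
        return pd.DataFrame(rows)


def build_probability_graph(
    stack: dict[str, CategoricalRaster], result_var: str, domain: RegionMask
) -> ProbabilityGraph:
    """Build the complete pairwise probability graph from a categorical stack.

    ``stack`` maps variable id to layer and must include ``result_var``.
    Counts for each pair use the cells valid in *both* layers (and in the
    domain), so pairwise tables remain consistent under shared validity.
    """
    if result_var not in stack:
        raise KeyError(f"result variable {result_var!r} not in stack")
    variables = list(stack)
    if len(variables) < 2:
        raise ValueError("need at least two variables")
    if len(set(variables)) != len(variables):
        raise ValueError("duplicate variable ids")
    grids = [r.grid for r in stack.values()]
    require_aligned(domain.grid, *grids)
    # All tables and marginals use the cells valid in EVERY layer, so the
    # Bayes identity and marginal consistency hold exactly across pairs.
    sel_all = domain.member.copy()
    for r in stack.values():
        sel_all &= r.valid
    n_cells = int(sel_all.sum())
    if n_cells == 0:
        raise ValueError("no cells valid in all layers inside the domain")
    common = RegionMask(domain.grid, sel_all)
    tables: dict[tuple[str, str], ContingencyTable] = {}
    for i, a in enumerate(variables):
        for b in variables[i + 1 :]:
            tables[(a, b)] = joint_counts(stack[a], stack[b], common, a, b)
    marginals = {}
    for v, r in stack.items():
        counts = np.bincount(r.levels[sel_all], minlength=r.n_states + 1)[1:]
        marginals[v] = counts / counts.sum()
    return ProbabilityGraph(
        variables,
        result_var,
        {v: r.n_states for v, r in stack.items()},
        tables,
        marginals,
        n_cells,
    )


def _argmax_with_ties(p: np.ndarray, defined: np.ndarray) -> tuple[int, tuple[int, ...]]:
    """Best state (1-based) among defined entries; ties -> lowest, recorded."""
    masked = np.where(defined, p, -np.inf)
    best = float(np.max(masked))
    winners = tuple(int(i) + 1 for i in np.flatnonzero(np.isclose(masked, best, atol=1e-12)))
    return winners[0], winners


def conditional_state_subset(g: ProbabilityGraph, result_level: int) -> StateSubset:
    """CSS for one result level: per indicator, argmax_s P(X = s | result = level)."""
    m = g.n_states[g.result_var]
    if not 1 <= result_level <= m:
        raise ValueError(f"result level {result_level} outside 1..{m}")
    assignments: dict[str, frozenset[int]] = {}
    ties: dict[str, tuple[int, ...]] = {}
    for v in g.variables:
        if v == g.result_var:
            continue
        cpt = g.cpt(v, g.result_var)
        if not cpt.defined[result_level - 1]:
            raise ValueError(f"result level {result_level} has zero support")
        col = cpt.probs[:, result_level - 1]
        best, winners = _argmax_with_ties(col, np.ones(col.size, bool))
        assignments[v] = frozenset({best})
        if len(winners) > 1:
            ties[v] = winners
    return StateSubset(assignments, label=f"CSS {result_level}", ties=ties)


def optimal_state_subset(g: ProbabilityGraph, target_level: int = 1) -> StateSubset:
    """Optimal subset: per indicator, argmax_s P(result = target | X = s).

    States of X with zero support are excluded from the argmax (their
    conditional is undefined).
    """
    m = g.n_states[g.result_var]
    if not 1 <= target_level <= m:
        raise ValueError(f"target level {target_level} outside 1..{m}")
    assignments: dict[str, frozenset[int]] = {}
    ties: dict[str, tuple[int, ...]] = {}
    for v in g.variables:
        if v == g.result_var:
            continue
        cpt = g.cpt(g.result_var, v)  # P(result | X)
        if not cpt.defined.any():
            raise ValueError(f"variable {v} has no supported states")
        row = cpt.probs[target_level - 1, :]
        best, winners = _argmax_with_ties(row, cpt.defined)
        assignments[v] = frozenset({best})
        if len(winners) > 1:
            ties[v] = winners
    return StateSubset(assignments, label="optimal", ties=ties)


def match_subset(
    stack: dict[str, CategoricalRaster], subset: StateSubset, domain: RegionMask
) -> RegionMask:
    """Cells (valid in every referenced layer, inside the domain) satisfying the subset."""
    missing = [v for v in subset.assignments if v not in stack]
    if missing:
        raise KeyError(f"subset references absent variables {missing}")
    grids = [stack[v].grid for v in subset.assignments]
    require_aligned(domain.grid, *grids) if grids else None
    member = domain.member.copy()
    for v, states in subset.assignments.items():
        layer = stack[v]
        member &= layer.valid & np.isin(layer.levels, list(states))
    return RegionMask(domain.grid, member)
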