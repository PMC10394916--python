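"""Agent state (subgraph density), its discretization, and the value table.

The agent's sole state feature is the weighted density of the current
subgraph.  Densities are discretized into a fixed number of equal-width
bins on [0, 1]; a tabular value function maps each bin to a learned value,
updated by a synchronous max-over-actions (Bellman) rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .network_io import WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = ["SubgraphState", "ValueTable", "density", "bin_index"]


@dataclass(frozen=True)
class SubgraphState:
    """A subgraph summarized by its member set and summed edge weight.

    ``d`` is the weighted density ``2*m / (n*(n-1))`` for ``n >= 2`` nodes,
    where ``m`` is the sum of induced edge weights; defined as 0 for
    subgraphs of fewer than two nodes.
    """

    members: frozenset
    m: float

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def d(self) -> float:
        n = self.n
        if n < 2:
            return 0.0
        return 2.0 * self.m / (n * (n - 1))

    def with_node(self, node: str, network: WeightedNetwork) -> "SubgraphState":
        """State after adding ``node``, updating ``m`` incrementally.

        ``m`` changes by exactly the summed weights of ``node``'s edges
        into the current members.
        """
        if node in self.members:
            raise ValueError(f"node {node!r} already in subgraph")
        delta = 0.0
        for u in self.members:
            if network.has_edge(node, u):
                delta += network.weight(node, u)
        return SubgraphState(self.members | {node}, self.m + delta)


def density(members: Iterable[str], network: WeightedNetwork) -> SubgraphState:
    """Exact density state of the subgraph induced by ``members``.

    Raises ``KeyError`` if any member is absent from the network.
    """
    mem = frozenset(members)
    for node in mem:
        if not network.has_node(node):
            raise KeyError(f"node {node!r} not in network")
    return SubgraphState(mem, network.induced_weight(mem))


def bin_index(d: float, n_bins: int = 20) -> int:
    """Map a density to its bin: bin b covers [b/n_bins, (b+1)/n_bins).

    The top bin is closed at 1.  Densities above 1 (possible only with
    out-of-range edge weights) clamp to the top bin with a warning.
    Negative densities are an error.
    """
    if d < 0:
        raise ValueError(f"negative density {d}")
    if d > 1.0:
        logger.warning("density %g above 1; clamping to top bin", d)
        return n_bins - 1
    b = int(math.floor(d * n_bins))
    return min(b, n_bins - 1)


def _zeros() -> np.ndarray:  # default factory placeholder, replaced in __post_init__
    return np.zeros(0)


@dataclass
class ValueTable:
    """Discretized density -> value map plus the reward/discount scheme.

    Values start at zero.  With the default rewards (+0.2 / -0.2 / 0) and
    discount 0.5, every stored value is bounded by 0.2 / (1 - 0.5) = 0.4
    in absolute value throughout training (geometric-series bound).
    """

    n_bins: int = 20
    gamma: float = 0.5
    reward_correct: float = 0.2
    reward_wrong: float = -0.2
    reward_terminal: float = 0.0
    values: np.ndarray = field(default_factory=_zeros)
    trained_on: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.gamma < 1:
            raise ValueError(f"gamma must be in [0, 1), got {self.gamma}")
        if self.n_bins < 1:
            raise ValueError("n_bins must be positive")
        if self.values.size == 0:
            self.values = np.zeros(self.n_bins)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.n_bins,):
            raise ValueError(
                f"values has shape {self.values.shape}, expected ({self.n_bins},)"
            )

    # -- lookups ---------------------------------------------------------

    def bin_of(self, d: float) -> int:
        return bin_index(d, self.n_bins)

    def lookup(self, d: float) -> float:
        return float(self.values[self.bin_of(d)])

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_bins + 1)

    @property
    def bin_midpoints(self) -> np.ndarray:
        edges = self.bin_edges
        return (edges[:-1] + edges[1:]) / 2.0

    def value_bound(self) -> float:
        r = max(abs(self.reward_correct), abs(self.reward_wrong),
                abs(self.reward_terminal))
        return r / (1.0 - self.gamma)

    # -- update ----------------------------------------------------------

    def bellman_update(
        self,
        current_state: SubgraphState,
        actions: Sequence[tuple[float, SubgraphState]],
    ) -> tuple[float, int]:
        """Max-over-actions update of the current state's bin.

        Each action is ``(reward, next_state)``; its value is
        ``reward + gamma * V(next_state)`` with all next-state values read
        from the table *before* the write (synchronous within one step).
        The current bin is overwritten with the max action value.  Returns
        ``(updated_value, best_action_index)``; ties break to the lowest
        index.
        """
        if len(actions) == 0:
            raise ValueError("bellman_update requires at least one action")
        action_values = [r + self.gamma * self.lookup(st.d) for r, st in actions]
        best_idx = 0
        best_val = action_values[0]
        for i, v in enumerate(action_values[1:], start=1):
            if v > best_val:
                best_val, best_idx = v, i
        self.values[self.bin_of(current_state.d)] = best_val
        return best_val, best_idx

    # -- misc ------------------------------------------------------------

    def copy(self) -> "ValueTable":
        return ValueTable(
            n_bins=self.n_bins,
            gamma=self.gamma,
            reward_correct=self.reward_correct,
            reward_wrong=self.reward_wrong,
            reward_terminal=self.reward_terminal,
            values=self.values.copy(),
            trained_on=self.trained_on,
        )

    def equals(self, other: "ValueTable") -> bool:
        return (
            self.n_bins == other.n_bins
            and self.gamma == other.gamma
            and self.reward_correct == other.reward_correct
            and self.reward_wrong == other.reward_wrong
            and self.reward_terminal == other.reward_terminal
            and bool(np.array_equal(self.values, other.values))
        )
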