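"""Learn the density->value table by replaying growth episodes.

Each episode grows a subgraph from a seed edge inside one training
complex.  At every step all neighbors of the current subgraph are scored
as actions (correct-member reward vs wrong-member reward) together with a
terminal "stop growing" action; the current state's bin is overwritten
with the max action value and the argmax neighbor is added permanently.
Epochs sweep every node of every complex as a start node and repeat until
the table stops changing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .network_io import ComplexCollection, WeightedNetwork
from .state_value import SubgraphState, ValueTable, density

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "TrainingHistory",
    "EpisodeStep",
    "select_training_seed_edge",
    "run_training_episode",
    "train",
]


@dataclass
class TrainingConfig:
    gamma: float = 0.5
    reward_correct: float = 0.2
    reward_wrong: float = -0.2
    reward_terminal: float = 0.0
    n_bins: int = 20
    tolerance: float = 1e-3
    max_epochs: int = 50
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.gamma < 1:
            raise ValueError("gamma must lie in [0, 1)")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be at least 1")

    def new_table(self, trained_on: str | None = None) -> ValueTable:
        return ValueTable(
            n_bins=self.n_bins,
            gamma=self.gamma,
            reward_correct=self.reward_correct,
            reward_wrong=self.reward_wrong,
            reward_terminal=self.reward_terminal,
            trained_on=trained_on,
        )


@dataclass
class TrainingHistory:
    """Per-bin value series (one entry per update touching the bin) and
    per-epoch maximum absolute table change."""

    bin_series: dict[int, list[float]] = field(default_factory=dict)
    epoch_max_change: list[float] = field(default_factory=list)
    converged: bool = False
    n_epochs: int = 0
    n_updates: int = 0

    def record_update(self, bin_idx: int, value: float) -> None:
        self.bin_series.setdefault(bin_idx, []).append(value)
        self.n_updates += 1


@dataclass(frozen=True)
class EpisodeStep:
    """One Bellman update: the state it touched and what was chosen."""

    members: frozenset
    density: float
    bin: int
    updated_value: float
    chosen: str | None  # None when the terminal action won
    action_values: tuple[float, ...]


def select_training_seed_edge(
    complex_members: frozenset | set,
    start_node: str,
    network: WeightedNetwork,
) -> tuple[str, str] | None:
    """Seed edge for an episode: the start node plus its heaviest in-complex
    neighbor (lexicographically smallest on weight ties).

    Returns ``None`` when the start node has no neighbor inside the
    complex (the episode is skipped).
    """
    if start_node not in complex_members:
        raise ValueError(f"start node {start_node!r} not in complex")
    in_complex = [
        n for n in network.neighbors(start_node) if n in complex_members
    ]
    if not in_complex:
        return None
    partner = min(in_complex, key=lambda n: (-network.weight(start_node, n), n))
    return (start_node, partner)


def run_training_episode(
    complex_members: frozenset | set,
    start_node: str,
    table: ValueTable,
    network: WeightedNetwork,
    history: TrainingHistory | None = None,
) -> list[EpisodeStep] | None:
    """Grow one subgraph from ``start_node`` over its training complex.

    Actions are enumerated over the sorted neighbors of the current
    subgraph, followed by the terminal action (terminal reward, next state
    equal to the current state).  The argmax neighbor is added even when
    it lies outside the complex; the episode ends when the terminal action
    attains the max.  Returns the trace of updates, or ``None`` if no seed
    edge exists.
    """
    seed = select_training_seed_edge(complex_members, start_node, network)
    if seed is None:
        logger.warning(
            "start node %r isolated within its complex; skipping episode",
            start_node,
        )
        return None
    members = frozenset(seed)
    state = density(members, network)
    trace: list[EpisodeStep] = []
    while True:
        neighbors = sorted(network.subgraph_neighbors(state.members))
        actions: list[tuple[float, SubgraphState]] = []
        for nbr in neighbors:
            reward = (
                table.reward_correct
                if nbr in complex_members
                else table.reward_wrong
            )
            actions.append((reward, state.with_node(nbr, network)))
        actions.append((table.reward_terminal, state))
        action_values = tuple(
            r + table.gamma * table.lookup(st.d) for r, st in actions
        )
        updated, best_idx = table.bellman_update(state, actions)
        if history is not None:
            history.record_update(table.bin_of(state.d), updated)
        terminal_chosen = best_idx == len(neighbors)
        trace.append(
            EpisodeStep(
                members=state.members,
                density=state.d,
                bin=table.bin_of(state.d),
                updated_value=updated,
                chosen=None if terminal_chosen else neighbors[best_idx],
                action_values=action_values,
            )
        )
        if terminal_chosen:
            return trace
        state = actions[best_idx][1]


def train(
    complexes: ComplexCollection,
    network: WeightedNetwork,
    config: TrainingConfig | None = None,
) -> tuple[ValueTable, TrainingHistory]:
    """Value iteration over all training complexes until convergence.

    Each epoch runs one episode per (complex, start node) pair, with start
    nodes shuffled by the configured seed; training stops when the maximum
    absolute change of the table over an epoch falls below the tolerance,
    or after ``max_epochs`` epochs.
    """
    if config is None:
        config = TrainingConfig()
    if len(complexes) == 0:
        raise ValueError("cannot train on an empty complex collection")
    table = config.new_table(trained_on=f"{len(complexes)} complexes")
    history = TrainingHistory()
    rng = np.random.default_rng(config.rng_seed)
    bound = table.value_bound()

    for epoch in range(config.max_epochs):
        values_before = table.values.copy()
        for name, members in complexes:
            present = sorted(m for m in members if network.has_node(m))
            if not present:
                logger.warning("complex %s has no members in network", name)
                continue
            order = [str(x) for x in rng.permutation(present)]
            for start in order:
                run_training_episode(members, start, table, network, history)
        max_change = float(np.max(np.abs(table.values - values_before)))
        history.epoch_max_change.append(max_change)
        history.n_epochs = epoch + 1
        if np.max(np.abs(table.values)) > bound + 1e-12:
            raise AssertionError(
                "value bound violated: |V| exceeds reward/(1-gamma)"
            )
        if max_change < config.tolerance:
            history.converged = True
            logger.info("converged after %d epochs (max change %.2e)",
                        epoch + 1, max_change)
            break
    if not history.converged:
        logger.warning("did not converge within %d epochs (last change %.2e)",
                       config.max_epochs, history.epoch_max_change[-1])
    return table, history
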