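"""Node profiling and reliable-negative inference for positive-unlabeled learning.

After clustering drug pairs on a GSOM, each node is profiled from the
labels of its members (``positive`` = known interacting pair, ``unlabeled``
= everything else):

* ``negative``  — every member unlabeled: the node sits away from all known
  interactions, so its members are inferred non-interacting pairs;
* ``positive``  — every member a known positive;
* ``ambiguous`` — a mix: its unlabeled members resemble known interactions
  and form the prediction universe;
* ``excluded``  — fewer members than ``min_node_size`` (default 2): too
  small to trust, dropped to limit false negatives.

Running the procedure under two feature representations and intersecting
the negative sets gives the *consensus* negatives used to train the
classifier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .errors import LabelConflictError
from .gsom import GSOMMap
from .similarity import POSITIVE, UNLABELED, PairKey

NODE_POSITIVE = "positive"
NODE_NEGATIVE = "negative"
NODE_AMBIGUOUS = "ambiguous"
NODE_EXCLUDED = "excluded"


def positive_proportion(n_positive: int, n_members: int) -> float:
    """Fraction of a node's members that are labeled positive."""
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    if not 0 <= n_positive <= n_members:
        raise ValueError("need 0 <= n_positive <= n_members")
    return n_positive / n_members


@dataclass(frozen=True)
class NodeProfile:
    node_id: int
    member_pairs: tuple[PairKey, ...]
    n_members: int
    n_positive: int
    positive_proportion: float
    label: str  # positive | negative | ambiguous | excluded

    def unlabeled_members(self, labels: Mapping[PairKey, str]) -> tuple[PairKey, ...]:
        return tuple(p for p in self.member_pairs if labels[p] == UNLABELED)


@dataclass(frozen=True)
class NegativeSet:
    """Inferred non-interacting pairs with their provenance."""

    pairs: frozenset[PairKey]
    provenance: str  # e.g. SFR1 | SFR2 | consensus | random-baseline

    def __len__(self) -> int:
        return len(self.pairs)


def profile_nodes(
    map_: GSOMMap,
    labels: Mapping[PairKey, str],
    min_node_size: int = 2,
) -> list[NodeProfile]:
    """Profile every node of ``map_`` from its members' PU labels.

    Nodes smaller than ``min_node_size`` are ``excluded``; otherwise a node
    is ``negative`` iff it holds no positives, ``positive`` iff it holds
    only positives, and ``ambiguous`` in between.
    """
    if min_node_size < 1:
        raise ValueError("min_node_size must be >= 1")
    profiles = []
    for node_id, members in sorted(map_.members().items()):
        n_pos = 0
        for p in members:
            lab = labels.get(p)
            if lab is None:
                raise KeyError(f"pair {p!r} assigned to node {node_id} has no label")
            if lab == POSITIVE:
                n_pos += 1
            elif lab != UNLABELED:
                raise LabelConflictError(f"pair {p!r} has unknown label {lab!r}")
        n = len(members)
        if n == 0:
            continue  # pruned nodes cannot occur, but be safe
        if n < min_node_size:
            label = NODE_EXCLUDED
        elif n_pos == 0:
            label = NODE_NEGATIVE
        elif n_pos == n:
            label = NODE_POSITIVE
        else:
            label = NODE_AMBIGUOUS
        profiles.append(
            NodeProfile(
                node_id=node_id,
                member_pairs=tuple(members),
                n_members=n,
                n_positive=n_pos,
                positive_proportion=positive_proportion(n_pos, n),
                label=label,
            )
        )
    return profiles


def infer_negatives(profiles: Iterable[NodeProfile], provenance: str = "map") -> NegativeSet:
    """Union of member pairs over negative-labeled nodes."""
    pairs: set[PairKey] = set()
    for prof in profiles:
        if prof.label == NODE_NEGATIVE:
            pairs.update(prof.member_pairs)
    return NegativeSet(pairs=frozenset(pairs), provenance=provenance)


def consensus_negatives(a: NegativeSet, b: NegativeSet) -> NegativeSet:
    """Pairs inferred negative under both representations."""
    return NegativeSet(pairs=a.pairs & b.pairs, provenance="consensus")


def ambiguous_unlabeled_pairs(
    profiles: Iterable[NodeProfile], labels: Mapping[PairKey, str]
) -> set[PairKey]:
    """Unlabeled members of ambiguous nodes — the prediction universe."""
    out: set[PairKey] = set()
    for prof in profiles:
        if prof.label == NODE_AMBIGUOUS:
            out.update(prof.unlabeled_members(labels))
    return out


def profiles_to_frame(profiles: Iterable[NodeProfile]) -> pd.DataFrame:
    """Tabular view of node profiles (one row per node)."""
    return pd.DataFrame(
        [
            {
                "node_id": p.node_id,
                "n_members": p.n_members,
                "n_positive": p.n_positive,
                "positive_proportion": p.positive_proportion,
                "label": p.label,
            }
            for p in profiles
        ]
    )
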