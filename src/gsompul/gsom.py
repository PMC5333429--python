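"""Growing Self-Organizing Map (GSOM) clustering.

A GSOM is a self-organizing map that starts from a small lattice (here
2 x 2) and adds nodes where the map under-represents the data.  Each
presented input updates its best-matching unit (BMU) and the BMU's lattice
neighborhood with the usual SOM rule; the BMU additionally accumulates its
squared quantization error.  When a node's accumulated error exceeds the
growth threshold

    GT = -D * ln(spread_factor)

(D = input dimensionality), the map grows: a boundary node spawns new nodes
into all free orthogonal lattice positions (weights set by neighbor
interpolation/extrapolation), while an interior node redistributes part of
its error to its lattice neighbors.  The spread factor in (0, 1] therefore
controls map size: values near 1 give a permissive threshold and a large
map, tiny values suppress growth.

Training is two-phase (growing then smoothing, where smoothing runs with a
small learning rate, a tight neighborhood and no growth), fully
deterministic given the seed.  The inner loop is JIT-compiled with numba
when available and falls back to the identical pure-Python code otherwise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyMapError, GsomPulError

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


def growth_threshold(D: int, spread_factor: float) -> float:
    """Growth threshold -D * ln(spread_factor); 0 iff spread_factor == 1."""
    if D < 1:
        raise ValueError("dimensionality must be >= 1")
    if not 0 < spread_factor <= 1:
        raise ValueError(f"spread_factor must be in (0, 1], got {spread_factor}")
    return -float(D) * math.log(spread_factor)


@dataclass(frozen=True)
class GSOMConfig:
    """Training hyper-parameters.

    ``spread_factor`` is the only parameter tied to the method itself; the
    rest are standard SOM schedule choices.  Learning rate decays linearly
    within each phase; the Gaussian neighborhood radius shrinks linearly
    from ``neighborhood_radius_initial`` to ``neighborhood_radius_final``
    over the growing phase and stays at the final value while smoothing.
    """

    spread_factor: float = 0.1
    learning_rate_initial: float = 0.3
    smoothing_learning_rate: float = 0.05
    growing_epochs: int = 20
    smoothing_epochs: int = 10
    neighborhood_radius_initial: float = 2.0
    neighborhood_radius_final: float = 0.5
    error_distribution_factor: float = 0.5
    random_seed: int = 0
    max_nodes: int = 1200

    def __post_init__(self) -> None:
        if not 0 < self.spread_factor <= 1:
            raise ValueError("spread_factor must be in (0, 1]")
        if self.growing_epochs < 1 or self.smoothing_epochs < 1:
            raise ValueError("epoch counts must be >= 1")
        if not 0 < self.error_distribution_factor < 1:
            raise ValueError("error_distribution_factor must be in (0, 1)")
        if self.learning_rate_initial <= 0 or self.smoothing_learning_rate <= 0:
            raise ValueError("learning rates must be positive")
        if self.max_nodes < 4:
            raise ValueError("max_nodes must allow at least the initial lattice")


@dataclass(frozen=True)
class GSOMNode:
    node_id: int
    grid_position: tuple[int, int]
    weight: np.ndarray
    accumulated_error: float


@dataclass
class GSOMMap:
    """Trained map: surviving nodes plus the input -> node assignment."""

    nodes: list[GSOMNode]
    dimensionality: int
    growth_threshold: float
    assignment: dict[Hashable, int]
    config: GSOMConfig

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def weight_matrix(self) -> np.ndarray:
        if not self.nodes:
            raise EmptyMapError("map has no nodes")
        return np.vstack([n.weight for n in self.nodes])

    def members(self) -> dict[int, list[Hashable]]:
        """Node id -> list of assigned sample ids (assignment order)."""
        out: dict[int, list[Hashable]] = {n.node_id: [] for n in self.nodes}
        for sid, nid in self.assignment.items():
            out[nid].append(sid)
        return out

    # ---- serialization (single structured text file) -------------------
    def to_json(self) -> str:
        payload = {
            "dimensionality": self.dimensionality,
            "growth_threshold": self.growth_threshold,
            "config": self.config.__dict__,
            "nodes": [
                {
                    "node_id": n.node_id,
                    "grid_x": n.grid_position[0],
                    "grid_y": n.grid_position[1],
                    "weight": [float(w) for w in n.weight],
                    "accumulated_error": n.accumulated_error,
                    "members": [list(s) if isinstance(s, tuple) else s
                                for s, nid in self.assignment.items() if nid == n.node_id],
                }
                for n in self.nodes
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GSOMMap":
        payload = json.loads(text)
        nodes = []
        assignment: dict[Hashable, int] = {}
        for nd in payload["nodes"]:
            nodes.append(
                GSOMNode(
                    node_id=int(nd["node_id"]),
                    grid_position=(int(nd["grid_x"]), int(nd["grid_y"])),
                    weight=np.asarray(nd["weight"], dtype=float),
                    accumulated_error=float(nd["accumulated_error"]),
                )
            )
            for s in nd["members"]:
                key = tuple(s) if isinstance(s, list) else s
                assignment[key] = int(nd["node_id"])
        return cls(
            nodes=nodes,
            dimensionality=int(payload["dimensionality"]),
            growth_threshold=float(payload["growth_threshold"]),
            assignment=assignment,
            config=GSOMConfig(**payload["config"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "GSOMMap":
        with open(path) as fh:
            return cls.from_json(fh.read())


def find_bmu(map_: GSOMMap, x: np.ndarray) -> int:
    """Node id minimizing squared Euclidean distance to ``x``; ties -> smallest id."""
    if not map_.nodes:
        raise EmptyMapError("cannot find BMU on an empty map")
    x = np.asarray(x, dtype=float)
    if x.shape != (map_.dimensionality,):
        raise ValueError(
            f"input has shape {x.shape}, map dimensionality is {map_.dimensionality}"
        )
    W = map_.weight_matrix()
    d = ((W - x) ** 2).sum(axis=1)
    return map_.nodes[int(np.argmin(d))].node_id


@njit(cache=False)
def _run_span(data, order, start, weights, errors, pos, n_nodes, lr, sigma, gt, grow):
    """Present inputs order[start:]; stop early when a node must grow.

    Returns (next_start, winner): winner >= 0 flags a growth event at that
    node after processing order[next_start - 1]; winner == -1 means the
    span completed.  BMU ties resolve to the smallest node index because the
    scan keeps the first minimum.
    """
    d = data.shape[1]
    two_s2 = 2.0 * sigma * sigma
    for t in range(start, order.shape[0]):
        i = order[t]
        best = 0
        bestd = 1e300
        for k in range(n_nodes):
            s = 0.0
            for j in range(d):
                diff = data[i, j] - weights[k, j]
                s += diff * diff
            if s < bestd:
                bestd = s
                best = k
        for k in range(n_nodes):
            dx = pos[k, 0] - pos[best, 0]
            dy = pos[k, 1] - pos[best, 1]
            h = math.exp(-(dx * dx + dy * dy) / two_s2)
            if h > 1e-3:
                a = lr * h
                for j in range(d):
                    weights[k, j] += a * (data[i, j] - weights[k, j])
        if grow:
            errors[best] += bestd
            if errors[best] > gt:
                return t + 1, best
    return order.shape[0], -1


_ORTH = ((1, 0), (-1, 0), (0, 1), (0, -1))


class _Trainer:
    """Mutable training state; exists so growth bookkeeping stays readable."""

    def __init__(self, X: np.ndarray, config: GSOMConfig, rng: np.random.Generator):
        self.X = X
        self.config = config
        self.rng = rng
        n, d = X.shape
        self.d = d
        self.gt = growth_threshold(d, config.spread_factor)
        cap = 64
        self.weights = np.zeros((cap, d), dtype=float)
        self.errors = np.zeros(cap, dtype=float)
        self.pos = np.zeros((cap, 2), dtype=np.int64)
        init_positions = [(0, 0), (1, 0), (0, 1), (1, 1)]
        init_rows = rng.choice(n, size=4, replace=False)
        for k, (p, r) in enumerate(zip(init_positions, init_rows)):
            self.weights[k] = X[r]
            self.pos[k] = p
        self.n_nodes = 4
        self.pos2idx = {p: k for k, p in enumerate(init_positions)}

    def _ensure_capacity(self, extra: int) -> None:
        need = self.n_nodes + extra
        cap = self.weights.shape[0]
        if need <= cap:
            return
        new_cap = max(need, cap * 2)
        self.weights = np.vstack(
            [self.weights, np.zeros((new_cap - cap, self.d))]
        )
        self.errors = np.concatenate([self.errors, np.zeros(new_cap - cap)])
        self.pos = np.vstack(
            [self.pos, np.zeros((new_cap - cap, 2), dtype=np.int64)]
        )

    def _new_weight(self, winner: int, q: tuple[int, int]) -> np.ndarray:
        """Initialize a node grown at free position ``q`` next to ``winner``."""
        px, py = int(self.pos[winner, 0]), int(self.pos[winner, 1])
        w_win = self.weights[winner]
        opp = (2 * px - q[0], 2 * py - q[1])
        if opp in self.pos2idx:  # extrapolate through the winner
            return 2.0 * w_win - self.weights[self.pos2idx[opp]]
        beyond = (2 * q[0] - px, 2 * q[1] - py)
        if beyond in self.pos2idx:  # interpolate between winner and far node
            return 0.5 * (w_win + self.weights[self.pos2idx[beyond]])
        for dx, dy in _ORTH:
            r = (px + dx, py + dy)
            if r != q and r in self.pos2idx:
                return 2.0 * w_win - self.weights[self.pos2idx[r]]
        return w_win + self.rng.normal(0.0, 1e-3, size=self.d)

    def handle_growth(self, winner: int) -> None:
        p = (int(self.pos[winner, 0]), int(self.pos[winner, 1]))
        free = [
            (p[0] + dx, p[1] + dy)
            for dx, dy in _ORTH
            if (p[0] + dx, p[1] + dy) not in self.pos2idx
        ]
        if not free:
            # interior node: push error outward instead of growing
            old = self.errors[winner]
            for dx, dy in _ORTH:
                k = self.pos2idx.get((p[0] + dx, p[1] + dy))
                if k is not None:
                    self.errors[k] += self.config.error_distribution_factor * old
            self.errors[winner] = self.gt / 2.0
            return
        if self.n_nodes + len(free) > self.config.max_nodes:
            self.errors[winner] = self.gt / 2.0
            return
        self._ensure_capacity(len(free))
        for q in free:
            k = self.n_nodes
            self.weights[k] = self._new_weight(winner, q)
            self.pos[k] = q
            self.errors[k] = 0.0
            self.pos2idx[q] = k
            self.n_nodes += 1
        self.errors[winner] = self.gt / 2.0

    def run(self) -> None:
        cfg = self.config
        n = self.X.shape[0]
        for phase, n_epochs, grow in (
            ("grow", cfg.growing_epochs, True),
            ("smooth", cfg.smoothing_epochs, False),
        ):
            for ep in range(n_epochs):
                frac = ep / max(n_epochs - 1, 1)
                if grow:
                    lr = cfg.learning_rate_initial * (1.0 - 0.9 * frac)
                    sigma = (
                        cfg.neighborhood_radius_initial
                        + (cfg.neighborhood_radius_final - cfg.neighborhood_radius_initial) * frac
                    )
                else:
                    lr = cfg.smoothing_learning_rate * (1.0 - 0.9 * frac)
                    sigma = cfg.neighborhood_radius_final
                order = self.rng.permutation(n).astype(np.int64)
                start = 0
                while start < n:
                    start, winner = _run_span(
                        self.X,
                        order,
                        start,
                        self.weights,
                        self.errors,
                        self.pos,
                        self.n_nodes,
                        float(lr),
                        float(sigma),
                        float(self.gt),
                        grow,
                    )
                    if winner >= 0:
                        self.handle_growth(winner)


def train_gsom(
    vectors: np.ndarray,
    config: GSOMConfig | None = None,
    sample_ids: Sequence[Hashable] | None = None,
) -> GSOMMap:
    """Train a GSOM on ``vectors`` (rows = inputs).

    ``sample_ids`` names the rows in the returned assignment (defaults to
    row indices).  Nodes left with no assigned input are pruned, so every
    surviving node has at least one member.  Deterministic per seed.
    """
    X = np.ascontiguousarray(np.asarray(vectors, dtype=float))
    if X.ndim != 2 or X.shape[0] < 4:
        raise ValueError("need a 2-D array with at least 4 input rows")
    if not np.isfinite(X).all():
        raise GsomPulError("non-finite values in GSOM input")
    config = config or GSOMConfig()
    if sample_ids is None:
        ids: list[Hashable] = list(range(X.shape[0]))
    else:
        ids = list(sample_ids)
        if len(ids) != X.shape[0]:
            raise ValueError("sample_ids length must match number of rows")

    rng = np.random.default_rng(config.random_seed)
    trainer = _Trainer(X, config, rng)
    trainer.run()

    W = trainer.weights[: trainer.n_nodes]
    # final assignment: BMU per input, ties to the smallest node index
    d2 = ((X[:, None, :] - W[None, :, :]) ** 2).sum(axis=2) if X.shape[0] * trainer.n_nodes * X.shape[1] < 2_000_000 else None
    if d2 is not None:
        winners = np.argmin(d2, axis=1)
    else:
        from scipy.spatial.distance import cdist

        winners = np.argmin(cdist(X, W, metric="sqeuclidean"), axis=1)

    occupied = sorted(set(int(w) for w in winners))
    remap = {old: new for new, old in enumerate(occupied)}
    nodes = [
        GSOMNode(
            node_id=remap[old],
            grid_position=(int(trainer.pos[old, 0]), int(trainer.pos[old, 1])),
            weight=W[old].copy(),
            accumulated_error=float(trainer.errors[old]),
        )
        for old in occupied
    ]
    assignment = {sid: remap[int(w)] for sid, w in zip(ids, winners)}
    return GSOMMap(
        nodes=nodes,
        dimensionality=X.shape[1],
        growth_threshold=trainer.gt,
        assignment=assignment,
        config=config,
    )


def awcd(
    map_: GSOMMap,
    vectors: np.ndarray,
    sample_ids: Sequence[Hashable] | None = None,
) -> float:
    """Average within-cluster distance.

    Sum over all inputs of the squared Euclidean distance to their winning
    node's weight, divided by the number of nodes.
    """
    if not map_.nodes:
        raise EmptyMapError("AWCD needs a non-empty map")
    X = np.asarray(vectors, dtype=float)
    ids = list(range(X.shape[0])) if sample_ids is None else list(sample_ids)
    if len(ids) != X.shape[0]:
        raise ValueError("sample_ids length must match number of rows")
    weights = {n.node_id: n.weight for n in map_.nodes}
    total = 0.0
    for sid, x in zip(ids, X):
        nid = map_.assignment.get(sid)
        if nid is None:
            raise ValueError(f"sample {sid!r} has no node assignment")
        total += float(((x - weights[nid]) ** 2).sum())
    return total / map_.n_nodes


def sweep_spread_factor(
    vectors: np.ndarray,
    spread_factors: Sequence[float],
    config: GSOMConfig | None = None,
    sample_ids: Sequence[Hashable] | None = None,
    min_node_size: int = 2,
) -> pd.DataFrame:
    """Train one map per spread factor (same seed) and tabulate diagnostics.

    The node count excludes single-instance nodes (more generally nodes
    below ``min_node_size``), matching how map sizes are compared when
    choosing a spread factor.
    """
    config = config or GSOMConfig()
    rows = []
    for sf in spread_factors:
        cfg = replace(config, spread_factor=float(sf))
        m = train_gsom(vectors, cfg, sample_ids=sample_ids)
        sizes = {nid: len(mem) for nid, mem in m.members().items()}
        n_kept = sum(1 for s in sizes.values() if s >= min_node_size)
        rows.append(
            {
                "spread_factor": float(sf),
                "growth_threshold": m.growth_threshold,
                "n_nodes": m.n_nodes,
                "n_nodes_min_size": n_kept,
                "awcd": awcd(m, vectors, sample_ids=sample_ids),
            }
        )
    return pd.DataFrame(rows)


def plot_map(map_: GSOMMap, node_values: Mapping[int, float] | None = None, path=None):
    """Scatter the node lattice, optionally colored by a per-node value
    (e.g. positive proportion).  Returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = [n.grid_position[0] for n in map_.nodes]
    ys = [n.grid_position[1] for n in map_.nodes]
    c = None
    if node_values is not None:
        c = [node_values.get(n.node_id, np.nan) for n in map_.nodes]
    fig, ax = plt.subplots(figsize=(6, 6))
    sc = ax.scatter(xs, ys, c=c, cmap="coolwarm", s=60, edgecolor="k", linewidth=0.3)
    if c is not None:
        fig.colorbar(sc, ax=ax, label="positive proportion")
    ax.set_xlabel("grid x")
    ax.set_ylabel("grid y")
    ax.set_title(f"GSOM lattice ({map_.n_nodes} nodes)")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
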