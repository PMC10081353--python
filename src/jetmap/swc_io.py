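"""Reading, writing and decomposing SWC neuron traces.

An SWC file stores a neuron reconstruction as a rooted tree of sample
points ("knots"): one row per point with columns
``id type x y z radius parent``.  Coordinates and radii are in microns and
``parent == -1`` marks a root.  The mapping machinery in this package
operates on non-branching curves, so trees are decomposed into
:class:`PolylineBranch` objects — ordered knot sequences parameterized by
cumulative arc length — by recursively peeling off the longest
root-to-leaf path.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "NeuronNode",
    "NeuronTree",
    "PolylineBranch",
    "SWCParseError",
    "SWCValidationError",
    "read_swc",
    "write_swc",
    "decompose_to_branches",
    "arc_length_parameterize",
    "downsample_branch",
    "branches_to_csv",
]


class SWCParseError(ValueError):
    """A malformed SWC line (names the offending line number)."""


class SWCValidationError(ValueError):
    """Structurally invalid tree: duplicate ids, dangling parents, cycles."""


@dataclass
class NeuronNode:
    """One SWC sample point.

    Attributes
    ----------
    id : int
        Identifier, unique within a tree.
    type_code : int
        SWC structure code (soma, axon, dendrite, ...); carried through
        unchanged, never interpreted.
    position : ndarray, shape (3,)
        x, y, z in microns.
    radius : float
        Local radius in microns (non-negative; not used by the mapping).
    parent_id : int
        Parent node id, or -1 for a root.
    """

    id: int
    type_code: int
    position: np.ndarray
    radius: float
    parent_id: int

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise SWCValidationError(f"node {self.id}: position must be a 3-vector")
        if self.radius < 0:
            raise SWCValidationError(f"node {self.id}: negative radius {self.radius}")


class NeuronTree:
    """A rooted tree of :class:`NeuronNode` (one connected SWC component)."""

    def __init__(self, nodes: Sequence[NeuronNode]):
        self.nodes: dict[int, NeuronNode] = {}
        for node in nodes:
            if node.id in self.nodes:
                raise SWCValidationError(f"duplicate node id {node.id}")
            self.nodes[node.id] = node
        roots = [n.id for n in nodes if n.parent_id == -1]
        if len(roots) != 1:
            raise SWCValidationError(f"expected exactly one root, found {len(roots)}")
        self.root_id: int = roots[0]
        self._node_order = [n.id for n in nodes]  # preserve file order
        self.children: dict[int, list[int]] = {nid: [] for nid in self.nodes}
        for node in nodes:
            if node.parent_id != -1:
                if node.parent_id not in self.nodes:
                    raise SWCValidationError(
                        f"node {node.id}: dangling parent {node.parent_id}"
                    )
                self.children[node.parent_id].append(node.id)
        self._check_acyclic_connected()

    def _check_acyclic_connected(self) -> None:
        seen = set()
        stack = [self.root_id]
        while stack:
            nid = stack.pop()
            if nid in seen:
                raise SWCValidationError("cycle detected in parent links")
            seen.add(nid)
            stack.extend(self.children[nid])
        if len(seen) != len(self.nodes):
            orphans = set(self.nodes) - seen
            raise SWCValidationError(
                f"nodes unreachable from root {self.root_id}: {sorted(orphans)[:5]}"
            )

    def __len__(self) -> int:
        return len(self.nodes)

    def node_ids(self) -> list[int]:
        """Node ids in original file order."""
        return list(self._node_order)

    def leaves(self) -> list[int]:
        return [nid for nid, ch in self.children.items() if not ch]

    def edge_length(self, child_id: int) -> float:
        child = self.nodes[child_id]
        parent = self.nodes[child.parent_id]
        return float(np.linalg.norm(child.position - parent.position))

    def positions(self) -> np.ndarray:
        """(n, 3) array of node positions in file order."""
        return np.array([self.nodes[i].position for i in self._node_order])

    def with_positions(self, positions: np.ndarray) -> "NeuronTree":
        """Copy of the tree with node positions replaced (file order)."""
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (len(self), 3):
            raise ValueError("positions must be (n_nodes, 3)")
        new_nodes = [
            NeuronNode(n.id, n.type_code, pos, n.radius, n.parent_id)
            for n, pos in zip((self.nodes[i] for i in self._node_order), positions)
        ]
        return NeuronTree(new_nodes)


@dataclass
class PolylineBranch:
    """A non-branching polyline curve parameterized by arc length.

    ``params[i]`` is the cumulative chord length up to knot ``i``, so the
    piecewise-linear curve through the knots is unit speed: every segment's
    parameter increment equals its Euclidean length.
    """

    knots: np.ndarray  # (n, 3) microns
    params: np.ndarray  # (n,) cumulative arc length, microns
    source_ids: list[int] | None = None

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        self.params = np.asarray(self.params, dtype=float)
        if self.knots.ndim != 2 or self.knots.shape[1] != 3:
            raise ValueError("knots must be (n, 3)")
        if self.params.shape != (self.knots.shape[0],):
            raise ValueError("params length must match knots")
        if len(self.params) and self.params[0] != 0.0:
            raise ValueError("params must start at 0")
        if np.any(np.diff(self.params) <= 0):
            raise ValueError("params must be strictly increasing")
        seg = np.linalg.norm(np.diff(self.knots, axis=0), axis=1)
        if not np.allclose(seg, np.diff(self.params), rtol=1e-8, atol=1e-8):
            raise ValueError("params must equal cumulative chord length")

    @property
    def n_knots(self) -> int:
        return self.knots.shape[0]

    @property
    def length(self) -> float:
        return float(self.params[-1])

    @property
    def max_segment_length(self) -> float:
        return float(np.max(np.diff(self.params)))

    @property
    def mean_segment_length(self) -> float:
        return float(np.mean(np.diff(self.params)))

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the piecewise-linear interpolant at parameters ``t``."""
        t = np.asarray(t, dtype=float)
        out = np.empty(t.shape + (3,))
        for j in range(3):
            out[..., j] = np.interp(t, self.params, self.knots[:, j])
        return out


def read_swc(path: str | Path) -> list[NeuronTree]:
    """Read an SWC file into one :class:`NeuronTree` per root.

    Lines starting with ``#`` are comments; data lines have 7
    whitespace-separated fields ``id type x y z radius parent``.  Multiple
    ``parent == -1`` rows yield a forest (one tree each); node order within
    each tree follows the file.
    """
    path = Path(path)
    nodes: list[NeuronNode] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            if len(fields) != 7:
                raise SWCParseError(
                    f"{path.name}:{lineno}: expected 7 fields, got {len(fields)}"
                )
            try:
                nid = int(fields[0])
                type_code = int(fields[1])
                xyz = [float(v) for v in fields[2:5]]
                radius = float(fields[5])
                parent = int(fields[6])
            except ValueError as exc:
                raise SWCParseError(f"{path.name}:{lineno}: {exc}") from None
            nodes.append(NeuronNode(nid, type_code, np.array(xyz), radius, parent))

    ids = [n.id for n in nodes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise SWCValidationError(f"{path.name}: duplicate node ids {dupes[:5]}")

    # Partition the forest: walk parent links up to each component's root.
    by_id = {n.id: n for n in nodes}
    root_of: dict[int, int] = {}

    def find_root(nid: int) -> int:
        trail = []
        while nid not in root_of:
            node = by_id.get(nid)
            if node is None:
                raise SWCValidationError(f"{path.name}: dangling parent {nid}")
            trail.append(nid)
            if node.parent_id == -1:
                root_of[nid] = nid
                break
            nid = node.parent_id
        root = root_of[nid] if nid in root_of else nid
        for t in trail:
            root_of[t] = root
        return root

    for n in nodes:
        find_root(n.id)

    trees = []
    for root in dict.fromkeys(root_of[n.id] for n in nodes):  # stable order
        members = [n for n in nodes if root_of[n.id] == root]
        trees.append(NeuronTree(members))
    return trees


def write_swc(
    trees: NeuronTree | Iterable[NeuronTree],
    path: str | Path,
    renumber: bool = False,
    header: str | None = None,
) -> None:
    """Write trees to a 7-column SWC file.

    With ``renumber=True`` ids are rewritten consecutively from 1 in
    topological (file) order across the whole forest, with parent references
    kept consistent.  Type codes and radii pass through unchanged.
    """
    if isinstance(trees, NeuronTree):
        trees = [trees]
    lines = []
    if header:
        for h in header.splitlines():
            lines.append(f"# {h}")
    counter = 0
    for tree in trees:
        mapping: dict[int, int] = {}
        if renumber:
            for nid in tree.node_ids():
                counter += 1
                mapping[nid] = counter
        for nid in tree.node_ids():
            n = tree.nodes[nid]
            out_id = mapping.get(nid, nid)
            out_parent = -1 if n.parent_id == -1 else mapping.get(n.parent_id, n.parent_id)
            x, y, z = n.position
            lines.append(
                f"{out_id} {n.type_code} {x:.8g} {y:.8g} {z:.8g} {n.radius:.8g} {out_parent}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _path_to_root_lengths(tree: NeuronTree, subtree_root: int) -> dict[int, float]:
    """Arc length from ``subtree_root`` down to every node in its subtree."""
    dist = {subtree_root: 0.0}
    stack = [subtree_root]
    while stack:
        nid = stack.pop()
        for child in tree.children[nid]:
            dist[child] = dist[nid] + tree.edge_length(child)
            stack.append(child)
    return dist


def _longest_leaf_path(tree: NeuronTree, start: int) -> list[int]:
    """Longest (by arc length) path from ``start`` to a leaf in its subtree.

    Ties are broken toward the leaf with the smallest node id, so the
    decomposition is deterministic.
    """
    dist = _path_to_root_lengths(tree, start)
    leaves = [nid for nid in dist if not tree.children[nid]]
    best = min(leaves, key=lambda nid: (-dist[nid], nid))
    # walk back up from the leaf to start
    path = [best]
    while path[-1] != start:
        path.append(tree.nodes[path[-1]].parent_id)
    path.reverse()
    return path


def decompose_to_branches(tree: NeuronTree) -> list[PolylineBranch]:
    """Split a neuron tree into non-branching polyline branches.

    The root-to-leaf path of maximal arc length is removed first; each
    remaining subtree is decomposed recursively with its attachment node
    (the junction knot on the removed path) prepended, so every branch is a
    standalone curve and the branch segments cover every tree edge exactly
    once.  Junction knots are therefore duplicated across incident branches.
    A single-node tree yields an empty list.
    """
    if len(tree) < 2:
        return []
    branches: list[PolylineBranch] = []

    def peel(path_ids: list[int], is_subbranch: bool) -> None:
        branches.append(_branch_from_ids(tree, path_ids))
        on_path = set(path_ids)
        # a sub-branch's first knot is the junction on an already-peeled
        # path; its other subtrees belong to that path's own recursion
        start = 1 if is_subbranch else 0
        for nid in path_ids[start:]:
            for child in tree.children[nid]:
                if child not in on_path:
                    sub = _longest_leaf_path(tree, child)
                    peel([nid] + sub, True)

    peel(_longest_leaf_path(tree, tree.root_id), False)
    return branches


def _branch_from_ids(tree: NeuronTree, ids: list[int]) -> PolylineBranch:
    knots = np.array([tree.nodes[i].position for i in ids])
    branch = arc_length_parameterize(knots)
    kept = branch.source_ids  # indices retained after duplicate repair
    branch.source_ids = [ids[i] for i in kept] if kept is not None else list(ids)
    return branch


def arc_length_parameterize(knots: np.ndarray) -> PolylineBranch:
    """Build a :class:`PolylineBranch` with cumulative chord-length params.

    Consecutive duplicate knots violate regularity (|c'| > 0) and are
    dropped with a warning; ``source_ids`` records the retained indices.
    """
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 2 or knots.shape[1] != 3 or knots.shape[0] < 2:
        raise ValueError("need at least 2 knots of dimension 3")
    kept = np.arange(knots.shape[0])
    n_dropped = 0
    while True:
        seg = np.linalg.norm(np.diff(knots, axis=0), axis=1)
        params = np.concatenate(([0.0], np.cumsum(seg)))
        # a chord may be nonzero yet underflow in the cumulative parameter;
        # such sub-resolution knots are dropped like exact duplicates
        keep = np.concatenate(([True], np.diff(params) > 0))
        if np.all(keep):
            break
        n_dropped += int(np.sum(~keep))
        knots, kept = knots[keep], kept[keep]
        if knots.shape[0] < 2:
            raise ValueError("degenerate curve: all knots identical")
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} duplicate consecutive knot(s) to restore regularity",
            stacklevel=2,
        )
    return PolylineBranch(knots, params, source_ids=list(kept))


def downsample_branch(branch: PolylineBranch, period: int) -> PolylineBranch:
    """Retain both end knots plus every ``period``-th interior knot.

    Interior knots are kept at indices divisible by ``period``; params are
    recomputed as cumulative chord length of the retained knots.  With
    ``period=1`` the branch is returned unchanged.
    """
    if period < 1:
        raise ValueError(f"period must be >= 1, got {period}")
    if period == 1:
        return branch
    n = branch.n_knots
    idx = sorted({0, n - 1} | {i for i in range(1, n - 1) if i % period == 0})
    kept = branch.knots[idx]
    out = arc_length_parameterize(kept)
    if branch.source_ids is not None:
        out.source_ids = [branch.source_ids[i] for i in idx]
    return out


def branches_to_csv(branches: Sequence[PolylineBranch], path: str | Path) -> pd.DataFrame:
    """Export branches as a CSV with columns branch_id, knot_index, t, x, y, z."""
    rows = []
    for bid, br in enumerate(branches):
        for k in range(br.n_knots):
            rows.append(
                dict(branch_id=bid, knot_index=k, t=br.params[k],
                     x=br.knots[k, 0], y=br.knots[k, 1], z=br.knots[k, 2])
            )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
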