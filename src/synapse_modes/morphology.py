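"""SWC neuron morphology: reading, writing and arc-length path distances.

Distances are measured along the reconstruction polyline (piecewise linear
between node centres), emulating filament-tracer distance measurements, not
straight-line (chord) distances. A designated *reference node* serves as
distance zero for the onset-vs-distance analyses; for the motor neurons
emulated here it sits ~80 µm of arc from the soma, where the axon has
crossed the notochord.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SWCNode", "NeuronMorphology", "ROIAttachment",
    "load_swc", "save_swc", "path_distance",
    "load_attachments", "save_attachments",
]

COMPARTMENTS = ("soma", "axon", "branch_point", "bouton")


@dataclass(frozen=True)
class SWCNode:
    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent: int  # -1 for the root


class MorphologyError(ValueError):
    """Structural problem in an SWC tree (orphan parent, cycle, ...)."""


@dataclass
class NeuronMorphology:
    """A rooted SWC tree with a reference node for distance zero."""

    nodes: list[SWCNode]
    reference_node: int | None = None
    soma_node: int | None = None
    _index: dict[int, SWCNode] = field(init=False, repr=False)
    _root_dist: dict[int, float] = field(init=False, repr=False)
    _depth: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for n in self.nodes:
            if n.id in self._index:
                raise MorphologyError(f"duplicate node id {n.id}")
            if not np.all(np.isfinite([n.x, n.y, n.z])):
                raise MorphologyError(f"non-finite coordinates at node {n.id}")
            if not n.radius > 0:
                raise MorphologyError(f"non-positive radius at node {n.id}")
            self._index[n.id] = n
        roots = [n for n in self.nodes if n.parent == -1]
        if len(roots) != 1:
            raise MorphologyError(f"expected exactly one root, found {len(roots)}")
        for n in self.nodes:
            if n.parent != -1 and n.parent not in self._index:
                raise MorphologyError(f"node {n.id} has unknown parent {n.parent}")
        if self.soma_node is None:
            self.soma_node = roots[0].id
        if self.reference_node is None:
            self.reference_node = self.soma_node
        for nid in (self.reference_node, self.soma_node):
            if nid not in self._index:
                raise MorphologyError(f"designated node {nid} not in tree")
        self._build_paths(roots[0].id)

    def _build_paths(self, root_id: int) -> None:
        # Cumulative arc distance to root plus depth; also detects cycles,
        # since a node on a cycle is never reached from the root.
        children: dict[int, list[int]] = {n.id: [] for n in self.nodes}
        for n in self.nodes:
            if n.parent != -1:
                children[n.parent].append(n.id)
        self._root_dist = {root_id: 0.0}
        self._depth = {root_id: 0}
        stack = [root_id]
        while stack:
            pid = stack.pop()
            p = self._index[pid]
            for cid in children[pid]:
                c = self._index[cid]
                seg = float(np.hypot(np.hypot(c.x - p.x, c.y - p.y), c.z - p.z))
                self._root_dist[cid] = self._root_dist[pid] + seg
                self._depth[cid] = self._depth[pid] + 1
                stack.append(cid)
        if len(self._root_dist) != len(self.nodes):
            raise MorphologyError("parent links contain a cycle or a disconnected part")

    def __contains__(self, node_id: int) -> bool:
        return node_id in self._index

    def node(self, node_id: int) -> SWCNode:
        try:
            return self._index[node_id]
        except KeyError:
            raise KeyError(f"unknown node id {node_id}") from None

    def coords(self, node_id: int) -> np.ndarray:
        n = self.node(node_id)
        return np.array([n.x, n.y, n.z])

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "NeuronMorphology":
        """Rigidly transformed copy (path distances are invariant under this)."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, float)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        nodes = []
        for n in self.nodes:
            x, y, z = R @ np.array([n.x, n.y, n.z]) + t
            nodes.append(SWCNode(n.id, n.type_code, float(x), float(y), float(z),
                                 n.radius, n.parent))
        return NeuronMorphology(nodes, self.reference_node, self.soma_node)


def path_distance(morph: NeuronMorphology, node: int, origin: int) -> float:
    """Arc length (µm) along the unique tree path between two nodes.

    Computed as d(node, root) + d(origin, root) − 2·d(lca, root), where lca
    is the lowest common ancestor. Symmetric, and zero for node == origin.
    """
    for nid in (node, origin):
        if nid not in morph:
            raise KeyError(f"unknown node id {nid}")
    a, b = node, origin
    da, db = morph._depth[a], morph._depth[b]
    while da > db:
        a = morph.node(a).parent
        da -= 1
    while db > da:
        b = morph.node(b).parent
        db -= 1
    while a != b:
        a = morph.node(a).parent
        b = morph.node(b).parent
    lca = a
    return (morph._root_dist[node] + morph._root_dist[origin]
            - 2.0 * morph._root_dist[lca])


# ---------------------------------------------------------------------------
# SWC I/O (standard whitespace-delimited 7-column dialect, '#' comments)

def load_swc(path, reference_node: int | None = None,
             soma_node: int | None = None) -> NeuronMorphology:
    """Read an SWC file and validate tree structure.

    Raises ``ValueError`` with the line number for malformed lines, and
    ``MorphologyError`` for structural defects (orphan parents, cycles).
    """
    nodes: list[SWCNode] = []
    with open(path) as f:
        for lineno, raw in enumerate(f, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(
                    f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                nid, tc = int(parts[0]), int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                parent = int(parts[6])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: {e}") from None
            nodes.append(SWCNode(nid, tc, x, y, z, r, parent))
    if not nodes:
        raise ValueError(f"{path}: no nodes found")
    return NeuronMorphology(nodes, reference_node, soma_node)


def save_swc(morph: NeuronMorphology, path) -> None:
    with open(path, "w") as f:
        f.write("# id type x y z radius parent\n")
        for n in morph.nodes:
            f.write(f"{n.id} {n.type_code} {n.x:.6f} {n.y:.6f} {n.z:.6f} "
                    f"{n.radius:.6f} {n.parent}\n")


# ---------------------------------------------------------------------------
# ROI-to-node attachments (sidecar CSV: roi_id,node_id,compartment)

@dataclass(frozen=True)
class ROIAttachment:
    roi_id: str
    node_id: int
    compartment: str

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"compartment {self.compartment!r} not in {COMPARTMENTS}")


def validate_attachments(attachments: list[ROIAttachment],
                         morph: NeuronMorphology) -> None:
    for a in attachments:
        if a.node_id not in morph:
            raise MorphologyError(
                f"ROI {a.roi_id} attached to unknown node {a.node_id}")


def attachment_distances(attachments: list[ROIAttachment],
                         morph: NeuronMorphology,
                         origin: int | None = None) -> pd.DataFrame:
    """Arc distance (µm) of every attached ROI from ``origin``.

    ``origin`` defaults to the morphology's reference node.
    """
    validate_attachments(attachments, morph)
    origin = morph.reference_node if origin is None else origin
    rows = [{
        "roi_id": a.roi_id,
        "node_id": a.node_id,
        "compartment": a.compartment,
        "distance_um": path_distance(morph, a.node_id, origin),
    } for a in attachments]
    return pd.DataFrame(rows)


def load_attachments(path) -> list[ROIAttachment]:
    df = pd.read_csv(path)
    return [ROIAttachment(str(r.roi_id), int(r.node_id), str(r.compartment))
            for r in df.itertuples()]


def save_attachments(attachments: list[ROIAttachment], path) -> None:
    pd.DataFrame([a.__dict__ for a in attachments]).to_csv(path, index=False)
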