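"""Core data containers: binary networks and region geometry.

A :class:`BinaryNetwork` is a symmetric 0/1 adjacency matrix with labeled
nodes — the genome of the evolutionary engine and the unit of every analysis.
A :class:`RegionGeometry` holds region centroid coordinates in millimetres and
the derived pairwise Euclidean distance matrix used for wiring cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["BinaryNetwork", "RegionGeometry", "default_labels"]


def default_labels(n: int) -> list[str]:
    return [f"r{i:03d}" for i in range(n)]


@dataclass(frozen=True)
class BinaryNetwork:
    """Undirected, unweighted network over labeled nodes.

    Parameters
    ----------
    adjacency
        Symmetric (N, N) matrix of 0/1 entries with a zero diagonal.
    node_labels
        Ordered node labels; defaults to ``r000, r001, ...``.
    """

    adjacency: np.ndarray
    node_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if np.diag(a).any():
            raise ValueError("adjacency diagonal must be zero")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        a = a.astype(np.uint8)
        a.setflags(write=False)
        object.__setattr__(self, "adjacency", a)
        labels = tuple(self.node_labels) or tuple(default_labels(a.shape[0]))
        if len(labels) != a.shape[0]:
            raise ValueError("node_labels length must match adjacency size")
        if len(set(labels)) != len(labels):
            raise ValueError("node_labels must be unique")
        object.__setattr__(self, "node_labels", labels)

    # -- basic properties -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def density(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2)

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    def edges(self) -> np.ndarray:
        """(m, 2) array of upper-triangle edge index pairs, row-major."""
        iu, ju = np.nonzero(np.triu(self.adjacency, 1))
        return np.column_stack([iu, ju])

    # -- genome conversion -------------------------------------------------
    def genome(self) -> np.ndarray:
        """Upper-triangle (row-major) binary vector of length N(N-1)/2."""
        iu = np.triu_indices(self.n_nodes, 1)
        return self.adjacency[iu].astype(np.uint8)

    @classmethod
    def from_genome(
        cls, genome: np.ndarray, n_nodes: int, node_labels: Sequence[str] = ()
    ) -> "BinaryNetwork":
        genome = np.asarray(genome, dtype=np.uint8)
        if genome.size != n_nodes * (n_nodes - 1) // 2:
            raise ValueError("genome length must be N(N-1)/2")
        a = np.zeros((n_nodes, n_nodes), dtype=np.uint8)
        a[np.triu_indices(n_nodes, 1)] = genome
        return cls(a + a.T, tuple(node_labels))

    @classmethod
    def from_edges(
        cls, edges: Sequence[tuple[str, str]], node_labels: Sequence[str]
    ) -> "BinaryNetwork":
        labels = list(node_labels)
        index = {lab: i for i, lab in enumerate(labels)}
        a = np.zeros((len(labels), len(labels)), dtype=np.uint8)
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            a[index[u], index[v]] = 1
            a[index[v], index[u]] = 1
        return cls(a, tuple(labels))

    def induced_subgraph(self, keep: np.ndarray) -> "BinaryNetwork":
        keep = np.asarray(keep)
        labels = tuple(self.node_labels[i] for i in keep)
        return BinaryNetwork(self.adjacency[np.ix_(keep, keep)], labels)

    # -- I/O ---------------------------------------------------------------
    def save(self, path: str | Path, header: bool = False) -> None:
        """Write a whitespace-delimited adjacency matrix text file."""
        path = Path(path)
        with path.open("w") as fh:
            if header:
                fh.write("\t".join(self.node_labels) + "\n")
            for row in self.adjacency:
                fh.write(" ".join(str(int(v)) for v in row) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "BinaryNetwork":
        """Read a whitespace/comma-delimited 0/1 matrix, optional label header."""
        lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
        labels: tuple[str, ...] = ()
        first = lines[0].replace(",", " ").split()
        if not all(tok in ("0", "1") for tok in first):
            labels = tuple(first)
            lines = lines[1:]
        rows = [[int(tok) for tok in ln.replace(",", " ").split()] for ln in lines]
        return cls(np.array(rows, dtype=np.uint8), labels)


@dataclass(frozen=True)
class RegionGeometry:
    """Region centroid coordinates (mm) and pairwise Euclidean distances."""

    coordinates: np.ndarray
    labels: tuple[str, ...] = field(default=())
    distance: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coordinates must be an (N, 3) matrix")
        coords.setflags(write=False)
        object.__setattr__(self, "coordinates", coords)
        labels = tuple(self.labels) or tuple(default_labels(coords.shape[0]))
        if len(labels) != coords.shape[0]:
            raise ValueError("labels length must match coordinates")
        object.__setattr__(self, "labels", labels)
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=-1))
        n = coords.shape[0]
        off = ~np.eye(n, dtype=bool)
        if n > 1 and not (dist[off] > 0).all():
            raise ValueError("region centroids must be pairwise distinct")
        dist.setflags(write=False)
        object.__setattr__(self, "distance", dist)

    @property
    def n_regions(self) -> int:
        return self.coordinates.shape[0]

    def upper_tri_distances(self) -> np.ndarray:
        """Distances in the genome's upper-triangle row-major order."""
        return self.distance[np.triu_indices(self.n_regions, 1)]

    def save(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("label\tx\ty\tz\n")
            for lab, (x, y, z) in zip(self.labels, self.coordinates):
                fh.write(f"{lab}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")

    @classmethod
    def load(cls, path: str | Path) -> "RegionGeometry":
        """Read a tab-delimited (label, x, y, z) table, optional header."""
        labels, rows = [], []
        for ln in Path(path).read_text().splitlines():
            ln = ln.strip()
            if not ln:
                continue
            parts = ln.split("\t") if "\t" in ln else ln.split()
            if parts[0].lower() == "label":
                continue
            labels.append(parts[0])
            rows.append([float(v) for v in parts[1:4]])
        return cls(np.array(rows), tuple(labels))
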