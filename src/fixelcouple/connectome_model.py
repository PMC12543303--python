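"""Domain types and I/O for structure-function connectome coupling.

Connectomes are symmetric weighted adjacency matrices over a fixed atlas
(119 nodes in the reference analysis: 100 cortical parcels in seven
resting-state networks plus 19 subcortical parcels).  Structural
connectivity (SC) comes in four weightings -- average fiber density (FD),
average log fiber-bundle cross-section (logFbC), combined fiber
density-and-cross-section (FDC), each multiplied by the streamline count
of the edge, and a plain streamline count -- while functional connectivity
(FC) is a dense, signed matrix of Fisher-Z transformed BOLD correlations.

Missing structural edges (no streamline support) are carried as an explicit
boolean mask, never as sentinel zeros: a zero SC weight and an absent SC
edge are different things and must not be conflated when averaging.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MODALITIES = ("FD", "logFbC", "FDC", "streamline", "FC")
SC_MODALITIES = ("FD", "logFbC", "FDC", "streamline")
#: SC modalities whose weights must be non-negative where present.
_NONNEG_MODALITIES = ("FD", "FDC", "streamline")

GROUPS = ("CN", "MCI", "AD")

MISSING_TOKEN = "NA"
SYMMETRY_RTOL = 1e-8


class ConnectomeError(ValueError):
    """Raised when a connectome violates its structural contract."""


@dataclass(frozen=True)
class AtlasDefinition:
    """Node labels, network membership and default-mode-network flags.

    Node ids are implicit 0-based positions; files using 1-based ids are
    shifted on read (``index_offset``).
    """

    labels: tuple
    network: tuple
    is_dmn: tuple

    def __post_init__(self):
        n = len(self.labels)
        if not (len(self.network) == len(self.is_dmn) == n):
            raise ConnectomeError("atlas columns have unequal lengths")
        if len(set(self.labels)) != n:
            raise ConnectomeError("atlas labels are not unique")
        n_dmn = sum(bool(d) for d in self.is_dmn)
        if not (0 < n_dmn < n):
            raise ConnectomeError(
                "DMN must be a nonempty strict subset of atlas nodes"
            )

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        n = self.n_nodes
        return n * (n - 1) // 2

    @property
    def dmn_nodes(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.is_dmn, dtype=bool))

    @property
    def networks(self) -> tuple:
        seen = []
        for net in self.network:
            if net not in seen:
                seen.append(net)
        return tuple(seen)

    def nodes_in_network(self, name: str) -> np.ndarray:
        mask = np.asarray([net == name for net in self.network])
        if not mask.any():
            raise KeyError(f"unknown network {name!r}")
        return np.flatnonzero(mask)

    @classmethod
    def from_tsv(cls, path, index_offset: int = 0) -> "AtlasDefinition":
        df = pd.read_csv(path, sep="\t")
        required = {"node_id", "label", "network", "is_dmn"}
        if not required.issubset(df.columns):
            raise ConnectomeError(f"atlas file must have columns {sorted(required)}")
        df = df.sort_values("node_id").reset_index(drop=True)
        ids = df["node_id"].to_numpy() - index_offset
        if not np.array_equal(ids, np.arange(len(df))):
            raise ConnectomeError("node_ids must be contiguous after offset")
        return cls(
            labels=tuple(df["label"].astype(str)),
            network=tuple(df["network"].astype(str)),
            is_dmn=tuple(bool(x) for x in df["is_dmn"]),
        )

    def to_tsv(self, path, index_offset: int = 0) -> None:
        df = pd.DataFrame(
            {
                "node_id": np.arange(self.n_nodes) + index_offset,
                "label": self.labels,
                "network": self.network,
                "is_dmn": [bool(x) for x in self.is_dmn],
            }
        )
        df.to_csv(path, sep="\t", index=False)


@dataclass
class ConnectomeMatrix:
    """Symmetric weighted adjacency with an explicit edge-presence mask.

    ``weights[i, j]`` is only meaningful where ``present[i, j]``; absent
    cells hold NaN.  The diagonal is always absent (self-connections are
    excluded from every analysis).
    """

    modality: str
    weights: np.ndarray
    present: np.ndarray

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ConnectomeError(f"unknown modality {self.modality!r}")
        w = np.asarray(self.weights, dtype=float)
        m = np.asarray(self.present, dtype=bool)
        if w.ndim != 2 or w.shape[0] != w.shape[1] or w.shape != m.shape:
            raise ConnectomeError("weights/present must be square and congruent")
        m = m.copy()
        np.fill_diagonal(m, False)
        if not np.array_equal(m, m.T):
            raise ConnectomeError("presence mask is not symmetric")
        w = np.where(m, w, np.nan)
        on = w[m]
        if not np.all(np.isfinite(on)):
            raise ConnectomeError("present weights must be finite")
        if not np.allclose(w[m], w.T[m], rtol=SYMMETRY_RTOL, atol=0.0):
            raise ConnectomeError("weights are asymmetric beyond tolerance")
        if self.modality == "FC":
            expected = ~np.eye(w.shape[0], dtype=bool)
            if not np.array_equal(m, expected):
                raise ConnectomeError("FC must be present on all off-diagonal cells")
        elif self.modality in _NONNEG_MODALITIES and on.size and on.min() < 0:
            raise ConnectomeError(
                f"{self.modality} weights must be non-negative where present"
            )
        self.weights = w
        self.present = m

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def __eq__(self, other) -> bool:
        if not isinstance(other, ConnectomeMatrix):
            return NotImplemented
        return (
            self.modality == other.modality
            and np.array_equal(self.present, other.present)
            and np.array_equal(
                self.weights[self.present], other.weights[other.present]
            )
        )


@dataclass
class EdgeVector:
    """Upper-triangle (i<j, row-major) flattening of a ConnectomeMatrix."""

    modality: str
    values: np.ndarray
    present: np.ndarray
    n_nodes: int

    @property
    def index_map(self):
        """(row_indices, col_indices) with i<j, aligned with ``values``."""
        return np.triu_indices(self.n_nodes, k=1)


@dataclass
class SubjectRecord:
    """One participant: diagnosis group, covariates, cognition, connectomes."""

    subject_id: str
    group: str
    age: float
    sex: str
    icv: float
    mmse: float | None = None
    ravlt: Mapping[str, float] | None = None
    matrices: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ConnectomeError(f"unknown group {self.group!r}")
        if self.sex not in ("M", "F"):
            raise ConnectomeError(f"sex must be 'M' or 'F', got {self.sex!r}")
        dims = {m.n_nodes for m in self.matrices.values()}
        if len(dims) > 1:
            raise ConnectomeError("subject matrices have inconsistent dimensions")


RAVLT_SCORES = ("learning", "immediate", "delay30", "recognition")


def vectorize(m: ConnectomeMatrix) -> EdgeVector:
    """Flatten the strict upper triangle, row-major, into an edge vector.

    For an N-node atlas the vector has N(N-1)/2 entries; edge k maps to the
    k-th (i, j) pair with i<j in row-major order.
    """
    iu, ju = np.triu_indices(m.n_nodes, k=1)
    return EdgeVector(
        modality=m.modality,
        values=m.weights[iu, ju],
        present=m.present[iu, ju],
        n_nodes=m.n_nodes,
    )


def devectorize(v: EdgeVector) -> ConnectomeMatrix:
    n = v.n_nodes
    w = np.full((n, n), np.nan)
    p = np.zeros((n, n), dtype=bool)
    iu, ju = np.triu_indices(n, k=1)
    w[iu, ju] = v.values
    w[ju, iu] = v.values
    p[iu, ju] = v.present
    p[ju, iu] = v.present
    return ConnectomeMatrix(modality=v.modality, weights=w, present=p)


def fixel_edge_weight(fixel_values, n_streamlines: int) -> float:
    """Edge weight from per-fixel metric values along one connection.

    The weight is the mean of the *nonzero* fixel values multiplied by the
    number of streamlines assigned to the edge, so that two edges with the
    same average fixel metric but different streamline support are weighted
    differently.  If every fixel value is zero the edge has no usable fixel
    support and the weight is NaN (edge missing).
    """
    if n_streamlines < 1:
        raise ValueError("n_streamlines must be >= 1")
    values = np.asarray(fixel_values, dtype=float)
    nonzero = values[values != 0.0]
    if nonzero.size == 0:
        return float("nan")
    return float(nonzero.mean() * n_streamlines)


def read_connectome(path, modality: str, atlas: AtlasDefinition) -> ConnectomeMatrix:
    """Read a square TSV connectome (node labels as header row/column).

    Missing edges are marked with the token ``NA``.  The file must be
    symmetric: upper/lower weight disagreement beyond 1e-8 relative, or an
    asymmetric missingness pattern, is an error rather than silently fixed.
    """
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=[MISSING_TOKEN],
        keep_default_na=False, float_precision="round_trip",
    )
    n = atlas.n_nodes
    if df.shape != (n, n):
        raise ConnectomeError(
            f"connectome is {df.shape}, atlas expects ({n}, {n})"
        )
    if list(df.index.astype(str)) != list(atlas.labels) or list(
        df.columns.astype(str)
    ) != list(atlas.labels):
        raise ConnectomeError("connectome node labels do not match atlas")
    w = df.to_numpy(dtype=float)
    p = ~np.isnan(w)
    np.fill_diagonal(p, False)
    if not np.array_equal(p, p.T):
        raise ConnectomeError("missing-edge pattern is not symmetric")
    both = p & p.T
    if not np.allclose(w[both], w.T[both], rtol=SYMMETRY_RTOL, atol=0.0):
        raise ConnectomeError("upper and lower triangles disagree beyond tolerance")
    if modality == "streamline":
        on = w[p]
        if on.size and on.min() < 0:
            raise ConnectomeError("negative streamline counts")
    # exact symmetrization (triangles already agree within tolerance)
    iu, ju = np.triu_indices(n, k=1)
    w[ju, iu] = w[iu, ju]
    return ConnectomeMatrix(modality=modality, weights=w, present=p)


def write_connectome(m: ConnectomeMatrix, path, labels=None) -> None:
    """Write a connectome as TSV with ``NA`` for absent edges.

    Weights are serialized with repr-level precision so that
    ``read_connectome(write_connectome(m))`` reproduces weights and mask
    exactly.  ``labels`` defaults to generic node names; pass the atlas
    labels to make the file self-describing.
    """
    path = Path(path)
    cells = np.where(m.present, m.weights, np.nan)
    if labels is None:
        labels = [f"n{i}" for i in range(m.n_nodes)]
    elif len(labels) != m.n_nodes:
        raise ConnectomeError("label count does not match matrix dimension")
    df = pd.DataFrame(cells, index=labels, columns=labels)
    df.to_csv(path, sep="\t", na_rep=MISSING_TOKEN, float_format="%.17g")


def read_manifest(path) -> pd.DataFrame:
    """Read a subject manifest TSV (one row per subject, covariates + paths)."""
    return pd.read_csv(
        path, sep="\t", na_values=[MISSING_TOKEN, ""], keep_default_na=False
    )


def load_subject(
    row: Mapping, atlas: AtlasDefinition, base_dir=None
) -> SubjectRecord:
    """Build a SubjectRecord from one manifest row, loading its matrices."""
    base = Path(base_dir) if base_dir is not None else Path(".")
    matrices = {}
    for modality in MODALITIES:
        key = f"path_{modality}"
        if key in row and isinstance(row[key], str) and row[key]:
            matrices[modality] = read_connectome(base / row[key], modality, atlas)
    ravlt = {}
    for score in RAVLT_SCORES:
        val = row.get(f"ravlt_{score}")
        if val is not None and not pd.isna(val):
            ravlt[score] = float(val)
    mmse = row.get("mmse")
    return SubjectRecord(
        subject_id=str(row["subject_id"]),
        group=str(row["group"]),
        age=float(row["age"]),
        sex=str(row["sex"]),
        icv=float(row["icv"]),
        mmse=None if mmse is None or pd.isna(mmse) else float(mmse),
        ravlt=ravlt or None,
        matrices=matrices,
    )
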