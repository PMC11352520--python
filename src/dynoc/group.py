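"""Group-level dynamic network by representative-edge selection.

For every edge (i, j) each subject contributes a cross-time feature vector
(the edge's T connectivity values).  The subject whose vector minimizes the
summed Euclidean distance to all subjects' vectors is the representative,
and its full time course is copied into the group tensor.  No averaging or
interpolation: every group edge is one subject's measured trajectory, and a
provenance table records whose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, StructuralError

__all__ = [
    "GroupTensorSet",
    "GroupDynamicNetwork",
    "representative_index",
    "build_group_network",
]


@dataclass
class GroupTensorSet:
    """S per-subject (N, N, T) connectivity stacks, stored as (S, N, N, T)."""

    tensors: np.ndarray
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        W = np.asarray(self.tensors, dtype=float)
        if W.ndim == 3:
            W = W[None]
        if W.ndim != 4 or W.shape[1] != W.shape[2]:
            raise StructuralError("tensors must have shape (S, N, N, T)")
        if not self.subject_ids:
            self.subject_ids = [f"sub{s + 1:03d}" for s in range(W.shape[0])]
        if len(self.subject_ids) != W.shape[0]:
            raise StructuralError(
                f"{len(self.subject_ids)} subject ids for {W.shape[0]} tensors"
            )
        for s in range(W.shape[0]):
            if not np.allclose(W[s], W[s].transpose(1, 0, 2), atol=1e-8):
                raise StructuralError(
                    f"subject {self.subject_ids[s]}: asymmetric connectivity slice"
                )
        self.tensors = W

    @property
    def n_subjects(self) -> int:
        return self.tensors.shape[0]

    @property
    def n_regions(self) -> int:
        return self.tensors.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.tensors.shape[3]


@dataclass
class GroupDynamicNetwork:
    """Group tensor F (N, N, T) plus an (N, N) table of selected subjects."""

    F: np.ndarray
    provenance: np.ndarray | None = None
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        F = np.asarray(self.F, dtype=float)
        if F.ndim != 3 or F.shape[0] != F.shape[1]:
            raise StructuralError("group tensor must have shape (N, N, T)")
        if self.provenance is None:
            self.provenance = np.zeros(F.shape[:2], dtype=int)
        else:
            self.provenance = np.asarray(self.provenance, dtype=int)
            if self.provenance.shape != F.shape[:2]:
                raise StructuralError("provenance table must be N x N")
        if not self.region_labels:
            self.region_labels = [f"R{j + 1:03d}" for j in range(F.shape[0])]
        self.F = F

    @property
    def n_regions(self) -> int:
        return self.F.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.F.shape[2]


def representative_index(vectors: np.ndarray) -> int:
    """Index of the vector closest to all others in summed Euclidean distance.

    Ties are broken by the lowest index.  The sum includes the zero
    self-distance, which cannot affect the argmin.
    """
    V = np.atleast_2d(np.asarray(vectors, dtype=float))
    if V.size == 0:
        raise ParameterError("no vectors given")
    sq = np.sum(V * V, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (V @ V.T)
    dist = np.sqrt(np.maximum(d2, 0.0))
    return int(np.argmin(dist.sum(axis=1)))


def build_group_network(W: GroupTensorSet) -> GroupDynamicNetwork:
    """Select, per edge, the representative subject's time course.

    Each unordered pair is processed once and mirrored; the diagonal stays at
    its (zero) input value with self-provenance 0.
    """
    tensors = W.tensors
    S, N, _, T = tensors.shape

    iu, ju = np.triu_indices(N, k=1)
    X = tensors[:, iu, ju, :]            # (S, E, T) edge feature vectors
    sq = np.einsum("set,set->se", X, X)  # (S, E)
    cross = np.einsum("set,uet->sue", X, X)
    d2 = sq[:, None, :] + sq[None, :, :] - 2.0 * cross
    dist = np.sqrt(np.maximum(d2, 0.0))  # (S, S, E)
    winners = np.argmin(dist.sum(axis=1), axis=0)  # (E,) lowest index on ties

    F = np.zeros((N, N, T))
    provenance = np.zeros((N, N), dtype=int)
    F[iu, ju, :] = X[winners, np.arange(iu.size), :]
    F[ju, iu, :] = F[iu, ju, :]
    provenance[iu, ju] = winners
    provenance[ju, iu] = winners
    return GroupDynamicNetwork(F=F, provenance=provenance)
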