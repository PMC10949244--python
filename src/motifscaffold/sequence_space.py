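"""Sequence-space bookkeeping for iterative design campaigns.

A hallucination batch yields tens to hundreds of fixed-length sequences.
They are clustered by pairwise identity (greedy centroid clustering, which
is deterministic and order-stable), the best cluster — lowest mean loss —
seeds the next round, and the cluster alignment is condensed into
per-position consensus constraints restricting the mutation alphabet of the
next MCMC iteration.  One-hot PCA embeds sequence sets in 2D for campaign
maps of the explored sequence space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hallucination import AMINO_ACIDS

__all__ = [
    "Cluster",
    "ClusterSet",
    "ConsensusConstraint",
    "EmbeddingCoords",
    "pairwise_identity",
    "cluster_by_identity",
    "select_best_cluster",
    "consensus_constraints",
    "onehot_pca",
]


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical positions between two equal-length sequences."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("empty sequences")
    return sum(x == y for x, y in zip(a, b)) / len(a)


@dataclass
class Cluster:
    centroid: str
    members: list[int]  # indices into the input sequence list


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    threshold: float
    sequences: list[str]

    def membership(self) -> pd.DataFrame:
        rows = [
            {
                "sequence_id": m,
                "cluster_id": ci,
                "identity_to_centroid": pairwise_identity(self.sequences[m], c.centroid),
            }
            for ci, c in enumerate(self.clusters)
            for m in c.members
        ]
        return pd.DataFrame(rows, columns=["sequence_id", "cluster_id", "identity_to_centroid"])


def cluster_by_identity(sequences: list[str], threshold: float = 0.6) -> ClusterSet:
    """Greedy centroid clustering in input order.

    Each sequence joins the first existing cluster whose centroid it matches
    at >= threshold identity, else founds a new cluster with itself as
    centroid.  Deterministic and a partition of the input.
    """
    if not sequences:
        raise ValueError("no sequences to cluster")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    clusters: list[Cluster] = []
    for i, seq in enumerate(sequences):
        for cluster in clusters:
            if pairwise_identity(seq, cluster.centroid) >= threshold:
                cluster.members.append(i)
                break
        else:
            clusters.append(Cluster(centroid=seq, members=[i]))
    return ClusterSet(clusters=clusters, threshold=threshold, sequences=list(sequences))


def select_best_cluster(clusters: ClusterSet, scores: dict[int, float]) -> int:
    """Index of the cluster with the lowest mean loss.

    Ties break toward the larger cluster, then the lower cluster id.
    """
    keys = []
    for ci, cluster in enumerate(clusters.clusters):
        missing = [m for m in cluster.members if m not in scores]
        if missing:
            raise KeyError(f"missing score for sequence id {missing[0]}")
        mean_loss = float(np.mean([scores[m] for m in cluster.members]))
        keys.append((mean_loss, -len(cluster.members), ci))
    return min(keys)[2]


@dataclass
class ConsensusConstraint:
    """Per-position allowed residue sets derived from a cluster alignment."""

    allowed: list[frozenset[str]]
    min_freq: float

    def as_alphabet(self) -> dict[int, str]:
        """Alphabet map consumable by MCMCConfig (sorted for determinism)."""
        return {i: "".join(sorted(s)) for i, s in enumerate(self.allowed)}


def consensus_constraints(members: list[str], min_freq: float = 0.5) -> ConsensusConstraint:
    """Allowed residues per position: those at frequency >= min_freq.

    If no residue reaches min_freq at a position, fall back to all residues
    observed there, so the allowed set is never empty.
    """
    if not members:
        raise ValueError("no member sequences")
    lengths = {len(s) for s in members}
    if len(lengths) != 1:
        raise ValueError("member sequences must be aligned (equal length)")
    n = len(members)
    allowed: list[frozenset[str]] = []
    for col in zip(*members):
        counts: dict[str, int] = {}
        for aa in col:
            counts[aa] = counts.get(aa, 0) + 1
        frequent = {aa for aa, c in counts.items() if c / n >= min_freq}
        allowed.append(frozenset(frequent if frequent else counts))
    return ConsensusConstraint(allowed=allowed, min_freq=min_freq)


@dataclass
class EmbeddingCoords:
    coords: np.ndarray  # (n, 2): PC1, PC2 per sequence
    explained_variance: np.ndarray  # fractions, descending

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sequence_id": np.arange(len(self.coords)), "PC1": self.coords[:, 0], "PC2": self.coords[:, 1]}
        )


def _onehot(sequences: list[str]) -> np.ndarray:
    index = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
    n, L = len(sequences), len(sequences[0])
    X = np.zeros((n, L * len(AMINO_ACIDS)))
    for i, seq in enumerate(sequences):
        for j, aa in enumerate(seq):
            if aa in index:
                X[i, j * len(AMINO_ACIDS) + index[aa]] = 1.0
    return X


def onehot_pca(sequences: list[str]) -> EmbeddingCoords:
    """2D PCA of one-hot encoded sequences (no per-column scaling).

    Mean-centred SVD projection onto the top two right-singular directions.
    Sign fixed so each PC's largest-magnitude loading is positive, making
    the embedding independent of input order up to the sequence permutation.
    All-identical input gives all-zero coordinates (not an error).
    """
    if len(sequences) < 3:
        raise ValueError("need at least 3 sequences")
    if len({len(s) for s in sequences}) != 1:
        raise ValueError("sequences must have equal length")
    X = _onehot(sequences)
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        return EmbeddingCoords(coords=np.zeros((len(sequences), 2)), explained_variance=np.zeros(2))
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    for k in range(min(2, len(s))):
        # sign fix: the largest-magnitude loading is made positive; near-ties
        # (within 1e-6 of the maximum) break to the lowest column index so
        # the choice is stable under row permutation and FP noise
        mags = np.abs(Vt[k])
        lead = int(np.flatnonzero(mags >= mags.max() - 1e-6)[0])
        if Vt[k, lead] < 0:
            Vt[k] = -Vt[k]
            U[:, k] = -U[:, k]
    coords = np.zeros((len(sequences), 2))
    var = np.zeros(2)
    total_var = float(np.sum(s**2))
    for k in range(min(2, len(s))):
        coords[:, k] = U[:, k] * s[k]
        var[k] = s[k] ** 2 / total_var if total_var > 0 else 0.0
    return EmbeddingCoords(coords=coords, explained_variance=var)
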