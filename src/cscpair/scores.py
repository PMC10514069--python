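"""Definitional scores for cell sub-crosstalk pairs.

A sub-crosstalk pair couples a sender cell subgroup C_k^L with a receiver
cell subgroup C_k^R. Two scores define a good pairing:

* ``expr_differ_score`` — within-subgroup expression dispersion: the sum of
  squared deviations of member cells from the subgroup mean cell (over the
  subgroup's gene set) plus squared deviations of the subgroup's genes from
  the mean gene (over member cells). Low values mean the subgroup's cells
  express similar ligand (or receptor) genes.
* ``commun_score`` — the bilinear form sum_{gL, gR} w_{gL,k} a_{gL,gR}
  w_{gR,k}: total weight of activated ligand-receptor pairs between the two
  subgroups. Its column-sum over k equals tr((W^L)^T A W^R), which is how
  the coupled NMF rewards crosstalk.

The partition-level objective sum_k (ExprDiffer^L_k + ExprDiffer^R_k -
Commun_k) is not used as the optimizer (the coupled NMF is); it is the
small-instance diagnostic the factorization is checked against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Partition",
    "SubgroupGeneSets",
    "expr_differ_score",
    "commun_score",
    "total_definition_objective",
    "gene_sets_from_factor",
]


@dataclass
class Partition:
    """Hard subgroup labels for both sides of one sender -> receiver pair."""

    sender_labels: np.ndarray
    receiver_labels: np.ndarray
    K: int

    def __post_init__(self) -> None:
        self.sender_labels = np.asarray(self.sender_labels, dtype=int)
        self.receiver_labels = np.asarray(self.receiver_labels, dtype=int)
        for name, lab in (("sender", self.sender_labels), ("receiver", self.receiver_labels)):
            if lab.size and (lab.min() < 0 or lab.max() >= self.K):
                raise ValueError(f"{name} labels outside 0..{self.K - 1}")

    @property
    def joint_labels(self) -> np.ndarray:
        return np.concatenate([self.sender_labels, self.receiver_labels])

    def empty_subgroups(self) -> list[int]:
        present = set(self.sender_labels) | set(self.receiver_labels)
        return [k for k in range(self.K) if k not in present]


@dataclass
class SubgroupGeneSets:
    """Per-subgroup gene index sets with non-negative per-gene weights.

    ``sets[k]`` holds row indices into the side's expression matrix and
    ``weights[k]`` the aligned weights w_{g,k} (factor loadings by default,
    or subgroup mean expression for the partition-level variant).
    """

    sets: dict[int, np.ndarray] = field(default_factory=dict)
    weights: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k in self.sets:
            self.sets[k] = np.asarray(self.sets[k], dtype=int)
            w = np.asarray(self.weights.get(k, np.ones(len(self.sets[k]))), dtype=float)
            if w.shape != self.sets[k].shape:
                raise ValueError(f"weights misaligned with gene set for subgroup {k}")
            if w.size and w.min() < 0:
                raise ValueError("gene weights must be non-negative")
            self.weights[k] = w


def gene_sets_from_factor(W: np.ndarray) -> SubgroupGeneSets:
    """Assign gene g to subgroup k = argmax_k W[g, k] (ties to smallest k),
    requiring W[g, k] > 0; weights are the factor entries."""
    W = np.asarray(W, dtype=float)
    K = W.shape[1]
    best = np.argmax(W, axis=1)
    sets: dict[int, np.ndarray] = {}
    weights: dict[int, np.ndarray] = {}
    for k in range(K):
        rows = np.where((best == k) & (W[:, k] > 0))[0]
        sets[k] = rows
        weights[k] = W[rows, k]
    return SubgroupGeneSets(sets=sets, weights=weights)


def gene_sets_from_partition(X: np.ndarray, labels: np.ndarray, K: int) -> SubgroupGeneSets:
    """Partition-level variant: a subgroup's genes are those with nonzero
    mean expression in its member cells; weights are those means."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=int)
    sets, weights = {}, {}
    for k in range(K):
        cols = labels == k
        if not cols.any():
            sets[k] = np.array([], dtype=int)
            weights[k] = np.array([])
            continue
        means = X[:, cols].mean(axis=1)
        rows = np.where(means > 0)[0]
        sets[k] = rows
        weights[k] = means[rows]
    return SubgroupGeneSets(sets=sets, weights=weights)


def expr_differ_score(
    X: np.ndarray, labels: np.ndarray, gene_sets: SubgroupGeneSets, K: int
) -> np.ndarray:
    """Per-subgroup expression-difference score for one side.

    For subgroup k with member-cell columns C and gene-set rows G:

        sum_{c in C} ||x_c - m_C||^2 + sum_{g in G} ||y_g - m_G||^2

    where x_c is restricted to rows G, y_g to columns C, and m_C / m_G are
    the corresponding mean cell / mean gene vectors. Empty subgroups score 0.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=int)
    out = np.zeros(K)
    for k in range(K):
        cols = np.where(labels == k)[0]
        rows = gene_sets.sets.get(k, np.array([], dtype=int))
        if cols.size == 0 or rows.size == 0:
            continue
        sub = X[np.ix_(rows, cols)]
        cell_term = float(((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum())
        gene_term = float(((sub - sub.mean(axis=0, keepdims=True)) ** 2).sum())
        out[k] = cell_term + gene_term
    return out


def commun_score(
    weights_L: np.ndarray, weights_R: np.ndarray, A: np.ndarray
) -> float:
    """Bilinear communication score w_L^T A w_R for one subgroup pair.

    ``weights_L`` / ``weights_R`` are dense weight vectors aligned to A's
    rows / columns (zero outside the subgroup's gene set). When the weights
    are the k-th factor columns this equals the k-th diagonal entry of
    (W^L)^T A W^R.
    """
    wl = np.asarray(weights_L, dtype=float)
    wr = np.asarray(weights_R, dtype=float)
    A = np.asarray(A, dtype=float)
    if A.shape != (wl.size, wr.size):
        raise ValueError(f"A shape {A.shape} != ({wl.size}, {wr.size})")
    return float(wl @ A @ wr)


def _dense_weights(n: int, gs: SubgroupGeneSets, k: int) -> np.ndarray:
    w = np.zeros(n)
    rows = gs.sets.get(k, np.array([], dtype=int))
    if rows.size:
        w[rows] = gs.weights[k]
    return w


def total_definition_objective(
    inputs, partition: Partition,
    ligand_sets: SubgroupGeneSets | None = None,
    receptor_sets: SubgroupGeneSets | None = None,
) -> float:
    """sum_k [ExprDiffer(C_k^L) + ExprDiffer(C_k^R) - Commun(C_k^L, C_k^R)].

    ``inputs`` is a CoupledInputs (or (XL, XR, A) arrays). When gene sets
    are not supplied they are derived from the partition (expressed genes
    per subgroup, mean-expression weights), making this a pure
    partition-level diagnostic comparable across candidate partitions.
    """
    from .nmf import _arrays  # local import to avoid a cycle

    XL, XR, A = _arrays(inputs)
    K = partition.K
    if ligand_sets is None:
        ligand_sets = gene_sets_from_partition(XL, partition.sender_labels, K)
    if receptor_sets is None:
        receptor_sets = gene_sets_from_partition(XR, partition.receiver_labels, K)
    ed_l = expr_differ_score(XL, partition.sender_labels, ligand_sets, K)
    ed_r = expr_differ_score(XR, partition.receiver_labels, receptor_sets, K)
    total = 0.0
    for k in range(K):
        cs = commun_score(
            _dense_weights(XL.shape[0], ligand_sets, k),
            _dense_weights(XR.shape[0], receptor_sets, k),
            A,
        )
        total += ed_l[k] + ed_r[k] - cs
    return float(total)
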