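"""Coupled consensus clustering over repeated coupled-NMF runs.

A single coupled-NMF solve depends on its random initialization. To
stabilize the sub-crosstalk pairs, the factorization is run T times with
different seeds; each run's hard partition becomes a binary coupled
connectivity matrix over the joint cell index (senders first, then
receivers), the T matrices are averaged into a consensus matrix, and
agglomerative (Ward) clustering of the consensus rows yields the final K
joint clusters. Clusters containing both sender and receiver cells are the
reported sub-crosstalk pairs; one-sided clusters are listed as unpaired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import adjusted_rand_score

from .errors import NoCSCPError
from .io import CoupledInputs
from .nmf import CoupledNMF, assign_subgroups
from .scores import (
    Partition,
    commun_score,
    expr_differ_score,
    gene_sets_from_factor,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectivityMatrix",
    "ConsensusMatrix",
    "CSCP",
    "CSCPResult",
    "CSCPFinder",
    "connectivity_matrix",
    "consensus_matrix",
    "cluster_consensus",
    "identify_cscps",
]


@dataclass
class ConnectivityMatrix:
    """Binary symmetric co-membership matrix over the joint cell index."""

    matrix: np.ndarray
    run_index: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("connectivity matrix must be symmetric")
        vals = np.unique(self.matrix)
        if not np.all(np.isin(vals, [0.0, 1.0])):
            raise ValueError("connectivity entries must be 0 or 1")
        if not np.all(np.diag(self.matrix) == 1.0):
            raise ValueError("connectivity diagonal must be 1")


@dataclass
class ConsensusMatrix:
    """Mean of T connectivity matrices; entry (i, j) is the co-clustering
    frequency of joint cells i and j across runs."""

    matrix: np.ndarray
    T: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.min() < 0 or self.matrix.max() > 1:
            raise ValueError("consensus entries must lie in [0, 1]")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("consensus matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 1.0):
            raise ValueError("consensus diagonal must be 1")


@dataclass
class CSCP:
    """One identified cell sub-crosstalk pair."""

    index: int
    sender_cells: list[str]
    receiver_cells: list[str]
    ligand_genes: list[str]
    receptor_genes: list[str]
    commun_score: float
    expr_differ_sender: float
    expr_differ_receiver: float


@dataclass
class CSCPResult:
    """Final output of the consensus pipeline."""

    cscps: list[CSCP]
    unpaired: list[dict]
    sender_labels: np.ndarray
    receiver_labels: np.ndarray
    joint_labels: np.ndarray
    consensus: ConsensusMatrix
    provenance: dict = field(default_factory=dict)


def connectivity_matrix(partition: Partition, run_index: int = 0) -> ConnectivityMatrix:
    """p_ij = 1 iff joint cells i and j carry the same subgroup index k
    (a sender in subgroup k co-clusters with a receiver in subgroup k)."""
    joint = partition.joint_labels
    P = (joint[:, None] == joint[None, :]).astype(float)
    return ConnectivityMatrix(matrix=P, run_index=run_index)


def consensus_matrix(runs: list[ConnectivityMatrix]) -> ConsensusMatrix:
    """Elementwise mean of the run connectivity matrices."""
    if not runs:
        raise ValueError("at least one connectivity matrix is required")
    shapes = {r.matrix.shape for r in runs}
    if len(shapes) != 1:
        raise ValueError(f"connectivity matrices disagree in shape: {shapes}")
    stack = np.stack([r.matrix for r in runs])
    return ConsensusMatrix(matrix=stack.mean(axis=0), T=len(runs))


def cluster_consensus(c: ConsensusMatrix, K: int) -> np.ndarray:
    """Ward agglomerative clustering of the consensus rows into K clusters."""
    n = c.matrix.shape[0]
    if K > n:
        raise ValueError(f"K={K} exceeds the number of joint cells {n}")
    model = AgglomerativeClustering(n_clusters=K, linkage="ward")
    return model.fit_predict(c.matrix)


def _match_clusters(labels_a: np.ndarray, labels_b: np.ndarray, K: int) -> dict[int, int]:
    """Best one-to-one map cluster(a) -> cluster(b) by overlap (Hungarian)."""
    M = np.zeros((K, K))
    for a, b in zip(labels_a, labels_b):
        if 0 <= a < K and 0 <= b < K:
            M[a, b] += 1
    rows, cols = linear_sum_assignment(-M)
    return dict(zip(rows, cols))


class CSCPFinder(ClusterMixin, BaseEstimator):
    """Identify cell sub-crosstalk pairs by consensus over coupled-NMF runs.

    Parameters
    ----------
    n_components : int, default=2
        Number of sub-crosstalk pairs K.
    n_runs : int, default=20
        Number T of coupled-NMF runs entering the consensus; run t is
        seeded ``random_state + t``.
    random_state : int, default=0
    multipliers, warmup_iters, max_iter, tol, eps :
        Forwarded to :class:`~cscpair.nmf.CoupledNMF`.

    Attributes
    ----------
    labels_ : joint cluster labels (senders then receivers)
    sender_labels_, receiver_labels_ : per-side labels
    consensus_matrix_ : ConsensusMatrix
    result_ : CSCPResult with per-pair cells, gene sets and scores
    """

    def __init__(self, n_components: int = 2, n_runs: int = 20,
                 random_state: int = 0,
                 multipliers: tuple[float, float, float] = (1.0, 1000.0, 1.0),
                 warmup_iters: int = 50, max_iter: int = 500,
                 tol: float = 1e-4, eps: float = 1e-10):
        self.n_components = n_components
        self.n_runs = n_runs
        self.random_state = random_state
        self.multipliers = multipliers
        self.warmup_iters = warmup_iters
        self.max_iter = max_iter
        self.tol = tol
        self.eps = eps

    def fit(self, X: CoupledInputs, y=None) -> "CSCPFinder":
        if not isinstance(X, CoupledInputs):
            raise TypeError("CSCPFinder.fit expects CoupledInputs")
        K, T = self.n_components, self.n_runs
        if T < 1:
            raise ValueError("n_runs must be >= 1")
        n_l, n_r = X.n_senders, X.n_receivers

        runs = []
        for t in range(T):
            est = CoupledNMF(
                n_components=K, multipliers=self.multipliers,
                warmup_iters=self.warmup_iters, max_iter=self.max_iter,
                tol=self.tol, random_state=self.random_state + t, eps=self.eps,
            ).fit(X)
            part = Partition(est.sender_labels_, est.receiver_labels_, K)
            runs.append((est, part, connectivity_matrix(part, run_index=t)))

        cons = consensus_matrix([p for _, _, p in runs])
        joint = cluster_consensus(cons, K)
        sender_labels = joint[:n_l]
        receiver_labels = joint[n_l:]

        # report gene sets from the run closest to the consensus partition
        aris = [adjusted_rand_score(joint, p.joint_labels) for _, p, _ in runs]
        best = int(np.argmax(aris))
        best_est, best_part, _ = runs[best]
        run_to_cons = _match_clusters(best_part.joint_labels, joint, K)
        cons_to_run = {v: k for k, v in run_to_cons.items()}

        lig_sets = gene_sets_from_factor(best_est.WL_)
        rec_sets = gene_sets_from_factor(best_est.WR_)
        ed_l = expr_differ_score(X.XL.values, sender_labels,
                                 _remap_sets(lig_sets, cons_to_run), K)
        ed_r = expr_differ_score(X.XR.values, receiver_labels,
                                 _remap_sets(rec_sets, cons_to_run), K)

        cscps: list[CSCP] = []
        unpaired: list[dict] = []
        for c in range(K):
            s_cells = [X.XL.cell_ids[i] for i in np.where(sender_labels == c)[0]]
            r_cells = [X.XR.cell_ids[i] for i in np.where(receiver_labels == c)[0]]
            k_run = cons_to_run.get(c)
            lg = [X.XL.gene_ids[i] for i in lig_sets.sets.get(k_run, [])] \
                if k_run is not None else []
            rg = [X.XR.gene_ids[i] for i in rec_sets.sets.get(k_run, [])] \
                if k_run is not None else []
            if k_run is not None:
                wl = np.zeros(X.XL.n_genes)
                wl[lig_sets.sets[k_run]] = lig_sets.weights[k_run]
                wr = np.zeros(X.XR.n_genes)
                wr[rec_sets.sets[k_run]] = rec_sets.weights[k_run]
                cs = commun_score(wl, wr, X.A)
            else:
                cs = 0.0
            entry = CSCP(
                index=c, sender_cells=s_cells, receiver_cells=r_cells,
                ligand_genes=lg, receptor_genes=rg, commun_score=cs,
                expr_differ_sender=float(ed_l[c]), expr_differ_receiver=float(ed_r[c]),
            )
            if s_cells and r_cells:
                cscps.append(entry)
            else:
                unpaired.append({
                    "index": c,
                    "side": "sender" if s_cells else "receiver",
                    "cells": s_cells or r_cells,
                })
        if not cscps:
            raise NoCSCPError(
                "no CSCP pairable: every consensus cluster is one-sided"
            )

        self.result_ = CSCPResult(
            cscps=cscps, unpaired=unpaired,
            sender_labels=sender_labels, receiver_labels=receiver_labels,
            joint_labels=joint, consensus=cons,
            provenance={
                "T": T, "K": K,
                "seeds": [self.random_state + t for t in range(T)],
                "best_run": best, "run_aris": aris,
                "params": {"multipliers": list(self.multipliers),
                           "warmup_iters": self.warmup_iters,
                           "max_iter": self.max_iter, "tol": self.tol},
                "final_objectives": [r[0].trace_.total[-1] for r in runs],
            },
        )
        self.consensus_matrix_ = cons
        self.sender_labels_ = sender_labels
        self.receiver_labels_ = receiver_labels
        self.labels_ = joint
        return self


def _remap_sets(gs, cons_to_run: dict[int, int]):
    """Re-index factor gene sets by consensus cluster instead of run subgroup."""
    from .scores import SubgroupGeneSets

    sets, weights = {}, {}
    for c, k in cons_to_run.items():
        if k in gs.sets:
            sets[c] = gs.sets[k]
            weights[c] = gs.weights[k]
    return SubgroupGeneSets(sets=sets, weights=weights)


def identify_cscps(
    inputs: CoupledInputs, K: int = 2, T: int = 20, base_seed: int = 0,
    **nmf_kwargs,
) -> CSCPResult:
    """Functional wrapper over :class:`CSCPFinder`."""
    est = CSCPFinder(n_components=K, n_runs=T, random_state=base_seed,
                     **nmf_kwargs).fit(inputs)
    return est.result_
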