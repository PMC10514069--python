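"""Validation procedures: spatial co-location, masked-sampling
reproducibility with a permutation ligand-receptor caller, and the
patient-response prediction pipeline, plus the shared statistics.

The three procedures mirror how sub-crosstalk pairs are validated in
practice: (1) paired sender/receiver subgroups should be spatially
co-located relative to whole-cell-type mixing; (2) ligand-receptor calls
made per sub-crosstalk pair should be more reproducible across asymmetric
subsamples than calls made per whole cell type; (3) features summarizing
expression per sub-crosstalk pair should predict therapy response better
than whole-cell-type features when the response signal is confined to one
pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.svm import SVC

from .consensus import CSCPFinder
from .errors import ZeroDifferenceError
from .io import CoupledInputs, ExpressionMatrix, LigandReceptorDB
from .synthetic import SpatialMap, construct_masked_samples

logger = logging.getLogger(__name__)

__all__ = [
    "LRCallSet",
    "cross_type_distances",
    "wilcoxon_signed_rank",
    "t_statistic",
    "jaccard_similarity",
    "reference_lr_caller",
    "masked_sampling_experiment",
    "build_patient_features",
    "lda_zscore_projection",
    "repeated_classifier_auc",
    "spatial_colocation_experiment",
    "prediction_experiment",
]


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(
    paired_a: Sequence[float], paired_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped. The exact null distribution is used for
    n <= 25 retained pairs, the normal approximation above. Returns the
    signed statistic W+ - W- (so swapping the inputs negates it) and the
    two-sided p-value.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        raise ZeroDifferenceError("all paired differences are zero")
    method = "exact" if d.size <= 25 else "approx"
    ranks = scipy.stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    res = scipy.stats.wilcoxon(d, method=method)
    return w_plus - w_minus, float(res.pvalue)


def t_statistic(groupA: Sequence[float], groupB: Sequence[float]) -> tuple[float, float]:
    """Two-sample pooled-variance t statistic with two-sided p-value.

    Degenerate zero-pooled-variance inputs: equal means give (0, 1);
    unequal means give a capped statistic (sign * 1e9, p = 0) with a log
    entry rather than an infinity.
    """
    a = np.asarray(groupA, dtype=float)
    b = np.asarray(groupB, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    sp2 = (((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
           / (a.size + b.size - 2))
    if sp2 == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        logger.warning("zero pooled variance with unequal means; capping |t|")
        return float(np.sign(a.mean() - b.mean()) * 1e9), 0.0
    t, p = scipy.stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def jaccard_similarity(setA, setB) -> float:
    """|A n B| / |A u B|; two empty sets count as identical (1, logged)."""
    sa, sb = set(setA), set(setB)
    if not sa and not sb:
        logger.info("jaccard of two empty sets defined as 1")
        return 1.0
    return len(sa & sb) / len(sa | sb)


# ---------------------------------------------------------------------------
# spatial evaluation
# ---------------------------------------------------------------------------

def cross_type_distances(
    map: SpatialMap, groupA_cells: Sequence[str], groupB_cells: Sequence[str]
) -> float:
    """Mean Euclidean distance over all A x B cross pairs of cells."""
    ga, gb = set(groupA_cells), set(groupB_cells)
    if not ga or not gb:
        raise ValueError("both groups must be nonempty")
    if ga & gb:
        raise ValueError("groups must be disjoint")
    idx = {c: i for i, c in enumerate(map.cell_ids)}
    xy = np.column_stack([map.x, map.y])
    pa = xy[[idx[c] for c in groupA_cells]]
    pb = xy[[idx[c] for c in groupB_cells]]
    return float(cdist(pa, pb).mean())


def spatial_colocation_experiment(
    maps: Sequence[SpatialMap],
) -> dict:
    """Per field of view, compare the mean sender-receiver distance within
    each sub-crosstalk pair against the whole-map cross-type distance.

    Returns the per-FOV distance pairs and a Wilcoxon signed-rank p-value
    over FOVs (within-pair mean vs whole-map mean).
    """
    within, overall = [], []
    records = []
    for i, m in enumerate(maps):
        senders = [c for c, t in zip(m.cell_ids, m.cell_types) if t == "sender"]
        receivers = [c for c, t in zip(m.cell_ids, m.cell_types) if t == "receiver"]
        d_all = cross_type_distances(m, senders, receivers)
        per_pair = []
        for k in np.unique(m.cscp_labels):
            sk = [c for c, t, l in zip(m.cell_ids, m.cell_types, m.cscp_labels)
                  if t == "sender" and l == k]
            rk = [c for c, t, l in zip(m.cell_ids, m.cell_types, m.cscp_labels)
                  if t == "receiver" and l == k]
            if sk and rk:
                per_pair.append(cross_type_distances(m, sk, rk))
        d_within = float(np.mean(per_pair))
        within.append(d_within)
        overall.append(d_all)
        records.append({"fov": i, "within_cscp": d_within, "whole_map": d_all,
                        "per_cscp": per_pair})
    stat, p = wilcoxon_signed_rank(within, overall)
    return {"fovs": records, "within_mean": float(np.mean(within)),
            "overall_mean": float(np.mean(overall)),
            "wilcoxon_statistic": stat, "wilcoxon_p": p}


# ---------------------------------------------------------------------------
# permutation ligand-receptor caller
# ---------------------------------------------------------------------------

@dataclass
class LRCallSet:
    """Ligand-receptor pairs called significant by the permutation caller."""

    calls: set = field(default_factory=set)
    scores: dict = field(default_factory=dict)
    pvalues: dict = field(default_factory=dict)
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pair, p in self.pvalues.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p-value out of range for {pair}")


def reference_lr_caller(
    XL_cells: ExpressionMatrix,
    XR_cells: ExpressionMatrix,
    lr_db: LigandReceptorDB,
    n_perm: int = 1000,
    alpha: float = 0.05,
    min_fraction: float = 0.2,
    seed: int = 0,
) -> LRCallSet:
    """Permutation test for active ligand-receptor pairs between a sender
    and a receiver cell population.

    For each pair, score = mean(mean ligand expression in senders, mean
    receptor expression in receivers). The null pools the sender and
    receiver cells and permutes the sender/receiver split ``n_perm`` times;
    p = (#permuted scores >= observed + 1) / (n_perm + 1). A pair is called
    iff p < alpha AND the ligand is detected (> 0) in more than
    ``min_fraction`` of senders AND the receptor in more than
    ``min_fraction`` of receivers. Pairs whose genes are missing from
    either matrix are skipped with a log entry (the permutation needs both
    genes measured in both populations).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    n_s, n_r = XL_cells.n_cells, XR_cells.n_cells
    n_tot = n_s + n_r
    perm = np.stack([rng.permutation(n_tot) for _ in range(n_perm)])
    sidx = perm[:, :n_s]
    ridx = perm[:, n_s:]

    gl = {g: i for i, g in enumerate(XL_cells.gene_ids)}
    gr = {g: i for i, g in enumerate(XR_cells.gene_ids)}
    calls, scores, pvalues = set(), {}, {}
    for lig, rec in sorted(lr_db.pairs):
        if lig not in gl or lig not in gr or rec not in gl or rec not in gr:
            logger.info("skipping pair (%s, %s): gene absent from a matrix", lig, rec)
            continue
        lig_pool = np.concatenate([XL_cells.values[gl[lig]], XR_cells.values[gr[lig]]])
        rec_pool = np.concatenate([XL_cells.values[gl[rec]], XR_cells.values[gr[rec]]])
        obs = 0.5 * (lig_pool[:n_s].mean() + rec_pool[n_s:].mean())
        null = 0.5 * (lig_pool[sidx].mean(axis=1) + rec_pool[ridx].mean(axis=1))
        p = (float(np.sum(null >= obs)) + 1.0) / (n_perm + 1.0)
        scores[(lig, rec)] = float(obs)
        pvalues[(lig, rec)] = p
        frac_l = float(np.mean(XL_cells.values[gl[lig]] > 0))
        frac_r = float(np.mean(XR_cells.values[gr[rec]] > 0))
        if p < alpha and frac_l > min_fraction and frac_r > min_fraction:
            calls.add((lig, rec))
    return LRCallSet(calls=calls, scores=scores, pvalues=pvalues,
                     settings={"n_perm": n_perm, "alpha": alpha,
                               "min_fraction": min_fraction, "seed": seed})


# ---------------------------------------------------------------------------
# masked-sampling reproducibility experiment
# ---------------------------------------------------------------------------

def _split_by_type(m: ExpressionMatrix, cells: Sequence[str], cell_type: str
                   ) -> ExpressionMatrix:
    keep = [c for c in cells
            if m.cell_types[m.cell_ids.index(c)] == cell_type]
    return m.subset(cells=keep)


def masked_sampling_experiment(
    full_matrix: ExpressionMatrix,
    inputs: CoupledInputs,
    lr_db: LigandReceptorDB,
    sender_labels: np.ndarray,
    receiver_labels: np.ndarray,
    keep_fraction: float = 0.2,
    n_perm: int = 200,
    alpha: float = 0.05,
    min_fraction: float = 0.2,
    n_runs: int = 5,
    seed: int = 0,
) -> dict:
    """Asymmetric two-sample reproducibility of ligand-receptor calls.

    Builds the mirrored masked samples, re-identifies K=2 sub-crosstalk
    pairs in each, and calls ligand-receptor pairs both at cell-type level
    (all kept cells) and per identified pair (calls tagged by pair index,
    with sample-2 indices aligned to sample 1 through shared-cell overlap).
    Returns the Jaccard similarity of the two samples' call sets at each
    level; higher at pair level means pair-resolved calls are more robust
    to asymmetric subsampling.
    """
    s1, s2 = construct_masked_samples(inputs, sender_labels, receiver_labels,
                                      keep_fraction=keep_fraction, seed=seed)
    id_lookup = {c: i for i, c in enumerate(full_matrix.cell_ids)}

    def _matrices_for(sample: CoupledInputs
                      ) -> tuple[ExpressionMatrix, ExpressionMatrix]:
        send = full_matrix.subset(cells=list(sample.XL.cell_ids))
        recv = full_matrix.subset(cells=list(sample.XR.cell_ids))
        return send, recv

    results = []
    for j, sample in enumerate((s1, s2)):
        send_m, recv_m = _matrices_for(sample)
        type_calls = reference_lr_caller(
            send_m, recv_m, lr_db, n_perm=n_perm, alpha=alpha,
            min_fraction=min_fraction, seed=seed + 101 + j).calls
        finder = CSCPFinder(n_components=2, n_runs=n_runs,
                            random_state=seed + 11 * (j + 1)).fit(sample)
        tagged = {}
        for cscp in finder.result_.cscps:
            sub_calls = reference_lr_caller(
                full_matrix.subset(cells=cscp.sender_cells),
                full_matrix.subset(cells=cscp.receiver_cells),
                lr_db, n_perm=n_perm, alpha=alpha,
                min_fraction=min_fraction, seed=seed + 211 + j).calls
            tagged[cscp.index] = sub_calls
        results.append({
            "sample": sample, "type_calls": type_calls, "tagged": tagged,
            "sender_labels": finder.sender_labels_,
            "receiver_labels": finder.receiver_labels_,
        })

    # align sample-2 cluster indices to sample 1 via shared cells
    def _cell_label_map(res) -> dict[str, int]:
        m = {}
        for c, l in zip(res["sample"].XL.cell_ids, res["sender_labels"]):
            m[c] = int(l)
        for c, l in zip(res["sample"].XR.cell_ids, res["receiver_labels"]):
            m[c] = int(l)
        return m

    m1, m2 = _cell_label_map(results[0]), _cell_label_map(results[1])
    shared = set(m1) & set(m2)
    K = 2
    overlap = np.zeros((K, K))
    for c in shared:
        overlap[m2[c], m1[c]] += 1
    rows, cols = linear_sum_assignment(-overlap)
    remap = dict(zip(rows, cols))

    cscp_calls_1 = {(k, *pair) for k, calls in results[0]["tagged"].items()
                    for pair in calls}
    cscp_calls_2 = {(remap.get(k, k), *pair)
                    for k, calls in results[1]["tagged"].items()
                    for pair in calls}
    j_cscp = jaccard_similarity(cscp_calls_1, cscp_calls_2)
    j_type = jaccard_similarity(results[0]["type_calls"], results[1]["type_calls"])
    return {
        "jaccard_cscp": j_cscp,
        "jaccard_celltype": j_type,
        "type_calls": (results[0]["type_calls"], results[1]["type_calls"]),
        "cscp_calls": (cscp_calls_1, cscp_calls_2),
    }


# ---------------------------------------------------------------------------
# prediction pipeline
# ---------------------------------------------------------------------------

def build_patient_features(
    per_patient_expr: Mapping[str, ExpressionMatrix],
    response: Mapping[str, str],
    level: str,
    cscp_labels: Mapping[str, np.ndarray] | None = None,
    receptor_gene: str = "RG000",
    ligand_gene: str | None = None,
    sender_type: str = "sender",
    receiver_type: str = "receiver",
    subtype_labels: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-patient feature table for response prediction.

    ``level`` selects the resolution:

    * ``cell_type`` — mean receptor expression over all receiver-type cells
      (plus, when ``ligand_gene`` is given, the mean of that and the mean
      ligand expression over sender cells).
    * ``cscp`` — the same statistics computed per sub-crosstalk pair (via
      ``cscp_labels``: per-patient joint labels, senders then receivers),
      concatenated over pairs.
    * ``cell_subtype`` — per-subtype receptor means (receptor-only; the
      two-gene variant has no defined subtype matching).

    Patients missing a required cell type / label set are dropped with a
    warning. Returns a DataFrame with feature columns plus ``response``.
    """
    if level not in ("cell_type", "cscp", "cell_subtype"):
        raise ValueError(f"unknown level {level!r}")
    rows = {}
    for pid, m in per_patient_expr.items():
        if pid not in response:
            logger.warning("patient %s has no response label; dropped", pid)
            continue
        if receptor_gene not in m.gene_ids or (
                ligand_gene is not None and ligand_gene not in m.gene_ids):
            raise KeyError(f"required gene absent for patient {pid}")
        types = np.asarray(m.cell_types)
        recv = types == receiver_type
        send = types == sender_type
        if not recv.any() or (ligand_gene is not None and not send.any()):
            logger.warning("patient %s lacks required cell types; dropped", pid)
            continue
        ri = m.gene_ids.index(receptor_gene)
        li = m.gene_ids.index(ligand_gene) if ligand_gene is not None else None

        def _feats(mask_r: np.ndarray, mask_s: np.ndarray) -> list[float]:
            rec_mean = float(m.values[ri, mask_r].mean()) if mask_r.any() else 0.0
            if li is None:
                return [rec_mean]
            lig_mean = float(m.values[li, mask_s].mean()) if mask_s.any() else 0.0
            return [0.5 * (rec_mean + lig_mean)]

        if level == "cell_type":
            feats = _feats(recv, send)
        elif level == "cscp":
            if cscp_labels is None or pid not in cscp_labels:
                logger.warning("patient %s lacks sub-crosstalk labels; dropped", pid)
                continue
            lab = np.asarray(cscp_labels[pid], dtype=int)
            feats = []
            for k in sorted(set(lab.tolist())):
                feats += _feats(recv & (lab == k), send & (lab == k))
        else:  # cell_subtype
            if ligand_gene is not None:
                raise ValueError(
                    "two-gene features are undefined at cell-subtype level "
                    "(no sender/receiver subtype matching exists)")
            labsrc = subtype_labels if subtype_labels is not None else cscp_labels
            if labsrc is None or pid not in labsrc:
                logger.warning("patient %s lacks subtype labels; dropped", pid)
                continue
            lab = np.asarray(labsrc[pid], dtype=int)
            feats = [float(m.values[ri, recv & (lab == k)].mean())
                     if (recv & (lab == k)).any() else 0.0
                     for k in sorted(set(lab.tolist()))]
        rows[pid] = feats
    if not rows:
        raise ValueError("no patients with complete data")
    width = max(len(v) for v in rows.values())
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=[f"f{i}" for i in range(width)])
    df["response"] = [response[p] for p in df.index]
    return df


def lda_zscore_projection(features: np.ndarray, labels: Sequence) -> np.ndarray:
    """Project features to 1-D along the two-class Fisher discriminant,
    then z-score across patients.

    One-dimensional features pass straight to the z-scoring. A singular
    within-class scatter matrix is ridged by 1e-6 (logged).
    """
    F = np.asarray(features, dtype=float)
    if F.ndim == 1:
        F = F[:, None]
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError("each class needs at least 2 patients")
    if F.shape[1] == 1:
        s = F[:, 0]
    else:
        m0 = F[y == classes[0]].mean(axis=0)
        m1 = F[y == classes[1]].mean(axis=0)
        Sw = np.zeros((F.shape[1], F.shape[1]))
        for c in classes:
            X = F[y == c] - F[y == c].mean(axis=0)
            Sw += X.T @ X
        if np.linalg.matrix_rank(Sw) < Sw.shape[0]:
            logger.warning("singular within-class scatter; adding ridge 1e-6")
            Sw = Sw + 1e-6 * np.eye(Sw.shape[0])
        w = np.linalg.solve(Sw, m1 - m0)
        s = F @ w
    sd = s.std(ddof=0)
    if sd == 0:
        return np.zeros_like(s)
    return (s - s.mean()) / sd


def repeated_classifier_auc(
    features: np.ndarray,
    labels: Sequence,
    n_repeats: int = 100,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> float:
    """Mean held-out ROC AUC of a linear maximum-margin classifier over
    repeated stratified train/test splits (default 100 repeats, 4/5 train)."""
    F = np.asarray(features, dtype=float)
    if F.ndim == 1:
        F = F[:, None]
    y = pd.factorize(pd.Series(labels), sort=True)[0]
    splitter = StratifiedShuffleSplit(n_splits=n_repeats,
                                      train_size=train_fraction,
                                      random_state=seed)
    aucs = []
    for tr, te in splitter.split(F, y):
        if len(np.unique(y[te])) < 2:
            logger.warning("degenerate test split resampled")
            continue
        clf = SVC(kernel="linear").fit(F[tr], y[tr])
        aucs.append(roc_auc_score(y[te], clf.decision_function(F[te])))
    return float(np.mean(aucs))


def prediction_experiment(
    per_patient_expr: Mapping[str, ExpressionMatrix],
    cscp_labels: Mapping[str, np.ndarray],
    response: Mapping[str, str],
    receptor_gene: str = "RG000",
    ligand_gene: str | None = None,
    n_repeats: int = 100,
    seed: int = 0,
) -> dict:
    """Compare cell-type-level against sub-crosstalk-pair-level features.

    Returns the mean repeated-split AUC and the |t| of the discriminant
    projection between responders and non-responders at both levels.
    """
    out = {}
    for level in ("cell_type", "cscp"):
        df = build_patient_features(per_patient_expr, response, level,
                                    cscp_labels=cscp_labels,
                                    receptor_gene=receptor_gene,
                                    ligand_gene=ligand_gene)
        F = df.drop(columns="response").to_numpy()
        y = df["response"].to_numpy()
        auc = repeated_classifier_auc(F, y, n_repeats=n_repeats, seed=seed)
        z = lda_zscore_projection(F, y)
        t, p = t_statistic(z[y == "responder"], z[y == "non-responder"])
        out[level] = {"auc": auc, "t": t, "t_abs": abs(t), "p": p,
                      "n_features": F.shape[1]}
    return out
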