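"""Synthetic planted-structure generators.

These emulate the data regime the method targets: a sender cell type whose
cells fall into K subgroups, each expressing its own block of ligand genes,
matched through a ligand-receptor table to receptor-gene blocks expressed
by the corresponding receiver subgroups, over a noisy baseline. Counts are
negative-binomial (Poisson in the infinite-dispersion limit) and are
log-library-normalized before factorization, mimicking UMI count
sparsity/overdispersion without attempting transcriptome-wide realism.

Also provided: spatially co-located blobs per sub-crosstalk pair, random
deletion/rematch perturbations of the ligand-receptor table, masked
two-sample designs for the reproducibility experiment, and a small patient
cohort whose therapy-response signal lives in a single sub-crosstalk pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyTableError
from .io import (
    CoupledInputs,
    ExpressionMatrix,
    LigandReceptorDB,
    build_coupled_inputs,
    normalize_expression,
)

__all__ = [
    "PlantedTruth",
    "SpatialMap",
    "generate_lr_db",
    "generate_planted_dataset",
    "generate_spatial_map",
    "perturb_lr_db",
    "construct_masked_samples",
    "generate_response_cohort",
]


@dataclass
class PlantedTruth:
    """Ground truth of a planted dataset."""

    sender_labels: np.ndarray
    receiver_labels: np.ndarray
    ligand_blocks: list[list[str]]
    receptor_blocks: list[list[str]]
    signal: float
    baseline: float
    dispersion: float
    seed: int
    full_matrix: ExpressionMatrix | None = None

    @property
    def K(self) -> int:
        return len(self.ligand_blocks)


@dataclass
class SpatialMap:
    """Per-cell 2-D coordinates with type and sub-crosstalk-pair labels."""

    cell_ids: list[str]
    x: np.ndarray
    y: np.ndarray
    cell_types: list[str]
    cscp_labels: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.cscp_labels = np.asarray(self.cscp_labels, dtype=int)
        n = len(self.cell_ids)
        if not (self.x.size == self.y.size == n == len(self.cell_types)
                == self.cscp_labels.size):
            raise ValueError("spatial map fields misaligned")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("coordinates must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_id": self.cell_ids, "x": self.x, "y": self.y,
            "cell_type": self.cell_types, "cscp": self.cscp_labels,
        })


def generate_lr_db(
    n_pairs: int, n_extra_ligands: int = 0, n_extra_receptors: int = 0,
    seed: int = 0,
) -> LigandReceptorDB:
    """One-to-one synthetic ligand-receptor pairs (LG000->RG000, ...) plus
    unpaired decoy genes that never appear in A's 1-entries."""
    if n_pairs < 1:
        raise EmptyTableError("n_pairs must be >= 1")
    pairs = {(f"LG{i:03d}", f"RG{i:03d}") for i in range(n_pairs)}
    ligs = sorted({l for l, _ in pairs}) + [f"LX{i:03d}" for i in range(n_extra_ligands)]
    recs = sorted({r for _, r in pairs}) + [f"RX{i:03d}" for i in range(n_extra_receptors)]
    return LigandReceptorDB(pairs=pairs, ligand_universe=sorted(ligs),
                            receptor_universe=sorted(recs))


def _nb_counts(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = m + m^2/dispersion; Poisson when
    dispersion is infinite."""
    mean = np.asarray(mean, dtype=float)
    if np.isinf(dispersion):
        return rng.poisson(mean).astype(float)
    p = dispersion / (dispersion + np.where(mean > 0, mean, 1.0))
    out = rng.negative_binomial(dispersion, p).astype(float)
    out[mean <= 0] = 0.0
    return out


def generate_planted_dataset(
    K: int = 2,
    cells_per_subgroup: int = 50,
    genes_per_block: int = 10,
    signal: float = 8.0,
    baseline: float = 2.0,
    dispersion: float = 5.0,
    seed: int = 0,
    noiseless: bool = False,
    normalize: bool = True,
    n_extra_ligands: int = 0,
    n_extra_receptors: int = 0,
) -> tuple[CoupledInputs, PlantedTruth]:
    """Planted block-structured dataset with K sub-crosstalk pairs.

    Each subgroup k (both sides, ``cells_per_subgroup`` cells each) expresses
    its own block of ``genes_per_block`` ligand (sender side) or receptor
    (receiver side) genes at count mean ``signal``; all other entries have
    mean ``baseline``. ``noiseless=True`` replaces the count draw by the
    exact means (the zero-noise limit used by the small-instance oracle).

    Returns the assembled :class:`CoupledInputs` and the ground truth; the
    full gene x cell matrix (both cell types together) is kept on the truth
    object for procedures that need non-LR rows of the other side.
    """
    if not signal > baseline >= 0:
        raise ValueError("require signal > baseline >= 0")
    if K < 1 or cells_per_subgroup < 1 or genes_per_block < 1:
        raise ValueError("degenerate sizes")
    rng = np.random.default_rng(seed)
    lr = generate_lr_db(K * genes_per_block, n_extra_ligands, n_extra_receptors,
                        seed=seed)
    lig_blocks = [[f"LG{i:03d}" for i in range(k * genes_per_block,
                                               (k + 1) * genes_per_block)]
                  for k in range(K)]
    rec_blocks = [[f"RG{i:03d}" for i in range(k * genes_per_block,
                                               (k + 1) * genes_per_block)]
                  for k in range(K)]
    lig_genes = [g for b in lig_blocks for g in b]
    rec_genes = [g for b in rec_blocks for g in b]
    n_cells = K * cells_per_subgroup
    labels = np.repeat(np.arange(K), cells_per_subgroup)

    def _mean_matrix(genes: list[str], blocks: list[list[str]]) -> np.ndarray:
        m = np.full((len(genes), n_cells), float(baseline))
        gi = {g: i for i, g in enumerate(genes)}
        for k, block in enumerate(blocks):
            cols = labels == k
            for g in block:
                m[gi[g], cols] = signal
        return m

    mean_s = _mean_matrix(lig_genes, lig_blocks)   # ligand genes in senders
    mean_r = _mean_matrix(rec_genes, rec_blocks)   # receptor genes in receivers
    # the other side's rows sit at baseline (receptors in senders, etc.)
    base_s = np.full((len(rec_genes), n_cells), float(baseline))
    base_r = np.full((len(lig_genes), n_cells), float(baseline))

    if noiseless:
        cs = np.vstack([mean_s, base_s])
        cr = np.vstack([base_r, mean_r])
    else:
        cs = np.vstack([_nb_counts(rng, mean_s, dispersion),
                        _nb_counts(rng, base_s, dispersion)])
        cr = np.vstack([_nb_counts(rng, base_r, dispersion),
                        _nb_counts(rng, mean_r, dispersion)])

    genes = lig_genes + rec_genes
    sender_ids = [f"S{c:04d}" for c in range(n_cells)]
    receiver_ids = [f"R{c:04d}" for c in range(n_cells)]
    m = ExpressionMatrix(
        values=np.hstack([cs, cr]),
        gene_ids=genes,
        cell_ids=sender_ids + receiver_ids,
        cell_types=["sender"] * n_cells + ["receiver"] * n_cells,
    )
    if normalize:
        m = normalize_expression(m)
    inputs = build_coupled_inputs(m, lr, "sender", "receiver",
                                  min_cells=min(5, n_cells))
    # align truth labels to the retained cell order (columns keep input order)
    truth = PlantedTruth(
        sender_labels=labels.copy(), receiver_labels=labels.copy(),
        ligand_blocks=lig_blocks, receptor_blocks=rec_blocks,
        signal=signal, baseline=baseline, dispersion=dispersion, seed=seed,
        full_matrix=m,
    )
    return inputs, truth


def generate_spatial_map(
    truth: PlantedTruth,
    centers: np.ndarray | None = None,
    spread: float = 1.0,
    seed: int = 0,
) -> SpatialMap:
    """Place each cell at an isotropic Gaussian draw around its
    sub-crosstalk pair's center; sender and receiver cells share blobs."""
    K = truth.K
    if centers is None:
        centers = np.array([[8.0 * k, 0.0] for k in range(K)])
    centers = np.asarray(centers, dtype=float)
    if centers.shape[0] < K:
        raise ValueError(f"{centers.shape[0]} centers for {K} sub-crosstalk pairs")
    rng = np.random.default_rng(seed)
    labels = np.concatenate([truth.sender_labels, truth.receiver_labels])
    n_s = truth.sender_labels.size
    ids = [f"S{c:04d}" for c in range(n_s)] + \
          [f"R{c:04d}" for c in range(truth.receiver_labels.size)]
    types = ["sender"] * n_s + ["receiver"] * truth.receiver_labels.size
    xy = centers[labels] + rng.normal(0.0, spread, size=(labels.size, 2))
    return SpatialMap(cell_ids=ids, x=xy[:, 0], y=xy[:, 1],
                      cell_types=types, cscp_labels=labels)


def perturb_lr_db(
    db: LigandReceptorDB, fraction: float, mode: str, seed: int = 0
) -> LigandReceptorDB:
    """Randomly delete or rematch a fraction of the ligand-receptor pairs.

    ``delete`` removes floor(fraction * |pairs|) uniformly chosen pairs;
    ``rematch`` replaces the receptor of that many pairs with a different
    receptor drawn from the universe without creating a duplicate pair.
    Universes are kept fixed so downstream matrix shapes are comparable.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if mode not in ("delete", "rematch"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    pairs = sorted(db.pairs)
    n_perturb = int(np.floor(fraction * len(pairs)))
    if n_perturb == 0:
        return LigandReceptorDB(pairs=set(pairs),
                                ligand_universe=list(db.ligand_universe),
                                receptor_universe=list(db.receptor_universe))
    chosen = rng.choice(len(pairs), size=n_perturb, replace=False)
    chosen_set = set(chosen.tolist())
    if mode == "delete":
        new_pairs = {p for i, p in enumerate(pairs) if i not in chosen_set}
    else:
        receptors = list(db.receptor_universe)
        if len(receptors) < 2:
            raise ValueError("rematch impossible: receptor universe of size 1")
        new_pairs = {p for i, p in enumerate(pairs) if i not in chosen_set}
        for i in sorted(chosen_set):
            lig, old_rec = pairs[i]
            candidates = [r for r in receptors
                          if r != old_rec and (lig, r) not in new_pairs]
            if not candidates:
                new_pairs.add(pairs[i])  # nowhere to rematch; keep as is
                continue
            new_pairs.add((lig, candidates[rng.integers(len(candidates))]))
    return LigandReceptorDB(pairs=new_pairs,
                            ligand_universe=list(db.ligand_universe),
                            receptor_universe=list(db.receptor_universe))


def _mask_side(cells: list[str], labels: np.ndarray, keep_cscp: int,
               keep_fraction: float, rng: np.random.Generator) -> list[str]:
    """Keep all cells of ``keep_cscp`` and a keep_fraction of the other."""
    keep: list[str] = []
    other = 1 - keep_cscp
    other_idx = np.where(labels == other)[0]
    n_keep = max(1, int(np.floor(keep_fraction * other_idx.size)))
    sampled = set(rng.choice(other_idx, size=n_keep, replace=False).tolist()) \
        if keep_fraction < 1.0 else set(other_idx.tolist())
    for i, c in enumerate(cells):
        if labels[i] == keep_cscp or i in sampled:
            keep.append(c)
    return keep


def construct_masked_samples(
    inputs: CoupledInputs,
    sender_labels: np.ndarray,
    receiver_labels: np.ndarray,
    keep_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[CoupledInputs, CoupledInputs]:
    """Two-sample masked design for the reproducibility experiment.

    With exactly two labeled sub-crosstalk pairs, sample 1 keeps every
    pair-0 cell and floor(keep_fraction * n) (at least 1) randomly chosen
    pair-1 cells on both sides; sample 2 is the mirror. Cell order is
    preserved; the kept subsets are reproducible given ``seed``.
    """
    sender_labels = np.asarray(sender_labels, dtype=int)
    receiver_labels = np.asarray(receiver_labels, dtype=int)
    for lab, n in ((sender_labels, inputs.n_senders),
                   (receiver_labels, inputs.n_receivers)):
        if lab.size != n:
            raise ValueError("labels misaligned with inputs")
        if set(np.unique(lab)) - {0, 1}:
            raise ValueError("masked sampling requires exactly 2 labeled pairs")
        for k in (0, 1):
            if not (lab == k).any():
                raise ValueError(f"sub-crosstalk pair {k} has no cells on one side")
    rng = np.random.default_rng(seed)
    out = []
    for keep_cscp in (0, 1):
        s_cells = _mask_side(inputs.XL.cell_ids, sender_labels, keep_cscp,
                             keep_fraction, rng)
        r_cells = _mask_side(inputs.XR.cell_ids, receiver_labels, keep_cscp,
                             keep_fraction, rng)
        out.append(CoupledInputs(
            XL=inputs.XL.subset(cells=s_cells),
            XR=inputs.XR.subset(cells=r_cells),
            A=inputs.A.copy(),
            sender_type=inputs.sender_type,
            receiver_type=inputs.receiver_type,
        ))
    return out[0], out[1]


def generate_response_cohort(
    n_responders: int = 9,
    n_nonresponders: int = 20,
    cells_per_subgroup: int = 20,
    effect: float = 1.0,
    base: float = 1.0,
    sd: float = 0.3,
    patient_sd: float = 0.4,
    seed: int = 0,
    ligand_gene: str = "LG000",
    receptor_gene: str = "RG000",
) -> tuple[dict[str, ExpressionMatrix], dict[str, np.ndarray], dict[str, str]]:
    """Synthetic patient cohort for the therapy-response prediction pipeline.

    Each patient contributes sender and receiver cells split over two
    sub-crosstalk pairs. Responders carry an elevated receptor (and ligand)
    mean only within pair 0; at cell-type level that signal is diluted by
    the pair-1 cells, which is what makes pair-resolved features more
    predictive. ``patient_sd`` adds a per-patient random baseline shift
    (inter-patient variability) so that the diluted cell-type-level signal
    is only partially discriminative. The 9/20 class ratio mirrors a
    typical anti-PD-1 cohort.

    Returns (per-patient expression, per-patient joint pair labels keyed by
    cell ID order senders-then-receivers, per-patient response label).
    """
    rng = np.random.default_rng(seed)
    expr: dict[str, ExpressionMatrix] = {}
    cscp: dict[str, np.ndarray] = {}
    response: dict[str, str] = {}
    n_cells = 2 * cells_per_subgroup
    labels = np.repeat([0, 1], cells_per_subgroup)
    for p in range(n_responders + n_nonresponders):
        pid = f"P{p:02d}"
        is_resp = p < n_responders
        pbase = base + rng.normal(0.0, patient_sd)
        lig = np.clip(rng.normal(pbase, sd, n_cells), 0, None)
        rec = np.clip(rng.normal(pbase, sd, n_cells), 0, None)
        if is_resp:
            boost = labels == 0
            lig[boost] = np.clip(rng.normal(pbase + effect, sd, boost.sum()), 0, None)
            rec[boost] = np.clip(rng.normal(pbase + effect, sd, boost.sum()), 0, None)
        values = np.zeros((2, 2 * n_cells))
        values[0, :n_cells] = lig          # ligand gene in sender cells
        values[1, n_cells:] = rec          # receptor gene in receiver cells
        expr[pid] = ExpressionMatrix(
            values=values,
            gene_ids=[ligand_gene, receptor_gene],
            cell_ids=[f"{pid}S{i:03d}" for i in range(n_cells)]
                     + [f"{pid}R{i:03d}" for i in range(n_cells)],
            cell_types=["sender"] * n_cells + ["receiver"] * n_cells,
        )
        cscp[pid] = np.concatenate([labels, labels])
        response[pid] = "responder" if is_resp else "non-responder"
    return expr, cscp, response
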