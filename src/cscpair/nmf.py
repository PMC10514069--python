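"""Coupled non-negative matrix factorization.

Two expression matrices — ligand genes x sender cells (X^L) and receptor
genes x receiver cells (X^R) — are factorized jointly:

    min_{W,H >= 0}  1/2 ||X^L - W^L H^L||_F^2 + lambda1/2 ||X^R - W^R H^R||_F^2
                    - lambda2 tr((W^L)^T A W^R) + mu (||W^L||_F^2 + ||W^R||_F^2)

where A is the binary ligand x receptor pair indicator. The trace term
rewards factor pairs (W^L[:,k], W^R[:,k]) that load on matched
ligand-receptor genes, so the k-th columns of H^L and H^R define a paired
sender/receiver cell subgroup (a cell sub-crosstalk pair candidate).

The solver uses multiplicative updates (Gauss-Seidel order W^L, W^R, H^L,
H^R) after an uncoupled warm-up; lambda1, lambda2 and mu are selected from
the warm-up residuals and scaled by user multipliers (defaults 1, 1000, 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .io import CoupledInputs

logger = logging.getLogger(__name__)

__all__ = [
    "FactorSet",
    "NMFParams",
    "ObjectiveTrace",
    "CoupledNMF",
    "initialize_factors",
    "compute_objective",
    "multiplicative_update",
    "select_parameters",
    "run_coupled_nmf",
    "assign_subgroups",
]


@dataclass
class FactorSet:
    """The four non-negative factors W^L (genes x K), H^L (K x cells),
    W^R, H^R sharing the inner dimension K."""

    WL: np.ndarray
    HL: np.ndarray
    WR: np.ndarray
    HR: np.ndarray

    def __post_init__(self) -> None:
        self.WL = np.asarray(self.WL, dtype=float)
        self.HL = np.asarray(self.HL, dtype=float)
        self.WR = np.asarray(self.WR, dtype=float)
        self.HR = np.asarray(self.HR, dtype=float)
        ks = {self.WL.shape[1], self.HL.shape[0], self.WR.shape[1], self.HR.shape[0]}
        if len(ks) != 1:
            raise ValueError(f"inconsistent inner dimension K across factors: {ks}")

    @property
    def K(self) -> int:
        return self.WL.shape[1]

    def copy(self) -> "FactorSet":
        return FactorSet(self.WL.copy(), self.HL.copy(), self.WR.copy(), self.HR.copy())


@dataclass
class NMFParams:
    """Hyperparameters of one coupled NMF solve."""

    K: int = 2
    lambda1: float = 1.0
    lambda2: float = 0.0
    mu: float = 0.0
    multipliers: tuple[float, float, float] = (1.0, 1000.0, 1.0)
    max_iter: int = 500
    tol: float = 1e-4
    seed: int = 0
    eps: float = 1e-10
    warmup_iters: int = 50

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if min(self.lambda1, self.lambda2, self.mu) < 0:
            raise ValueError("lambda1, lambda2, mu must be non-negative")
        if self.tol <= 0 or self.eps <= 0:
            raise ValueError("tol and eps must be positive")


@dataclass
class ObjectiveTrace:
    """Per-iteration objective bookkeeping.

    ``total[i] == 0.5*rec_l[i] + lambda1/2*rec_r[i] - lambda2*coupling[i]
    + mu*regularization[i]`` at every recorded iteration.
    """

    total: list[float] = field(default_factory=list)
    rec_l: list[float] = field(default_factory=list)
    rec_r: list[float] = field(default_factory=list)
    coupling: list[float] = field(default_factory=list)
    regularization: list[float] = field(default_factory=list)

    def append(self, total: float, rec_l: float, rec_r: float,
               coupling: float, regularization: float) -> None:
        self.total.append(total)
        self.rec_l.append(rec_l)
        self.rec_r.append(rec_r)
        self.coupling.append(coupling)
        self.regularization.append(regularization)

    def __len__(self) -> int:
        return len(self.total)


def _arrays(inputs) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(inputs, CoupledInputs):
        return inputs.XL.values, inputs.XR.values, inputs.A
    XL, XR, A = inputs
    return np.asarray(XL, float), np.asarray(XR, float), np.asarray(A, float)


def initialize_factors(
    dims: tuple[int, int, int, int], K: int, seed: int
) -> FactorSet:
    """Draw four strictly positive uniform(0, 1] random factor matrices.

    ``dims`` is (rows of X^L, cols of X^L, rows of X^R, cols of X^R). The
    draw is reproducible given ``seed``.
    """
    nl_g, nl_c, nr_g, nr_c = dims
    if K > min(dims):
        warnings.warn(
            f"K={K} exceeds the smallest matrix dimension {min(dims)}; "
            "the factorization is over-parameterized but still defined",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    draw = lambda shape: 1.0 - rng.random(shape)  # uniform on (0, 1]
    return FactorSet(
        WL=draw((nl_g, K)), HL=draw((K, nl_c)),
        WR=draw((nr_g, K)), HR=draw((K, nr_c)),
    )


def compute_objective(
    inputs, f: FactorSet, p: NMFParams
) -> tuple[float, dict[str, float]]:
    """Total coupled-NMF objective and its four terms.

    Returns ``(total, terms)`` with raw (unweighted) terms ``rec_l``,
    ``rec_r`` (squared Frobenius residuals), ``coupling``
    (tr((W^L)^T A W^R)) and ``regularization`` (||W^L||^2 + ||W^R||^2).
    """
    XL, XR, A = _arrays(inputs)
    rl = XL - f.WL @ f.HL
    rr = XR - f.WR @ f.HR
    rec_l = float(np.sum(rl * rl))
    rec_r = float(np.sum(rr * rr))
    coupling = float(np.trace(f.WL.T @ A @ f.WR))
    reg = float(np.sum(f.WL * f.WL) + np.sum(f.WR * f.WR))
    total = 0.5 * rec_l + 0.5 * p.lambda1 * rec_r - p.lambda2 * coupling + p.mu * reg
    return total, {
        "rec_l": rec_l, "rec_r": rec_r, "coupling": coupling, "regularization": reg,
    }


def multiplicative_update(inputs, f: FactorSet, p: NMFParams) -> FactorSet:
    """One full multiplicative-update round, in the order W^L, W^R, H^L, H^R.

    Each factor update uses the most recent values of the others
    (Gauss-Seidel). A is oriented ligand-rows x receptor-columns, so the
    coupling term enters the W^L numerator as (lambda2/2) A W^R and the W^R
    numerator as (lambda2 / 2 lambda1) A^T W^L. ``p.eps`` guards every
    denominator; non-negativity is preserved by construction.
    """
    XL, XR, A = _arrays(inputs)
    eps = p.eps
    WL, HL, WR, HR = f.WL.copy(), f.HL.copy(), f.WR.copy(), f.HR.copy()

    num = XL @ HL.T + 0.5 * p.lambda2 * (A @ WR)
    den = WL @ (HL @ HL.T) + 2.0 * p.mu * WL + eps
    WL = WL * (num / den)

    if p.lambda2 > 0 and p.lambda1 > 0:
        cross = (p.lambda2 / (2.0 * p.lambda1)) * (A.T @ WL)
    else:
        cross = 0.0
    num = XR @ HR.T + cross
    den = WR @ (HR @ HR.T) + 2.0 * p.mu * WR + eps
    WR = WR * (num / den)

    HL = HL * ((WL.T @ XL) / (WL.T @ WL @ HL + eps))
    HR = HR * ((WR.T @ XR) / (WR.T @ WR @ HR + eps))
    return FactorSet(WL, HL, WR, HR)


def select_parameters(
    inputs, f_warm: FactorSet,
    multipliers: tuple[float, float, float] = (1.0, 1000.0, 1.0),
) -> tuple[float, float, float]:
    """Select (lambda1, lambda2, mu) from warm-started residuals.

    lambda1 = ||X^L - W^L H^L||^2 / ||X^R - W^R H^R||^2
    lambda2 = ||X^L - W^L H^L||^2 / (2 tr((W^L)^T A W^R))
    mu      = ||X^L - W^L H^L||^2 / (2 (||W^L||^2 + ||W^R||^2))

    each scaled by its multiplier. A zero denominator sends that parameter
    to 0 with a logged warning.
    """
    _, terms = compute_objective(inputs, f_warm, NMFParams(K=f_warm.K))
    rec_l = terms["rec_l"]

    def _ratio(denom: float, name: str) -> float:
        if denom <= 0:
            logger.warning("degenerate denominator for %s; falling back to 0", name)
            return 0.0
        return rec_l / denom

    lam1 = multipliers[0] * _ratio(terms["rec_r"], "lambda1")
    lam2 = multipliers[1] * _ratio(2.0 * terms["coupling"], "lambda2")
    mu = multipliers[2] * _ratio(2.0 * terms["regularization"], "mu")
    return lam1, lam2, mu


def assign_subgroups(H: np.ndarray) -> np.ndarray:
    """Hard subgroup assignment: cell j -> argmax_k H[k, j], ties to smallest k."""
    H = np.asarray(H, dtype=float)
    zero_cols = ~np.any(H > 0, axis=0)
    if zero_cols.any():
        warnings.warn(
            f"{int(zero_cols.sum())} all-zero H columns assigned to subgroup 0",
            stacklevel=2,
        )
    return np.argmax(H, axis=0)


_FACTOR_FLOOR = 1e-12


def _align_receiver_columns(f: FactorSet, A: np.ndarray) -> FactorSet:
    """Permute receiver factor columns to maximize the communication score.

    The k-th sender and receiver subgroups form one sub-crosstalk pair, so
    the column pairing should maximize tr((W^L)^T A W^R) over permutations
    (solved exactly as a linear assignment). With an effective coupling
    weight the identity permutation is already optimal; this step resolves
    the pairing when the selected lambda2 is degenerate (e.g. the residual,
    and with it the coupling weight, vanishes on exactly separable data).
    """
    from scipy.optimize import linear_sum_assignment

    M = f.WL.T @ A @ f.WR
    _, cols = linear_sum_assignment(-M)
    if np.array_equal(cols, np.arange(f.K)):
        return f
    return FactorSet(f.WL, f.HL, f.WR[:, cols], f.HR[cols, :])


def _rescale_columns(f: FactorSet) -> FactorSet:
    """Fix the NMF scale gauge: unit-norm W columns, scale folded into H.

    W H is invariant under (W D^-1, D H); fixing ||W[:, k]|| = 1 bounds the
    bilinear coupling reward, without which the lambda2-weighted objective
    is unbounded below and the factors overflow. Zero columns are left
    untouched.
    """
    out = f.copy()
    for W, H in ((out.WL, out.HL), (out.WR, out.HR)):
        norms = np.linalg.norm(W, axis=0)
        pos = norms > 0
        W[:, pos] /= norms[pos]
        H[pos, :] *= norms[pos, None]
    # floor keeps entries movable: multiplicative rules lock exact zeros,
    # which on separable data can zero out the coupling trace entirely
    for M in (out.WL, out.HL, out.WR, out.HR):
        np.maximum(M, _FACTOR_FLOOR, out=M)
    return out


class CoupledNMF(ClusterMixin, BaseEstimator):
    """Single coupled-NMF solve as a scikit-learn style estimator.

    Parameters
    ----------
    n_components : int, default=2
        Number of sub-crosstalk pairs K. Small values (2 or 3) are
        recommended when the subgroup structure is unknown.
    multipliers : tuple of three floats, default=(1, 1000, 1)
        Scale factors applied to the automatically selected lambda1,
        lambda2 and mu. Setting an entry to 0 disables that term.
    warmup_iters : int, default=50
        Uncoupled multiplicative-update rounds (lambda2 = mu = 0) run
        before parameter selection.
    max_iter : int, default=500
        Maximum coupled rounds after warm-up.
    tol : float, default=1e-4
        Relative objective-change threshold; convergence requires it to be
        met over 10 consecutive rounds.
    random_state : int, default=0
        Seed for the uniform(0, 1] factor initialization.
    eps : float, default=1e-10
        Denominator guard in the multiplicative rules.

    Attributes
    ----------
    WL_, HL_, WR_, HR_ : the fitted factors
    params_ : NMFParams with the selected lambda1, lambda2, mu
    trace_ : ObjectiveTrace over the coupled phase
    sender_labels_, receiver_labels_ : hard subgroup assignments
    labels_ : joint assignment (senders then receivers)
    """

    _CONVERGE_ROUNDS = 10

    def __init__(self, n_components: int = 2,
                 multipliers: tuple[float, float, float] = (1.0, 1000.0, 1.0),
                 warmup_iters: int = 50, max_iter: int = 500, tol: float = 1e-4,
                 random_state: int = 0, eps: float = 1e-10):
        self.n_components = n_components
        self.multipliers = multipliers
        self.warmup_iters = warmup_iters
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state
        self.eps = eps

    def fit(self, X, y=None) -> "CoupledNMF":
        """Factorize the coupled inputs.

        ``X`` is a :class:`~cscpair.io.CoupledInputs` or a tuple
        ``(XL, XR, A)`` of arrays.
        """
        XL, XR, A = _arrays(X)
        K = self.n_components
        f = initialize_factors(
            (XL.shape[0], XL.shape[1], XR.shape[0], XR.shape[1]),
            K, self.random_state,
        )
        warm = NMFParams(K=K, lambda1=1.0, lambda2=0.0, mu=0.0,
                         eps=self.eps, seed=self.random_state,
                         warmup_iters=self.warmup_iters)
        for _ in range(self.warmup_iters):
            f = _rescale_columns(multiplicative_update((XL, XR, A), f, warm))

        lam1, lam2, mu = select_parameters((XL, XR, A), f, tuple(self.multipliers))
        params = NMFParams(
            K=K, lambda1=lam1, lambda2=lam2, mu=mu,
            multipliers=tuple(self.multipliers), max_iter=self.max_iter,
            tol=self.tol, seed=self.random_state, eps=self.eps,
            warmup_iters=self.warmup_iters,
        )
        trace = ObjectiveTrace()
        total, terms = compute_objective((XL, XR, A), f, params)
        trace.append(total, terms["rec_l"], terms["rec_r"],
                     terms["coupling"], terms["regularization"])
        streak = 0
        for it in range(self.max_iter):
            f = _rescale_columns(multiplicative_update((XL, XR, A), f, params))
            total, terms = compute_objective((XL, XR, A), f, params)
            if not np.isfinite(total):
                raise RuntimeError(
                    f"non-finite objective at coupled round {it + 1} "
                    f"(lambda1={lam1:.3g}, lambda2={lam2:.3g}, mu={mu:.3g})"
                )
            prev = trace.total[-1]
            trace.append(total, terms["rec_l"], terms["rec_r"],
                         terms["coupling"], terms["regularization"])
            rel = abs(total - prev) / (abs(prev) + params.eps)
            streak = streak + 1 if rel < self.tol else 0
            if streak >= self._CONVERGE_ROUNDS:
                break

        f = _align_receiver_columns(f, A)
        self.WL_, self.HL_, self.WR_, self.HR_ = f.WL, f.HL, f.WR, f.HR
        self.factors_ = f
        self.params_ = params
        self.trace_ = trace
        self.n_iter_ = len(trace) - 1
        self.sender_labels_ = assign_subgroups(f.HL)
        self.receiver_labels_ = assign_subgroups(f.HR)
        self.labels_ = np.concatenate([self.sender_labels_, self.receiver_labels_])
        return self


def run_coupled_nmf(
    inputs, K: int = 2, seed: int = 0, max_iter: int = 500, tol: float = 1e-4,
    warmup_iters: int = 50,
    multipliers: tuple[float, float, float] = (1.0, 1000.0, 1.0),
    eps: float = 1e-10,
) -> tuple[FactorSet, NMFParams, ObjectiveTrace]:
    """Functional wrapper over :class:`CoupledNMF`: warm-up, parameter
    selection, coupled updates to convergence."""
    est = CoupledNMF(n_components=K, multipliers=multipliers,
                     warmup_iters=warmup_iters, max_iter=max_iter, tol=tol,
                     random_state=seed, eps=eps).fit(inputs)
    return est.factors_, est.params_, est.trace_
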