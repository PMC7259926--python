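"""t-SNE reduction of the standardized 11-D features to a 3-D phase space.

The embedding preserves neighbour structure probabilistically: each point i
gets a Gaussian kernel in the 11-D space whose bandwidth sigma_i is calibrated
by bisection so that the row distribution p_{j|i} has a prescribed perplexity
2^H (the effective neighbour count).  The 3-D map minimises the
Kullback-Leibler divergence KL(P||Q) between the symmetrised input affinities
p_ij = (p_{j|i} + p_{i|j}) / 2n and a heavy-tailed Student-t kernel
q_ij = (1 + ||y_i - y_j||^2)^-1 normalised over all pairs.

Two backends: an exact gradient-descent implementation (records the full KL
trace and is bit-reproducible from a seed) used for n <= 5000, and sklearn's
Barnes-Hut approximation above that.  Optimiser settings follow common t-SNE
practice: learning rate 200, early exaggeration 12 for the first quarter of
the iterations, momentum 0.5 then 0.8, per-coordinate gains.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Union

import numpy as np

from .errors import NumericalError, ValidationError
from .preprocess import FeatureMatrix

EXACT_MAX_N = 5000  # exact O(n^2) backend up to this size, Barnes-Hut beyond
_MACHINE_EPS = 1e-12


@dataclass
class ConditionalProbabilities:
    """Row-stochastic conditional affinities p_{j|i} with calibrated bandwidths."""

    P: np.ndarray  # (n, n) conditional p_{j|i}; zero diagonal, rows sum to 1
    sigma: np.ndarray  # (n,) per-point Gaussian bandwidths
    target_perplexity: float

    @property
    def n(self) -> int:
        return self.P.shape[0]

    def symmetrized(self) -> np.ndarray:
        """Joint affinities p_ij = (p_{j|i} + p_{i|j}) / (2n); sums to 1."""
        return (self.P + self.P.T) / (2.0 * self.n)

    def achieved_perplexity(self) -> np.ndarray:
        """Per-row perplexity 2^H(P_i) with H the Shannon entropy (base 2)."""
        P = np.maximum(self.P, _MACHINE_EPS)
        H = -(np.where(self.P > 0, self.P * np.log2(P), 0.0)).sum(axis=1)
        return 2.0**H


@dataclass
class Embedding3D:
    """A 3-D t-SNE map with provenance and the final KL divergence."""

    Y: np.ndarray  # (n, 3)
    kl_final: float
    seed: int
    perplexity: float
    n_iter: int
    method: str = "exact"
    kl_trace: Optional[np.ndarray] = None  # per-iteration KL (exact backend)
    params: dict = dc_field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.Y.shape[0]


def _squared_distances(X: np.ndarray) -> np.ndarray:
    sq = np.einsum("ij,ij->i", X, X)
    D = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(D, 0.0, out=D)
    np.fill_diagonal(D, 0.0)
    return D


def _as_values(X: Union[FeatureMatrix, np.ndarray]) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return np.asarray(X.values, dtype=float)
    return np.asarray(X, dtype=float)


def calibrate_bandwidths(
    X: Union[FeatureMatrix, np.ndarray],
    perplexity: float,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> ConditionalProbabilities:
    """Bisection on each sigma_i until the row perplexity matches the target.

    The search runs on the precision beta_i = 1 / (2 sigma_i^2); for every
    point the achieved perplexity exp(H_i) is brought within ``tol`` of the
    target (well inside the 1e-4 contract).  Distances are Euclidean in the
    feature space as given.
    """
    Xv = _as_values(X)
    n = Xv.shape[0]
    if not perplexity < n:
        raise ValidationError(f"perplexity ({perplexity}) must be < n ({n})")
    if perplexity <= 1:
        raise ValidationError("perplexity must exceed 1")
    D = _squared_distances(Xv)
    logU = np.log(perplexity)

    beta = np.ones(n)
    beta_min = np.full(n, -np.inf)
    beta_max = np.full(n, np.inf)
    mask = ~np.eye(n, dtype=bool)
    P = np.zeros((n, n))

    for _ in range(max_iter):
        W = np.exp(-D * beta[:, None])
        W[~mask] = 0.0
        sumW = np.maximum(W.sum(axis=1), _MACHINE_EPS)
        # H in nats: log sumW + beta * <D>_W ; perplexity = exp(H)
        H = np.log(sumW) + beta * (D * W).sum(axis=1) / sumW
        P = W / sumW[:, None]
        diff = H - logU
        if np.all(np.abs(diff) < tol / max(perplexity, 1.0)):
            break
        too_wide = diff > 0  # entropy too high -> narrow the kernel
        beta_min = np.where(too_wide, beta, beta_min)
        beta_max = np.where(~too_wide, beta, beta_max)
        grow = too_wide & np.isinf(beta_max)
        shrink = ~too_wide & np.isinf(beta_min)
        mid = np.where(np.isfinite(beta_min) & np.isfinite(beta_max),
                       (beta_min + beta_max) / 2.0, beta)
        beta = np.where(grow, beta * 2.0, np.where(shrink, beta / 2.0, mid))
    else:
        # unreachable targets happen on degenerate inputs (e.g. many exactly
        # duplicated points bound the entropy from below); keep the closest
        # achievable calibration rather than aborting
        achieved = np.exp(H)
        worst = float(np.max(np.abs(achieved - perplexity)))
        if worst > 1e-4:
            import warnings

            warnings.warn(
                f"perplexity calibration off by up to {worst:.3g} for some points "
                "(target may be unreachable for degenerate distances)"
            )

    sigma = np.sqrt(1.0 / (2.0 * beta))
    return ConditionalProbabilities(P=P, sigma=sigma, target_perplexity=float(perplexity))


def _joint_q(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Student-t numerators and normalised joint Q for an embedding."""
    num = 1.0 / (1.0 + _squared_distances(Y))
    np.fill_diagonal(num, 0.0)
    Q = num / np.maximum(num.sum(), _MACHINE_EPS)
    return num, Q


def kl_divergence(
    P: Union[ConditionalProbabilities, np.ndarray],
    Y: Union[Embedding3D, np.ndarray],
) -> float:
    """KL(P||Q) = sum_{i != j} p_ij log(p_ij / q_ij), q from the Student-t kernel.

    ``P`` may be a ConditionalProbabilities (symmetrised internally) or an
    already-joint affinity matrix; q is strictly positive so the divergence is
    finite, and p = 0 terms contribute 0.  Nonnegative by Gibbs' inequality.
    """
    if isinstance(P, ConditionalProbabilities):
        Pj = P.symmetrized()
    else:
        Pj = np.asarray(P, dtype=float)
    Yv = Y.Y if isinstance(Y, Embedding3D) else np.asarray(Y, dtype=float)
    if Pj.shape[0] != Yv.shape[0]:
        raise ValidationError("P and Y dimensions disagree")
    _, Q = _joint_q(Yv)
    mask = Pj > 0
    return float(np.sum(Pj[mask] * np.log(Pj[mask] / np.maximum(Q[mask], _MACHINE_EPS))))


def _embed_exact(
    P_joint: np.ndarray,
    n_iter: int,
    rng: np.random.Generator,
    learning_rate: float,
    early_exaggeration: float,
    init: Optional[np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    n = P_joint.shape[0]
    Y = np.array(init, dtype=float) if init is not None else rng.normal(0.0, 1e-4, (n, 3))
    P = np.maximum(P_joint, _MACHINE_EPS)
    update = np.zeros_like(Y)
    gains = np.ones_like(Y)
    ee_end = max(1, n_iter // 4)
    trace = np.empty(n_iter)

    for it in range(n_iter):
        exaggeration = early_exaggeration if it < ee_end else 1.0
        momentum = 0.5 if it < ee_end else 0.8
        num, Q = _joint_q(Y)
        Qc = np.maximum(Q, _MACHINE_EPS)
        trace[it] = float(np.sum(P * np.log(P / Qc)))
        PQ = (exaggeration * P - Q) * num
        grad = 4.0 * ((np.diag(PQ.sum(axis=1)) - PQ) @ Y)
        flip = np.sign(grad) != np.sign(update)
        gains = np.where(flip, gains + 0.2, gains * 0.8)
        np.maximum(gains, 0.01, out=gains)
        update = momentum * update - learning_rate * gains * grad
        Y = Y + update
        Y = Y - Y.mean(axis=0)
    if not np.all(np.isfinite(Y)):
        raise NumericalError("t-SNE optimisation produced non-finite coordinates")
    return Y, trace


def embed(
    X: Union[FeatureMatrix, np.ndarray],
    perplexity: float = 400.0,
    n_iter: int = 300,
    seed: int = 0,
    method: str = "auto",
    learning_rate: float = 200.0,
    early_exaggeration: float = 12.0,
    init: Optional[np.ndarray] = None,
) -> Embedding3D:
    """Embed the feature matrix into 3-D by minimising KL(P||Q).

    ``method`` is ``"exact"``, ``"barnes_hut"`` or ``"auto"`` (exact up to
    ``EXACT_MAX_N`` points).  Initial coordinates are N(0, 1e-4) draws seeded
    by ``seed`` (or the explicit ``init``); repeated calls with the same
    inputs are bit-identical on the exact backend.  The exact backend records
    the per-iteration KL trace evaluated against the unexaggerated P.
    """
    if isinstance(X, FeatureMatrix) and X.stage != "standardized":
        raise ValidationError(f"embed expects a standardized FeatureMatrix, got '{X.stage}'")
    if n_iter < 1:
        raise ValidationError("n_iter must be >= 1")
    Xv = _as_values(X)
    n = Xv.shape[0]
    if method == "auto":
        method = "exact" if n <= EXACT_MAX_N else "barnes_hut"

    if method == "exact":
        cond = calibrate_bandwidths(Xv, perplexity)
        rng = np.random.default_rng(seed)
        Y, trace = _embed_exact(
            cond.symmetrized(), n_iter, rng, learning_rate, early_exaggeration, init
        )
        return Embedding3D(
            Y=Y,
            kl_final=float(trace[-1]),
            seed=int(seed),
            perplexity=float(perplexity),
            n_iter=int(n_iter),
            method="exact",
            kl_trace=trace,
            params={
                "learning_rate": learning_rate,
                "early_exaggeration": early_exaggeration,
                "early_exaggeration_iters": max(1, n_iter // 4),
            },
        )
    if method == "barnes_hut":
        from sklearn.manifold import TSNE

        if not perplexity < n:
            raise ValidationError(f"perplexity ({perplexity}) must be < n ({n})")
        tsne = TSNE(
            n_components=3,
            perplexity=perplexity,
            max_iter=max(int(n_iter), 250),
            learning_rate=learning_rate,
            early_exaggeration=early_exaggeration,
            init="random",
            random_state=int(seed) % (2**31),
            method="barnes_hut",
        )
        Y = tsne.fit_transform(Xv)
        return Embedding3D(
            Y=np.asarray(Y, dtype=float),
            kl_final=float(tsne.kl_divergence_),
            seed=int(seed),
            perplexity=float(perplexity),
            n_iter=int(n_iter),
            method="barnes_hut",
            kl_trace=None,
            params={
                "learning_rate": learning_rate,
                "early_exaggeration": early_exaggeration,
                "backend": "sklearn.manifold.TSNE",
            },
        )
    raise ValidationError(f"unknown method '{method}'")
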