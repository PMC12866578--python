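"""Multi-stage deep circular embedding for circadian phase inference.

Given the augmented genes x samples matrix Y (each row an exact cosinor
curve over the pre-sort pseudo-time axis), the model jointly learns

1. a gene-sample association matrix S = HG^T * HS, where HG (2 x M) and
   HS (2 x N) are unit-circle embeddings of genes and samples produced by
   two mirrored shallow networks (deep matrix factorization);
2. a gene-gene correlation matrix G (M x M, row-stochastic) from scaled
   dot-product multi-head self-attention over gene rows;
3. an enhanced representation F of the stacked dual-context matrix
   E = [S^T; G] through a five-layer network with two circular (cos/sin)
   bottlenecks;
4. a two-unit autoencoder over the N sample rows of F whose latent
   coordinates (l1, l2), normalized to the unit circle, yield each
   sample's circadian phase V_theta = atan2(l2, l1) mod 2*pi.

All components are optimized jointly against the loss

    || Y^T - Yhat ||^2  +  w * sum_i sigmoid(P_i * Q_i)

where P_i and Q_i are squared-Gaussian-kernel row sums over pairwise
distances between sample vectors in the original space (columns of Y) and
in the latent space.  The structure term is kept in the printed form even
though each sigmoid is bounded in [0.5, 1); see the methods note for the
discussion of its sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from ._autodiff import Tensor, Adam, concat, atan2, softmax_rows
from .metrics import PhaseVector
from .preprocess import (
    ExpressionMatrix,
    znormalize,
    select_seed_genes,
    rank_genes_by_rhythmicity,
)
from .prior_stage import pca_presort, augment

logger = logging.getLogger(__name__)

__all__ = [
    "DcprConfig",
    "DcprModel",
    "DcprResult",
    "fit_dcpr",
    "extract_phases",
    "loss_terms",
]

_EPS = 1e-12


class TrainingInstabilityError(RuntimeError):
    """Raised when activations become non-finite during training."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite activations at epoch {epoch}")
        self.epoch = epoch


class UndefinedPhaseError(ValueError):
    """Raised when a latent point sits exactly at the origin."""


@dataclass
class DcprConfig:
    """Hyperparameters of the full pipeline.

    Attention/enhancer widths and optimizer settings default to values
    chosen for matrices of a few hundred modeled genes; all are
    overridable and recorded in the run diagnostics.
    """

    # attention
    n_heads: int = 2
    head_dim: int = 16  # d_k
    attn_embed_dim: int = 16  # d_0
    # enhancer
    enhancer_mid: int = 32  # width of H2
    # loss
    delta: Optional[float] = None  # kernel bandwidth; None = median heuristic
    structure_weight: float = 1.0
    # optimizer
    learning_rate: float = 1e-3
    max_epochs: int = 2000
    patience: int = 100
    rel_tol: float = 1e-6
    n_init: int = 2  # random restarts, best final loss wins
    seed: int = 0
    # activations / initialization
    f_activation: str = "tanh"  # encoder f
    g_activation: str = "identity"  # decoder g
    strict_eq5: bool = True  # mixed cos/sin unit-circle normalizer
    ae_svd_init: bool = True  # start the decoder at the rank-2 SVD solution
    # pipeline
    presort_enabled: bool = True
    augment_enabled: bool = True
    augment_period_h: float = 24.0
    augment_abscissa: str = "angle"  # or "uniform"
    auto_top_k: Optional[int] = None
    normalize_after_subset: bool = True
    # ablation switches
    augment_off: bool = False
    multistage_off: bool = False

    def __post_init__(self):
        if self.n_heads < 1 or self.head_dim < 1:
            raise ValueError("n_heads and head_dim must be >= 1")
        if self.delta is not None and self.delta <= 0:
            raise ValueError("delta must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DcprConfig":
        return cls(**d)


def _activation(name: str):
    if name == "tanh":
        return lambda x: x.tanh()
    if name == "identity":
        return lambda x: x
    raise ValueError(f"unknown activation {name!r}")


def _init(rng: np.random.Generator, shape: tuple[int, ...],
          fan_in: int | None = None) -> Tensor:
    """Symmetric random init scaled by 1/sqrt(fan_in) to preserve signal."""
    if fan_in is None:
        fan_in = shape[0] if len(shape) > 1 else shape[0]
    scale = 1.0 / np.sqrt(fan_in)
    return Tensor(rng.normal(0.0, scale, shape), requires_grad=True)


def _unit_circle(h1: Tensor, h2: Tensor, strict: bool) -> tuple[Tensor, Tensor]:
    """Map two raw coordinates onto the unit circle.

    Strict form (as the model defines it): cos of the first unit and sin of
    the second, jointly normalized.  Non-strict form: plain Euclidean
    normalization of (h1, h2).
    """
    if strict:
        c, s = h1.cos(), h2.sin()
    else:
        c, s = h1, h2
    norm = (c * c + s * s + _EPS) ** 0.5
    return c / norm, s / norm


class DcprModel:
    """Parameter container plus forward passes for every stage."""

    def __init__(self, m_genes: int, n_samples: int, config: DcprConfig,
                 rng: np.random.Generator, Y: np.ndarray | None = None):
        self.M, self.N, self.cfg = m_genes, n_samples, config
        c = config
        p: dict[str, Tensor] = {}
        if not c.multistage_off:
            # deep matrix factorization: gene net (input N), sample net (input M)
            p["Wg"] = _init(rng, (2, n_samples), fan_in=n_samples)
            p["bg"] = _init(rng, (2, 1), fan_in=1)
            p["Ws"] = _init(rng, (2, m_genes), fan_in=m_genes)
            p["bs"] = _init(rng, (2, 1), fan_in=1)
            # attention
            p["WQ"] = _init(rng, (n_samples, c.attn_embed_dim), fan_in=n_samples)
            p["WK"] = _init(rng, (n_samples, c.attn_embed_dim), fan_in=n_samples)
            p["WV"] = _init(rng, (n_samples, c.attn_embed_dim), fan_in=n_samples)
            for i in range(c.n_heads):
                d0 = c.attn_embed_dim
                p[f"WQ{i}"] = _init(rng, (d0, c.head_dim), fan_in=d0)
                p[f"WK{i}"] = _init(rng, (d0, c.head_dim), fan_in=d0)
                p[f"WV{i}"] = _init(rng, (d0, c.head_dim), fan_in=d0)
            p["WO"] = _init(rng, (c.n_heads * c.head_dim, m_genes),
                            fan_in=c.n_heads * c.head_dim)
            # enhancer
            p["We1"] = _init(rng, (m_genes, 2), fan_in=m_genes)
            p["be1"] = _init(rng, (1, 2), fan_in=1)
            p["We2"] = _init(rng, (2, c.enhancer_mid), fan_in=2)
            p["be2"] = _init(rng, (1, c.enhancer_mid), fan_in=1)
            p["We3"] = _init(rng, (c.enhancer_mid, 2), fan_in=c.enhancer_mid)
            p["be3"] = _init(rng, (1, 2), fan_in=1)
            p["Weo"] = _init(rng, (2, m_genes), fan_in=2)
            p["beo"] = _init(rng, (1, m_genes), fan_in=1)
        # autoencoder
        p["Wa1"] = _init(rng, (m_genes, 2), fan_in=m_genes)
        p["ba1"] = _init(rng, (1, 2), fan_in=1)
        p["Wa2"] = _init(rng, (2, m_genes), fan_in=2)
        p["ba2"] = _init(rng, (1, m_genes), fan_in=1)
        if config.ae_svd_init and Y is not None:
            # Start the decoder at the rank-2 SVD of the reconstruction
            # target Y^T.  The optimal latent for this decoder is the
            # (unsheared) top-2 PC score circle, which pins down the
            # otherwise arbitrary invertible linear reparameterization of
            # the two latent units and speeds up convergence considerably.
            Yt = Y.T
            mu = Yt.mean(axis=0)
            _, S, Vt = np.linalg.svd(Yt - mu, full_matrices=False)
            p["Wa2"].data = S[:2, None] * Vt[:2]
            p["ba2"].data = mu[None, :]
        self.params = p
        self._f = _activation(c.f_activation)
        self._g = _activation(c.g_activation)

    # -- stage forwards ----------------------------------------------------
    def gene_sample_association(self, Y: Tensor) -> Tensor:
        """S = HG^T * HS via the two mirrored factorization networks."""
        p, c = self.params, self.cfg

        def embed(W, b, X):
            H = W @ X + b  # 2 x items
            h21, h22 = _unit_circle(H[0:1, :], H[1:2, :], c.strict_eq5)
            h3 = atan2(h22, h21)  # polar angle per item
            return concat([h3.cos(), h3.sin()], axis=0)  # 2 x items

        HG = embed(p["Wg"], p["bg"], Y.T)  # 2 x M
        HS = embed(p["Ws"], p["bs"], Y)  # 2 x N
        return HG.T @ HS  # M x N

    def gene_gene_correlation(self, Y: Tensor) -> Tensor:
        """Row-stochastic gene-gene matrix from multi-head self-attention."""
        p, c = self.params, self.cfg
        Q, K, V = Y @ p["WQ"], Y @ p["WK"], Y @ p["WV"]  # M x d0
        heads = []
        scale = 1.0 / np.sqrt(c.head_dim)
        for i in range(c.n_heads):
            Qi, Ki, Vi = Q @ p[f"WQ{i}"], K @ p[f"WK{i}"], V @ p[f"WV{i}"]
            attn = softmax_rows((Qi @ Ki.T) * scale)
            heads.append(attn @ Vi)  # M x d_k
        multi = concat(heads, axis=1) @ p["WO"]  # M x M
        return softmax_rows(multi)

    def enhance(self, S: Tensor, G: Tensor) -> Tensor:
        """Dual-context enhancement of E = [S^T; G] -> F ((N+M) x M)."""
        p, c = self.params, self.cfg
        E = concat([S.T, G], axis=0)  # (N+M) x M
        H1 = E @ p["We1"] + p["be1"]
        c1 = concat([H1[:, 0:1].cos(), H1[:, 1:2].sin()], axis=1)
        H2 = c1 @ p["We2"] + p["be2"]
        H3 = H2 @ p["We3"] + p["be3"]
        c3 = concat([H3[:, 0:1].cos(), H3[:, 1:2].sin()], axis=1)
        return c3 @ p["Weo"] + p["beo"]

    def autoencode(self, F_samples: Tensor) -> tuple[Tensor, Tensor]:
        """Two-unit autoencoder: latent (N x 2) and reconstruction (N x M)."""
        p = self.params
        latent = self._f(F_samples @ p["Wa1"] + p["ba1"])
        Y_hat = self._g(latent @ p["Wa2"] + p["ba2"])
        return latent, Y_hat

    def forward(self, Y: Tensor) -> tuple[Tensor, Tensor]:
        """Full pass: returns (latent N x 2, reconstruction N x M)."""
        if self.cfg.multistage_off:
            return self.autoencode(Y.T)
        S = self.gene_sample_association(Y)
        G = self.gene_gene_correlation(Y)
        F = self.enhance(S, G)
        return self.autoencode(F[: self.N, :])

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())


def median_heuristic_bandwidth(A: np.ndarray) -> float:
    """Median of pairwise squared Euclidean distances between columns."""
    sq = (A * A).sum(axis=0)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (A.T @ A)
    iu = np.triu_indices(A.shape[1], k=1)
    med = float(np.median(d2[iu])) if len(iu[0]) else 1.0
    return med if med > 0 else 1.0


def loss_terms(
    Y_target: Tensor,
    Y_hat: Tensor,
    P: np.ndarray,
    latent: Tensor,
    delta: float,
    structure_weight: float = 1.0,
) -> tuple[Tensor, Tensor, Tensor]:
    """Reconstruction + kernel-structure loss.

    ``P`` holds the data-space kernel statistics P_i (constants); Q_i is the
    mirrored statistic over latent points, differentiable.  The structure
    term sum_i sigmoid(P_i * Q_i) is bounded in [N/2, N].
    """
    diff = Y_target - Y_hat
    recon = (diff * diff).sum()
    r = (latent * latent).sum(axis=1, keepdims=True)  # N x 1
    d2 = r + r.T - 2.0 * (latent @ latent.T)
    Q = (d2 * (-2.0 / delta)).exp().sum(axis=1)  # (e^{-d2/delta})^2 row sums
    pq = Tensor(P) * Q
    structure = (1.0 / (1.0 + (-pq).exp())).sum()
    total = recon + structure_weight * structure
    return total, recon, structure


def extract_phases(l1, l2, sample_ids=None) -> PhaseVector:
    """Unit-circle phases from latent coordinates: atan2(l2, l1) mod 2*pi."""
    l1 = np.asarray(l1, dtype=float).ravel()
    l2 = np.asarray(l2, dtype=float).ravel()
    norm = np.hypot(l1, l2)
    if np.any(norm == 0):
        bad = int(np.flatnonzero(norm == 0)[0])
        raise UndefinedPhaseError(f"latent point {bad} is at the origin")
    ang = np.mod(np.arctan2(l2 / norm, l1 / norm), 2.0 * np.pi)
    ang[ang >= 2.0 * np.pi] = 0.0
    return PhaseVector(ang, sample_ids)


@dataclass
class TrainingTrace:
    loss: list[float] = field(default_factory=list)
    recon: list[float] = field(default_factory=list)
    structure: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    converged: bool = False


def _train_once(
    Y: np.ndarray, config: DcprConfig, rng: np.random.Generator
) -> tuple[float, np.ndarray, TrainingTrace]:
    """One optimization run; returns (best loss, best latent, trace)."""
    M, N = Y.shape
    model = DcprModel(M, N, config, rng, Y=Y)
    Yt = Tensor(Y)
    target = Tensor(Y.T)
    delta = (
        config.delta
        if config.delta is not None
        else median_heuristic_bandwidth(Y)
    )
    sq = (Y * Y).sum(axis=0)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (Y.T @ Y)
    P = np.exp(-2.0 * np.maximum(d2, 0.0) / delta).sum(axis=1)

    opt = Adam(model.parameters(), lr=config.learning_rate)
    trace = TrainingTrace()
    best_loss, best_latent = np.inf, None
    stall = 0
    for epoch in range(config.max_epochs):
        latent, Y_hat = model.forward(Yt)
        total, recon, structure = loss_terms(
            target, Y_hat, P, latent, delta, config.structure_weight
        )
        val = float(total.data)
        if not np.isfinite(val):
            raise TrainingInstabilityError(epoch)
        trace.loss.append(val)
        trace.recon.append(float(recon.data))
        trace.structure.append(float(structure.data))
        if val < best_loss - config.rel_tol * max(abs(best_loss), 1.0):
            stall = 0
        else:
            stall += 1
        if val < best_loss:
            best_loss = val
            best_latent = latent.data.copy()
        if stall >= config.patience:
            trace.converged = True
            break
        opt.zero_grad()
        total.backward()
        opt.step()
    trace.stopped_epoch = len(trace.loss)
    return best_loss, best_latent, trace


@dataclass
class DcprResult:
    """Phases plus everything needed to audit the run."""

    phases: PhaseVector  # in the input matrix's sample order
    config: DcprConfig
    seed: int
    traces: list[TrainingTrace]
    chosen_init: int
    best_loss: float
    presort_angles: np.ndarray | None = None
    modeled_gene_ids: list[str] | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return self.traces[self.chosen_init].converged


def fit_dcpr(
    matrix: ExpressionMatrix,
    config: DcprConfig | None = None,
    seed_genes=None,
) -> DcprResult:
    """Run the full pipeline: normalize, pre-sort, augment, train, extract.

    Returns per-sample phases attached to the input sample ids (original
    column order), the training traces of every random restart, and the
    resolved configuration.
    """
    config = config or DcprConfig()
    if matrix.n_samples < 4:
        raise ValueError("phase inference needs at least 4 samples")
    warnings_list: list[str] = []

    work = matrix
    if seed_genes is not None:
        work = select_seed_genes(work, seed_genes)
        if config.normalize_after_subset:
            work = znormalize(work)
        else:
            work = znormalize(matrix).subset_genes(work.gene_ids)
    else:
        work = znormalize(work)

    if config.presort_enabled:
        presorted = pca_presort(work)
    else:
        presorted = _identity_presort(work)

    if (
        seed_genes is None
        and config.auto_top_k is not None
        and config.auto_top_k < presorted.data.shape[0]
    ):
        sub = ExpressionMatrix(presorted.data, presorted.true_times)
        ranking = rank_genes_by_rhythmicity(
            sub, presorted.pseudo_times_h, top_k=config.auto_top_k
        )
        sub = sub.subset_genes(ranking.selected_ids)
        # re-embed on the cleaned gene set: the circle is far less noisy
        presorted = (
            pca_presort(sub) if config.presort_enabled else _identity_presort(sub)
        )

    augment_on = config.augment_enabled and not config.augment_off
    if augment_on:
        augmented = augment(
            presorted,
            period_h=config.augment_period_h,
            abscissa=config.augment_abscissa,
        )
        Y = augmented.data.to_numpy(dtype=float)
    else:
        Y = presorted.data.to_numpy(dtype=float)

    rng = np.random.default_rng(config.seed)
    traces: list[TrainingTrace] = []
    best = (np.inf, None, -1)
    for k in range(max(config.n_init, 1)):
        sub_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        loss_k, latent_k, trace_k = _train_once(Y, config, sub_rng)
        traces.append(trace_k)
        if loss_k < best[0]:
            best = (loss_k, latent_k, k)
    best_loss, best_latent, chosen = best
    if not traces[chosen].converged:
        warnings_list.append(
            "optimizer hit max_epochs without meeting the early-stop "
            "criterion; returning best-loss phases"
        )

    sorted_ids = list(presorted.data.columns)
    phases_sorted = extract_phases(
        best_latent[:, 0], best_latent[:, 1], sorted_ids
    )
    # map back to the input column order
    pos = {s: i for i, s in enumerate(sorted_ids)}
    orig_ids = matrix.sample_ids
    phases = np.array(
        [phases_sorted.phases_rad[pos[s]] for s in orig_ids]
    )
    return DcprResult(
        phases=PhaseVector(phases, orig_ids),
        config=config,
        seed=config.seed,
        traces=traces,
        chosen_init=chosen,
        best_loss=best_loss,
        presort_angles=presorted.presort_angles,
        modeled_gene_ids=list(presorted.data.index),
        warnings=warnings_list,
    )


def _identity_presort(matrix: ExpressionMatrix):
    """Pass-through stand-in when pre-sorting is disabled."""
    from .prior_stage import PreSortedMatrix

    n = matrix.n_samples
    return PreSortedMatrix(
        data=matrix.data,
        sort_order=np.arange(n),
        presort_angles=np.arange(n) * 2.0 * np.pi / n,
        pc_scores=np.zeros((n, 2)),
        true_times=matrix.true_times,
    )
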