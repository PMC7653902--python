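"""Marginalized denoising of the heterogeneous drug-target network.

The fused target kernel, fused drug kernel and interaction matrix are
stacked into one square adjacency

    M = [[KFJT, Y'],
         [Y,    KFJD]]

of size (m + n) x (m + n) with targets first.  The model reconstructs M from
copies corrupted by independently zeroing every entry with probability
``noise``: with local weights L = U U' (one-hop paths) and global weights
G = V V' (two-hop paths through the corrupted copy), the objective is

    0.5 * E || M - L Mc - Mc G Mc' - b 1' ||_F^2
        + (lambda1 / 2) ||U||_F^2 + (lambda2 / 2) ||V||_F^2,

where Mc is the corrupted copy and the expectation over the corruption is
evaluated in closed form rather than by sampling.  The closed forms for the
pair, triple and quartic corrupted terms below are exact expectations under
independent entry-wise zeroing (validated against exhaustive enumeration in
the test suite); they follow from the fact that every raw moment of a 0/1
Bernoulli(q) corruption indicator equals q, so a product of matrix entries
contributes q to the power of the number of *distinct* entries involved.

Predictions use the uncorrupted network: M* = U U' M + M V V' M' + b, and
the drug-target score of (drug i, target j) is the average of the two
off-diagonal blocks of M*.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import minimize

from .data_io import ValidationError

__all__ = [
    "HeteroNetwork",
    "CorruptedSample",
    "MDMConfig",
    "MDMModel",
    "OptimizationError",
    "build_network",
    "corrupt",
    "exp_pair_term",
    "exp_pair_term_outer",
    "exp_triple_term",
    "exp_quartic_trace",
    "marginalized_loss",
    "loss_gradient",
    "fit",
    "reconstruct",
    "dti_scores",
    "default_latent_dim",
    "save_model",
    "load_model",
]


class OptimizationError(RuntimeError):
    """Raised when the optimizer encounters a non-finite objective."""


@dataclass
class HeteroNetwork:
    """The (m+n) x (m+n) block network; targets at 0..m-1, drugs at m..m+n-1."""

    M: np.ndarray
    m: int  # number of targets
    n: int  # number of drugs

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=float)
        d = self.m + self.n
        if self.M.shape != (d, d):
            raise ValidationError(
                f"network shape {self.M.shape} inconsistent with m={self.m}, n={self.n}"
            )
        if not np.allclose(self.M, self.M.T, atol=1e-10):
            raise ValidationError("heterogeneous network must be symmetric")

    @property
    def size(self) -> int:
        return self.m + self.n


@dataclass(frozen=True)
class CorruptedSample:
    M_tilde: np.ndarray
    p: float
    seed: int


@dataclass(frozen=True)
class MDMConfig:
    """Model and optimizer settings.

    ``noise`` is the probability of zeroing an entry (default 0.65, the
    value at which the method peaks on all four gold-standard datasets);
    ``q = 1 - noise`` is the residual probability used by the closed-form
    expectations.  ``latent_dim`` is the rank k of the local and global
    weight factors.
    """

    noise: float = 0.65
    latent_dim: int = 20
    lambda1: float = 0.01
    lambda2: float = 0.01
    max_iters: int = 200
    grad_tol: float = 1e-5
    memory: int = 10
    seed: int = 0

    @property
    def q(self) -> float:
        return 1.0 - self.noise

    def validate(self, size: int | None = None) -> None:
        if not 0.0 < self.noise < 1.0:
            raise ValidationError("noise must lie strictly in (0, 1)")
        if self.latent_dim < 1:
            raise ValidationError("latent_dim must be >= 1")
        if size is not None and self.latent_dim > size:
            raise ValidationError("latent_dim cannot exceed the network size")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValidationError("regularization coefficients must be >= 0")


def default_latent_dim(n_drugs: int) -> int:
    """Latent dimension scaled with the number of drugs, clamped to [20, 100]."""
    return int(min(100, max(20, round(n_drugs / 4))))


@dataclass
class MDMModel:
    U: np.ndarray
    V: np.ndarray
    b: np.ndarray
    config: MDMConfig = field(default_factory=MDMConfig)
    n_iterations: int = 0
    converged: bool = False
    initial_loss: float = np.nan
    final_loss: float = np.nan

    def __post_init__(self):
        self.U = np.asarray(self.U, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.U.shape != self.V.shape or self.U.shape[0] != self.b.shape[0]:
            raise ValidationError("inconsistent model factor shapes")

    @property
    def local_weights(self) -> np.ndarray:
        """L = U U', the one-hop reconstruction weights."""
        return self.U @ self.U.T

    @property
    def global_weights(self) -> np.ndarray:
        """G = V V', the two-hop reconstruction weights."""
        return self.V @ self.V.T


def build_network(KFJT, KFJD, Y) -> HeteroNetwork:
    """Assemble the block network M = [[KFJT, Y'], [Y, KFJD]]."""
    KFJT = np.asarray(getattr(KFJT, "values", KFJT), dtype=float)
    KFJD = np.asarray(getattr(KFJD, "values", KFJD), dtype=float)
    Y = np.asarray(Y, dtype=float)
    m = KFJT.shape[0]
    n = KFJD.shape[0]
    if KFJT.shape != (m, m) or KFJD.shape != (n, n) or Y.shape != (n, m):
        raise ValidationError(
            f"block dimension mismatch: KFJT {KFJT.shape}, KFJD {KFJD.shape}, "
            f"Y {Y.shape}"
        )
    M = np.block([[KFJT, Y.T], [Y, KFJD]])
    return HeteroNetwork(M, m=m, n=n)


def corrupt(net: HeteroNetwork, p: float, seed: int) -> CorruptedSample:
    """Zero every entry of the network independently with probability p."""
    if not 0.0 < p < 1.0:
        raise ValidationError("corruption probability must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    keep = rng.random(net.M.shape) >= p
    return CorruptedSample(net.M * keep, p=p, seed=seed)


# ---------------------------------------------------------------------------
# Closed-form expectations over independent entry-wise corruption.
#
# Mc = D o M with D_ij iid Bernoulli(q); E[prod of entries] = (prod of M
# entries) * q^(number of distinct entries).  Central moments of Bernoulli(q)
# used below: v = q(1-q), k3 = q(1-q)(1-2q), mu4 = q(1-q)(1 - 3q + 3q^2).
# ---------------------------------------------------------------------------

def _check_q(q: float) -> None:
    if not 0.0 <= q <= 1.0:
        raise ValidationError("q must lie in [0, 1]")


def exp_pair_term(M: np.ndarray, C: np.ndarray, q: float) -> np.ndarray:
    """Exact E[Mc' C Mc] = q^2 M'CM + q(1-q) diag((M o M)' diag(C))."""
    M = np.asarray(M, dtype=float)
    C = np.asarray(C, dtype=float)
    _check_q(q)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValidationError("C must be square")
    if C.shape[0] != M.shape[0]:
        raise ValidationError("C dimension must match the rows of M")
    v = q * (1.0 - q)
    return q * q * (M.T @ C @ M) + np.diag((M * M).T @ np.diag(C)) * v


def exp_pair_term_outer(M: np.ndarray, C: np.ndarray, q: float) -> np.ndarray:
    """Exact E[Mc C Mc'] = q^2 MCM' + q(1-q) diag((M o M) diag(C))."""
    M = np.asarray(M, dtype=float)
    C = np.asarray(C, dtype=float)
    _check_q(q)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValidationError("C must be square")
    if C.shape[0] != M.shape[1]:
        raise ValidationError("C dimension must match the columns of M")
    v = q * (1.0 - q)
    return q * q * (M @ C @ M.T) + np.diag((M * M) @ np.diag(C)) * v


def exp_triple_term(M: np.ndarray, C: np.ndarray, q: float) -> np.ndarray:
    """Exact E[Mc C Mc' Mc'] for square M.

    The three corrupted factors contribute q^3 when the entries they touch
    are all distinct; coincidences between any two (or all three) entries
    collapse Bernoulli powers and produce the lower-order corrections.  Any
    two pairwise coincidences force the third, so the inclusion-exclusion
    stops at the all-equal term with coefficient q(1-q)(1-2q).
    """
    M = np.asarray(M, dtype=float)
    C = np.asarray(C, dtype=float)
    _check_q(q)
    d = M.shape[0]
    if M.shape != (d, d) or C.shape != (d, d):
        raise ValidationError("triple term requires square M and C of equal size")
    c = np.diag(C).copy()
    dM = np.diag(M).copy()
    M2 = M * M
    w = M2 @ c                      # w_i = sum_a M_ia^2 C_aa
    u = (C * M).sum(axis=1)         # u_j = sum_b C_jb M_jb
    v = q * (1.0 - q)
    k3 = v * (1.0 - 2.0 * q)
    out = (q ** 3) * (M @ C @ M.T @ M.T)
    out += (q * q * (1.0 - q)) * (
        w[:, None] * M.T            # diag(w) M'
        + np.diag(M2 @ u)
        + (M @ C) * (dM * dM)[None, :]
    )
    out += k3 * np.diag(dM ** 3 * c)
    return out


def exp_quartic_trace(M: np.ndarray, C: np.ndarray, q: float) -> float:
    """Exact E[tr(Mc C Mc' Mc C Mc')] for symmetric C.

    Decomposes the trace over row pairs: distinct rows of the corruption
    mask are independent, leaving per-row second-moment matrices
    W_i = q^2 m_i m_i' + q(1-q) diag(m_i o m_i); the same-row contribution
    is the exact fourth moment of the quadratic form delta' H delta with
    H = diag(m_i) C diag(m_i) and iid Bernoulli(q) entries delta.
    """
    M = np.asarray(M, dtype=float)
    C = np.asarray(C, dtype=float)
    _check_q(q)
    if C.ndim != 2 or C.shape[0] != C.shape[1] or C.shape[0] != M.shape[1]:
        raise ValidationError("C must be square and match the columns of M")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValidationError("quartic trace requires symmetric C")
    v = q * (1.0 - q)
    k3 = v * (1.0 - 2.0 * q)
    mu4 = v * (1.0 - 3.0 * q + 3.0 * q * q)
    c = np.diag(C).copy()
    M2 = M * M
    MC = M @ C
    # cross-row part via the summed second-moment matrix
    S_W = q * q * (M.T @ M) + np.diag(M2.sum(axis=0)) * v
    cross_all = float(np.sum(S_W * (C @ S_W @ C)))
    # per-row statistics of H_i = diag(m_i) C diag(m_i)
    S_vec = np.einsum("ij,ij->i", MC, M)          # m' C m
    beta = M2 @ c                                 # tr(H)
    hh = np.einsum("ij,ij,ij->i", M2, MC, MC)     # sum_a m_a^2 (Cm)_a^2
    phi = np.einsum("ij,ij,j->i", M ** 3, MC, c)  # sum_a m_a^3 C_aa (Cm)_a
    fro = np.einsum("ij,ij->i", M2 @ (C * C), M2)  # ||H||_F^2
    psi = (M2 * M2) @ (c * c)                     # sum_a H_aa^2
    # subtract the i == j cross-row terms, add the exact same-row moments
    same_row = np.sum(
        2.0 * q * q * v * (S_vec * beta + hh)
        + 4.0 * q * k3 * phi
        + v * v * (beta * beta + fro)
        + (mu4 - 3.0 * v * v) * psi
    )
    return cross_all + float(same_row)


def _loss_terms(U, V, b, M, q, lambda1, lambda2):
    """Shared quantities for the loss and its gradient."""
    d = M.shape[0]
    L = U @ U.T
    G = V @ V.T
    v = q * (1.0 - q)
    g = np.diag(G).copy()
    M2 = M * M
    r = M2.sum(axis=1)
    m_row = M.sum(axis=1)  # M 1
    P_G = q * q * (M @ G @ M.T) + np.diag(M2 @ g) * v
    T_G = exp_triple_term(M, G, q)
    return dict(d=d, L=L, G=G, v=v, g=g, M2=M2, r=r, m_row=m_row,
                P_G=P_G, T_G=T_G)


def marginalized_loss(model: MDMModel, net: HeteroNetwork,
                      cfg: MDMConfig) -> float:
    """Closed-form expected denoising loss (see module docstring).

    Every corrupted term is replaced by its exact expectation: the single
    factor by q M, pairs by :func:`exp_pair_term`, the local-global cross
    term by :func:`exp_triple_term` and the squared global term by
    :func:`exp_quartic_trace`.
    """
    M = net.M
    U, V, b = model.U, model.V, model.b
    if U.shape[0] != M.shape[0] or b.shape[0] != M.shape[0]:
        raise ValidationError("model factors do not match the network size")
    q = cfg.q
    t = _loss_terms(U, V, b, M, q, cfg.lambda1, cfg.lambda2)
    L, P_G, T_G = t["L"], t["P_G"], t["T_G"]
    d, v, r, m_row = t["d"], t["v"], t["r"], t["m_row"]

    LM = L @ M
    e2 = float(np.sum(M * M))
    e2 += q * q * float(np.sum(LM * LM)) + v * float(r @ np.einsum("ij,ij->i", L, L))
    e2 += exp_quartic_trace(M, t["G"], q)
    e2 += d * float(b @ b)
    e2 -= 2.0 * q * float(np.sum(M * LM))
    e2 -= 2.0 * float(np.sum(M * P_G))
    e2 -= 2.0 * float(b @ m_row)
    e2 += 2.0 * float(np.sum(L * T_G.T))
    e2 += 2.0 * q * float(b @ (L @ m_row))
    e2 += 2.0 * float(b @ P_G.sum(axis=1))
    loss = 0.5 * e2 + 0.5 * cfg.lambda1 * float(np.sum(U * U)) \
        + 0.5 * cfg.lambda2 * float(np.sum(V * V))
    return loss


def loss_gradient(model: MDMModel, net: HeteroNetwork,
                  cfg: MDMConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradients of :func:`marginalized_loss` w.r.t. U, V and b.

    Derived by matrix differentials through L = U U' and G = V V'; the test
    suite holds these to central finite differences of the loss.
    """
    M = net.M
    U, V, b = model.U, model.V, model.b
    q = cfg.q
    t = _loss_terms(U, V, b, M, q, cfg.lambda1, cfg.lambda2)
    L, G, P_G, T_G = t["L"], t["G"], t["P_G"], t["T_G"]
    d, v, g, M2, r, m_row = t["d"], t["v"], t["g"], t["M2"], t["r"], t["m_row"]
    k3 = v * (1.0 - 2.0 * q)
    mu4 = v * (1.0 - 3.0 * q + 3.0 * q * q)
    dM = np.diag(M).copy()

    # --- U ---------------------------------------------------------------
    A = M @ M.T
    LA = L @ A
    RL = r[:, None] * L  # diag(r) L
    sym_L = (
        q * q * (LA + LA.T)
        + v * (RL + RL.T)
        - 2.0 * q * A
        + (T_G + T_G.T)
        + q * (np.outer(m_row, b) + np.outer(b, m_row))
    )
    grad_U = sym_L @ U + cfg.lambda1 * U

    # --- V ---------------------------------------------------------------
    MtM = M.T @ M
    MC = M @ G
    c_diagL = M2.T @ np.diag(L)            # sum_i L_ii M_ij^2
    t_colsum = (L * M).sum(axis=0)         # sum_i L_ik M_ik
    beta = M2 @ g
    S_vec = np.einsum("ij,ij->i", MC, M)
    M3 = M2 * M
    s4 = (M2 * M2).sum(axis=0)
    S_W = q * q * MtM + np.diag(M2.sum(axis=0)) * v

    DG = -2.0 * q * q * (M.T @ M @ M) - 2.0 * v * np.diag(M2.T @ dM)
    DG += 2.0 * q * q * np.outer(M.T @ b, M.sum(axis=0)) \
        + 2.0 * v * np.diag(M2.T @ b)
    DG += 2.0 * (
        (q ** 3) * (M.T @ L @ M @ M)
        + q * q * (1.0 - q) * (np.diag(M2.T @ t_colsum)
                               + c_diagL[:, None] * M
                               + M.T @ L * (dM * dM)[None, :])
        + k3 * np.diag(np.diag(L) * dM ** 3)
    )
    DG += 2.0 * (S_W @ G @ S_W)
    DG += 2.0 * q * q * v * (M.T @ (beta[:, None] * M) + np.diag(M2.T @ S_vec))
    DG += 4.0 * q * q * v * ((M2 * MC).T @ M)
    DG += 4.0 * q * k3 * (np.diag((M3 * MC).sum(axis=0)) + g[:, None] * (M3.T @ M))
    DG += 2.0 * v * v * np.diag(M2.T @ beta)
    DG += 2.0 * v * v * G * (M2.T @ M2)
    DG += 2.0 * (mu4 - 3.0 * v * v) * np.diag(g * s4)
    grad_V = 0.5 * (DG + DG.T) @ V + cfg.lambda2 * V

    # --- b ---------------------------------------------------------------
    grad_b = d * b - m_row + q * (L @ m_row) + P_G.sum(axis=1)
    return grad_U, grad_V, grad_b


def fit(net: HeteroNetwork, cfg: MDMConfig) -> MDMModel:
    """Fit U, V and b by L-BFGS on the marginalized loss.

    Factors are initialized from seeded Gaussian noise with scale
    1/sqrt(latent_dim) and b starts at zero; the three parameter blocks are
    optimized jointly as one flattened vector.  Deterministic given the
    configuration seed.
    """
    cfg.validate(net.size)
    d = net.size
    k = cfg.latent_dim
    rng = np.random.default_rng(cfg.seed)
    scale = 1.0 / np.sqrt(k)
    U0 = rng.normal(0.0, scale, (d, k))
    V0 = rng.normal(0.0, scale, (d, k))
    b0 = np.zeros(d)

    n_eval = [0]

    def unpack(x):
        U = x[: d * k].reshape(d, k)
        V = x[d * k: 2 * d * k].reshape(d, k)
        b = x[2 * d * k:]
        return MDMModel(U, V, b, cfg)

    def objective(x):
        n_eval[0] += 1
        m = unpack(x)
        val = marginalized_loss(m, net, cfg)
        if not np.isfinite(val):
            raise OptimizationError(
                f"non-finite loss at objective evaluation {n_eval[0]}"
            )
        gU, gV, gb = loss_gradient(m, net, cfg)
        return val, np.concatenate([gU.ravel(), gV.ravel(), gb])

    x0 = np.concatenate([U0.ravel(), V0.ravel(), b0])
    init_loss = marginalized_loss(MDMModel(U0, V0, b0, cfg), net, cfg)
    res = minimize(
        objective, x0, jac=True, method="L-BFGS-B",
        options=dict(maxiter=cfg.max_iters, maxcor=cfg.memory,
                     gtol=cfg.grad_tol, ftol=1e-12),
    )
    model = unpack(res.x)
    model.n_iterations = int(res.nit)
    model.converged = bool(res.success)
    model.initial_loss = float(init_loss)
    model.final_loss = float(res.fun)
    if model.final_loss > init_loss:  # L-BFGS only accepts decreasing iterates
        model = MDMModel(U0, V0, b0, cfg, n_iterations=0, converged=False,
                         initial_loss=float(init_loss),
                         final_loss=float(init_loss))
    return model


def reconstruct(model: MDMModel, net: HeteroNetwork) -> np.ndarray:
    """Reconstruction scores M* = U U' M + M V V' M' + b (row offset)."""
    M = net.M
    if model.U.shape[0] != M.shape[0]:
        raise ValidationError("model does not match the network size")
    return (model.U @ (model.U.T @ M)
            + (M @ model.V) @ (model.V.T @ M.T)
            + model.b[:, None])


def dti_scores(M_star: np.ndarray, net: HeteroNetwork) -> np.ndarray:
    """Extract the n x m drug-target score block (averaging the two copies)."""
    M_star = np.asarray(M_star, dtype=float)
    if M_star.shape != net.M.shape:
        raise ValidationError("prediction matrix shape mismatch")
    m = net.m
    return 0.5 * (M_star[m:, :m] + M_star[:m, m:].T)


def save_model(model: MDMModel, path, entity_ids=None) -> None:
    """Serialize a fitted model (factors, bias, config, id order) to one file."""
    meta = dict(config=asdict(model.config),
                n_iterations=model.n_iterations,
                converged=model.converged,
                initial_loss=model.initial_loss,
                final_loss=model.final_loss,
                entity_ids=list(entity_ids) if entity_ids is not None else None)
    with open(path, "wb") as fh:
        np.savez(fh, U=model.U, V=model.V, b=model.b,
                 meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8))


def load_model(path) -> tuple[MDMModel, list | None]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        cfg = MDMConfig(**meta["config"])
        model = MDMModel(data["U"], data["V"], data["b"], cfg,
                         n_iterations=meta["n_iterations"],
                         converged=meta["converged"],
                         initial_loss=meta["initial_loss"],
                         final_loss=meta["final_loss"])
    return model, meta["entity_ids"]
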