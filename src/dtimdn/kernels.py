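"""Similarity kernels over interaction profiles and their nonlinear fusion.

Three kernels are built per entity axis (drugs or targets): the supplied
chemical/sequence similarity, a Gaussian interaction-profile (GIP) kernel,
and an association-index kernel (Jaccard for binary interaction data,
Pearson correlation for continuous affinities).  The triple is merged by an
SNF-style cross-diffusion: each kernel is row-normalized with half its mass
on the diagonal, restricted to k nearest neighbors, and iteratively diffused
through the average of the other two before the three are averaged into the
final kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import DTIDataset, ValidationError

__all__ = [
    "KernelMatrix",
    "GipBandwidth",
    "FusionConfig",
    "gip_kernel",
    "jaccard_kernel",
    "pcc_kernel",
    "normalize_kernel",
    "local_kernel",
    "fuse",
    "build_final_kernels",
    "default_k_nn",
]


@dataclass
class KernelMatrix:
    """A square symmetric nonnegative similarity matrix over one entity set."""

    values: np.ndarray
    entity_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.entity_ids = list(self.entity_ids)
        n = len(self.entity_ids)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"kernel shape {self.values.shape} does not match {n} ids"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("kernel entries must be finite")
        if np.min(self.values) < 0:
            raise ValidationError("kernel entries must be nonnegative")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValidationError("kernel must be symmetric within 1e-10")

    @property
    def n(self) -> int:
        return len(self.entity_ids)


@dataclass(frozen=True)
class GipBandwidth:
    gamma: float

    def __post_init__(self):
        if not self.gamma > 0:
            raise ValidationError("GIP bandwidth must be positive")


@dataclass(frozen=True)
class FusionConfig:
    """Neighborhood size (self included) and diffusion iteration count."""

    k_nn: int = 0  # 0 means "derive from entity count" in build_final_kernels
    n_iters: int = 2

    def validate(self, n: int) -> None:
        if not 1 <= self.k_nn <= n:
            raise ValidationError(f"k_nn={self.k_nn} out of range [1, {n}]")
        if self.n_iters < 0:
            raise ValidationError("n_iters must be nonnegative")


def default_k_nn(n: int) -> int:
    """Default neighborhood size: about a third of the entities, at least 3."""
    return min(n, max(3, round(n / 3)))


def gip_kernel(profiles: np.ndarray,
               entity_ids=None) -> tuple[KernelMatrix, GipBandwidth]:
    """Gaussian interaction-profile kernel.

    The bandwidth gamma is the reciprocal of the mean squared profile norm,
    and K[i, j] = exp(-gamma * ||y_i - y_j||^2).  An all-zero profile matrix
    (every entity without interactions, as happens for held-out entities in
    new-drug/new-target validation) has an undefined bandwidth; gamma then
    falls back to 1 with a warning and the kernel is all ones.
    """
    P = np.asarray(profiles, dtype=float)
    if P.ndim != 2 or P.shape[0] < 1:
        raise ValidationError("profiles must be a 2-D matrix with >= 1 row")
    if entity_ids is None:
        entity_ids = list(range(P.shape[0]))
    sq_norms = np.einsum("ij,ij->i", P, P)
    mean_sq = float(sq_norms.mean())
    if mean_sq == 0.0:
        warnings.warn(
            "all-zero profile matrix: GIP bandwidth undefined, using gamma=1",
            stacklevel=2,
        )
        gamma = 1.0
    else:
        gamma = 1.0 / mean_sq
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * (P @ P.T)
    np.maximum(d2, 0.0, out=d2)
    K = np.exp(-gamma * d2)
    K = 0.5 * (K + K.T)
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(K, entity_ids), GipBandwidth(gamma)


def jaccard_kernel(profiles: np.ndarray, entity_ids=None) -> KernelMatrix:
    """Jaccard association-index kernel on binary interaction profiles.

    K[i, j] = |shared partners| / |union of partners|.  Two entities without
    any partner (0/0) get off-diagonal similarity 0; the diagonal is 1 by
    definition.
    """
    P = np.asarray(profiles, dtype=float)
    if not np.all(np.isin(P, (0.0, 1.0))):
        raise ValidationError("jaccard_kernel requires binary profiles")
    if entity_ids is None:
        entity_ids = list(range(P.shape[0]))
    inter = P @ P.T  # c11
    row = P.sum(axis=1)
    union = row[:, None] + row[None, :] - inter  # c01 + c10 + c11
    with np.errstate(invalid="ignore", divide="ignore"):
        K = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(0.5 * (K + K.T), entity_ids)


def pcc_kernel(profiles: np.ndarray, entity_ids=None) -> KernelMatrix:
    """Pearson-correlation kernel for continuous affinity profiles.

    Negative correlations are clipped to 0 (downstream fusion requires a
    nonnegative kernel) and zero-variance profiles contribute 0 off-diagonal.
    NaN cells mark missing measurements and are excluded pairwise: each pair
    is correlated over the features observed for both entities.
    """
    P = np.asarray(profiles, dtype=float)
    if P.ndim != 2 or P.shape[1] < 2:
        raise ValidationError("pcc_kernel needs at least 2 profile features")
    if entity_ids is None:
        entity_ids = list(range(P.shape[0]))
    n = P.shape[0]
    if not np.isnan(P).any():
        Pc = P - P.mean(axis=1, keepdims=True)
        sd = np.sqrt(np.einsum("ij,ij->i", Pc, Pc))
        denom = sd[:, None] * sd[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            K = np.where(denom > 0, (Pc @ Pc.T) / np.where(denom > 0, denom, 1.0), 0.0)
    else:
        K = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                mask = ~np.isnan(P[i]) & ~np.isnan(P[j])
                if mask.sum() < 2:
                    continue
                a, b = P[i, mask], P[j, mask]
                a = a - a.mean()
                b = b - b.mean()
                den = np.sqrt((a @ a) * (b @ b))
                if den > 0:
                    K[i, j] = K[j, i] = (a @ b) / den
    K = np.clip(K, 0.0, 1.0)
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(K, entity_ids)


def normalize_kernel(K: np.ndarray) -> np.ndarray:
    """Row-normalize a kernel with half the mass on the diagonal.

    P[i, j] = K[i, j] / (2 * sum_{k != i} K[i, k]) off the diagonal and
    P[i, i] = 1/2, so every row sums to 1.  A row whose off-diagonal entries
    are all zero has no neighbors to receive the off-diagonal half; its mass
    is spread uniformly as 1/(2(n-1)) with a warning.
    """
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    if K.ndim != 2 or K.shape[1] != n:
        raise ValidationError("kernel must be square")
    if np.min(K) < 0:
        raise ValidationError("kernel must be nonnegative")
    if n == 1:
        return np.array([[0.5]])
    off = K - np.diag(np.diag(K))
    rowsum = off.sum(axis=1)
    dead = rowsum == 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} kernel row(s) with zero off-diagonal mass; "
            "spreading uniformly",
            stacklevel=2,
        )
    P = np.empty_like(off)
    safe = np.where(dead, 1.0, rowsum)
    P[:] = off / (2.0 * safe[:, None])
    if dead.any():
        P[dead, :] = 1.0 / (2.0 * (n - 1))
    np.fill_diagonal(P, 0.5)
    return P


def local_kernel(P: np.ndarray, k_nn: int) -> np.ndarray:
    """Restrict a row-stochastic kernel to each row's k nearest neighbors.

    The neighbor set N_i always contains i itself plus the k_nn - 1 largest
    remaining entries of row i (ties broken toward the lowest index); the
    surviving entries are renormalized so each row sums to 1.
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    if not 1 <= k_nn <= n:
        raise ValidationError(f"k_nn={k_nn} out of range [1, {n}]")
    L = np.zeros_like(P)
    for i in range(n):
        others = np.delete(np.arange(n), i)
        # stable sort on -P gives ties to the lowest index
        order = others[np.argsort(-P[i, others], kind="stable")]
        neigh = np.concatenate(([i], order[: k_nn - 1]))
        denom = P[i, neigh].sum()
        L[i, neigh] = P[i, neigh] / denom
    return L


def fuse(K1: KernelMatrix, K2: KernelMatrix, K3: KernelMatrix,
         cfg: FusionConfig) -> KernelMatrix:
    """Cross-diffusion fusion of three kernels over the same entity set.

    Each kernel is normalized and kNN-localized; then for ``n_iters``
    rounds each normalized kernel is diffused through the average of the
    other two (P1 <- L1 ((P2+P3)/2) L1', cyclically), and after every round
    each is re-symmetrized with the identity added.  The fused kernel is the
    average of the three status matrices.
    """
    n = K1.n
    if K2.n != n or K3.n != n:
        raise ValidationError("fusion inputs must share one entity set")
    cfg.validate(n)
    Ps = [normalize_kernel(K.values) for K in (K1, K2, K3)]
    Ls = [local_kernel(P, cfg.k_nn) for P in Ps]
    I = np.eye(n)
    for _ in range(cfg.n_iters):
        new = [
            Ls[0] @ (0.5 * (Ps[1] + Ps[2])) @ Ls[0].T,
            Ls[1] @ (0.5 * (Ps[0] + Ps[2])) @ Ls[1].T,
            Ls[2] @ (0.5 * (Ps[0] + Ps[1])) @ Ls[2].T,
        ]
        Ps = [0.5 * (Q + Q.T) + I for Q in new]
    F = (Ps[0] + Ps[1] + Ps[2]) / 3.0
    F = 0.5 * (F + F.T)
    return KernelMatrix(F, K1.entity_ids)


def build_final_kernels(ds: DTIDataset, drug_cfg: FusionConfig | None = None,
                        target_cfg: FusionConfig | None = None,
                        binary_profiles: np.ndarray | None = None
                        ) -> tuple[KernelMatrix, KernelMatrix]:
    """Build the fused drug and target kernels for a dataset.

    The drug side fuses {chemical similarity, GIP kernel of drug profiles,
    association kernel of drug profiles}; the target side does the same with
    the sequence similarity and the transposed interaction matrix.  Binary
    datasets use the Jaccard association kernel; affinity datasets use the
    Pearson-correlation kernel on the continuous profiles (with missing
    measurements excluded pairwise) and, when ``binary_profiles`` (an n x m
    binarized interaction matrix) is supplied, feed that to the GIP kernel
    instead of the raw affinities.
    """
    Yf = ds.Y_filled if binary_profiles is None else np.asarray(
        binary_profiles, dtype=float)
    if Yf.shape != (ds.n_drugs, ds.n_targets):
        raise ValidationError("binary_profiles shape does not match the dataset")

    def _side(S, profiles, raw_profiles, ids, cfg):
        n = len(ids)
        if cfg is None or cfg.k_nn == 0:
            cfg = FusionConfig(
                k_nn=default_k_nn(n),
                n_iters=cfg.n_iters if cfg is not None else 2,
            )
        sim = KernelMatrix(0.5 * (S + S.T), ids)
        gip, _ = gip_kernel(profiles, ids)
        if ds.value_kind == "binary":
            assoc = jaccard_kernel(profiles, ids)
        else:
            assoc = pcc_kernel(raw_profiles, ids)
        return fuse(sim, gip, assoc, cfg)

    kfjd = _side(ds.SD, Yf, ds.Y, ds.drug_ids, drug_cfg)
    kfjt = _side(ds.ST, Yf.T, ds.Y.T, ds.target_ids, target_cfg)
    return kfjd, kfjt
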