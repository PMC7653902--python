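"""Cross-validation under CVP/CVD/CVT and ranking/affinity metrics.

Three validation regimes mirror the three prediction scenarios:

* CVP hides random interaction-matrix cells (drug repositioning),
* CVD hides whole drug rows (new-drug discovery),
* CVT hides whole target columns (new-target discovery).

Each fold recomputes every interaction-profile-derived kernel (GIP and the
association kernel) from the masked training matrix, never from the full
one, so no information from held-out cells can leak into training.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_io import DTIDataset, ValidationError
from .kernels import FusionConfig, build_final_kernels
from .mdm import MDMConfig, build_network, dti_scores, fit, reconstruct

__all__ = [
    "CVPlan",
    "AffinityThresholds",
    "FoldRecord",
    "MetricReport",
    "make_cv_plan",
    "mask_training",
    "auc",
    "aupr",
    "concordance_index",
    "binarize_affinity",
    "fit_predict",
    "run_cv",
]

SETTINGS = ("CVP", "CVD", "CVT")


@dataclass(frozen=True)
class AffinityThresholds:
    """Binarization cut-offs in nM; strictly below the cut-off is a positive."""

    kd_cut: float = 30.0
    ki_cut: float = 28.18


@dataclass
class CVPlan:
    """Fold assignments for one repeat block of cross-validation.

    ``assignments`` has shape (n_repeats, n_units) where a unit is a Y cell
    (CVP, flattened row-major), a drug (CVD) or a target (CVT).
    """

    setting: str
    n_folds: int
    n_repeats: int
    seed: int
    assignments: np.ndarray
    n_drugs: int
    n_targets: int
    positives_only: bool = False


def _balanced_folds(n_units: int, n_folds: int,
                    rng: np.random.Generator) -> np.ndarray:
    """A shuffled assignment with fold sizes differing by at most one."""
    labels = np.arange(n_units) % n_folds
    rng.shuffle(labels)
    return labels


def make_cv_plan(ds: DTIDataset, setting: str, n_folds: int = 10,
                 n_repeats: int = 5, seed: int = 0,
                 positives_only: bool = False) -> CVPlan:
    """Build seeded fold assignments for CVP, CVD or CVT.

    Repeat r uses the derived seed ``seed + r``.  With ``positives_only``
    (CVP only) just the known-interaction cells are partitioned; by default
    all n*m cells are.
    """
    setting = setting.upper()
    if setting not in SETTINGS:
        raise ValidationError(f"unknown CV setting {setting!r}; use CVP/CVD/CVT")
    if n_folds < 2:
        raise ValidationError("need at least 2 folds")
    n, m = ds.n_drugs, ds.n_targets
    if setting == "CVD" and n < n_folds:
        raise ValidationError(f"CVD with {n} drugs cannot make {n_folds} folds")
    if setting == "CVT" and m < n_folds:
        raise ValidationError(f"CVT with {m} targets cannot make {n_folds} folds")
    n_units = {"CVP": n * m, "CVD": n, "CVT": m}[setting]
    assignments = np.empty((n_repeats, n_units), dtype=int)
    for r in range(n_repeats):
        rng = np.random.default_rng(seed + r)
        if setting == "CVP" and positives_only:
            lab = np.full(n_units, -1, dtype=int)
            pos = np.flatnonzero(ds.Y_filled.ravel() != 0)
            if pos.size < n_folds:
                raise ValidationError("fewer positive cells than folds")
            lab[pos] = _balanced_folds(pos.size, n_folds, rng)
            assignments[r] = lab
        else:
            assignments[r] = _balanced_folds(n_units, n_folds, rng)
    return CVPlan(setting, n_folds, n_repeats, seed, assignments, n, m,
                  positives_only)


def mask_training(ds: DTIDataset, plan: CVPlan, fold: int, repeat: int = 0
                  ) -> tuple[DTIDataset, np.ndarray]:
    """Zero the held-out portion of Y and return (training set, held-out mask).

    The held-out mask is a boolean n x m matrix marking the cells whose true
    labels are evaluated for this fold; those cells are set to 0 (CVP) or
    belong to fully zeroed rows/columns (CVD/CVT) in the training matrix.
    Similarity matrices are left untouched.
    """
    if not 0 <= fold < plan.n_folds or not 0 <= repeat < plan.n_repeats:
        raise ValidationError("fold or repeat index out of range")
    n, m = plan.n_drugs, plan.n_targets
    lab = plan.assignments[repeat]
    held = np.zeros((n, m), dtype=bool)
    if plan.setting == "CVP":
        held = (lab == fold).reshape(n, m)
    elif plan.setting == "CVD":
        held[lab == fold, :] = True
    else:
        held[:, lab == fold] = True
    train = ds.copy()
    if ds.value_kind == "affinity":
        # 0 nM would read as an infinitely strong binder; hidden affinity
        # measurements become missing instead
        train.Y = np.where(held, np.nan, train.Y)
    else:
        train.Y = np.where(held, 0.0, train.Y_filled)
    return train, held


def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic.

    Equals (concordant pairs + 0.5 * tied pairs) / (positives * negatives).
    """
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise ValidationError("labels and scores must be equal-length vectors")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC undefined: only one class present")
    from scipy.stats import rankdata

    ranks = rankdata(scores)  # midranks handle ties as half-concordant
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def aupr(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the precision-recall curve by the step (average-precision)
    rule: sum over descending unique thresholds of (R_k - R_{k-1}) * P_k,
    with tied scores grouped at a single threshold.
    """
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise ValidationError("labels and scores must be equal-length vectors")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValidationError("AUPR undefined without positives")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order].astype(float)
    tp = np.cumsum(y)
    fp = np.cumsum(1.0 - y)
    # keep only the last index of each tied-score group
    last = np.r_[s[1:] != s[:-1], True]
    tp, fp = tp[last], fp[last]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    recall_prev = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - recall_prev) * precision))


def concordance_index(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Concordance index over all comparable pairs.

    For every pair with y_true_i > y_true_j, counts 1 if the prediction
    orders it the same way, 0.5 on a prediction tie; pairs tied in y_true
    are not comparable.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or y_true.size < 2:
        raise ValidationError("need two equal-length vectors of >= 2 values")
    dt = y_true[:, None] - y_true[None, :]
    dp = y_pred[:, None] - y_pred[None, :]
    comparable = dt > 0
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValidationError("concordance undefined: all y_true equal")
    wins = float(np.sum((dp > 0) & comparable))
    ties = float(np.sum((dp == 0) & comparable))
    return (wins + 0.5 * ties) / n_comp


def binarize_affinity(values: np.ndarray, thresholds: AffinityThresholds,
                      kind: str) -> tuple[np.ndarray, int]:
    """Binarize nM affinities: strictly below the cut-off is an interaction.

    Kd uses 30 nM, Ki uses 28.18 nM; a value exactly at the cut-off is
    negative.  Missing (NaN) measurements map to 0 and their count is
    returned alongside the binary matrix.
    """
    kind = kind.lower()
    if kind == "kd":
        cut = thresholds.kd_cut
    elif kind == "ki":
        cut = thresholds.ki_cut
    else:
        raise ValidationError(f"unknown affinity kind {kind!r}; use Kd or Ki")
    values = np.asarray(values, dtype=float)
    missing = int(np.isnan(values).sum())
    with np.errstate(invalid="ignore"):
        out = (values < cut).astype(float)
    out[np.isnan(values)] = 0.0
    return out, missing


def fit_predict(ds: DTIDataset, fusion_cfg: FusionConfig | None = None,
                mdm_cfg: MDMConfig | None = None,
                thresholds: AffinityThresholds = AffinityThresholds(),
                affinity_kind: str = "kd"):
    """Kernels -> network -> denoising fit -> drug-target scores, in one call.

    In affinity mode the network and GIP profiles use the binarized
    interaction matrix (strict nM cut-offs) so that a high score always
    means "interacts", while the association kernel keeps the continuous
    profiles through the Pearson branch.  Returns ``(scores, model, net)``.
    """
    if mdm_cfg is None:
        mdm_cfg = MDMConfig()
    if ds.value_kind == "affinity":
        y_net, _ = binarize_affinity(ds.Y, thresholds, affinity_kind)
    else:
        y_net = ds.Y_filled
    kfjd, kfjt = build_final_kernels(
        ds, fusion_cfg, fusion_cfg,
        binary_profiles=y_net if ds.value_kind == "affinity" else None,
    )
    net = build_network(kfjt, kfjd, y_net)
    model = fit(net, mdm_cfg)
    scores = dti_scores(reconstruct(model, net), net)
    return scores, model, net


@dataclass
class FoldRecord:
    repeat: int
    fold: int
    n_heldout: int
    n_pos: int
    auc: float
    aupr: float
    ci: float
    runtime_s: float
    skipped: bool = False


@dataclass
class MetricReport:
    setting: str
    folds: list = field(default_factory=list)
    n_skipped: int = 0
    seeds: dict = field(default_factory=dict)

    def _agg(self, attr):
        vals = [getattr(f, attr) for f in self.folds
                if not f.skipped and np.isfinite(getattr(f, attr))]
        if not vals:
            return float("nan"), float("nan")
        return float(np.mean(vals)), float(np.std(vals))

    @property
    def auc_mean_sd(self):
        return self._agg("auc")

    @property
    def aupr_mean_sd(self):
        return self._agg("aupr")

    @property
    def ci_mean_sd(self):
        return self._agg("ci")

    def to_tsv(self) -> str:
        lines = [f"# setting={self.setting} seeds={self.seeds} "
                 f"skipped={self.n_skipped}"]
        lines.append("repeat\tfold\tn_heldout\tn_pos\tauc\taupr\tci\truntime_s")
        for f in self.folds:
            lines.append(
                f"{f.repeat}\t{f.fold}\t{f.n_heldout}\t{f.n_pos}\t"
                f"{f.auc:.6f}\t{f.aupr:.6f}\t{f.ci:.6f}\t{f.runtime_s:.3f}"
            )
        am, asd = self.auc_mean_sd
        pm, psd = self.aupr_mean_sd
        cm, csd = self.ci_mean_sd
        lines.append(f"# mean AUC {am:.4f} +/- {asd:.4f}; "
                     f"mean AUPR {pm:.4f} +/- {psd:.4f}; "
                     f"mean CI {cm:.4f} +/- {csd:.4f}")
        return "\n".join(lines) + "\n"


def run_cv(ds: DTIDataset, plan: CVPlan,
           fusion_cfg: FusionConfig | None = None,
           mdm_cfg: MDMConfig | None = None,
           thresholds: AffinityThresholds = AffinityThresholds(),
           affinity_kind: str = "kd") -> MetricReport:
    """Run the full pipeline once per fold and score held-out cells only.

    Per fold: mask the training matrix, rebuild both fused kernels from the
    masked interactions, assemble the network, fit the denoising model and
    score the held-out (drug, target) cells against their true labels.  In
    affinity mode the labels for AUC/AUPR come from the strict nM cut-offs
    and the concordance index uses the continuous values.
    """
    if mdm_cfg is None:
        mdm_cfg = MDMConfig()
    report = MetricReport(setting=plan.setting,
                          seeds=dict(plan_seed=plan.seed, mdm_seed=mdm_cfg.seed))
    truth = ds.Y_filled
    if ds.value_kind == "affinity":
        labels_full, _ = binarize_affinity(ds.Y, thresholds, affinity_kind)
    else:
        labels_full = truth

    for r in range(plan.n_repeats):
        for fold in range(plan.n_folds):
            t0 = time.perf_counter()
            train, held = mask_training(ds, plan, fold, repeat=r)
            if plan.setting == "CVP" and plan.positives_only:
                lab = plan.assignments[r]
                eval_mask = held | ((train.Y_filled == 0)
                                    & (lab < 0).reshape(held.shape))
            else:
                eval_mask = held
            scores, _, _ = fit_predict(train, fusion_cfg, mdm_cfg,
                                       thresholds, affinity_kind)
            s = scores[eval_mask]
            lab_bin = labels_full[eval_mask]
            rec = FoldRecord(repeat=r, fold=fold, n_heldout=int(eval_mask.sum()),
                             n_pos=int(lab_bin.sum()), auc=np.nan, aupr=np.nan,
                             ci=np.nan, runtime_s=0.0)
            if lab_bin.min() == lab_bin.max():
                warnings.warn(
                    f"repeat {r} fold {fold}: single-class held-out labels, "
                    "AUC/AUPR skipped", stacklevel=2,
                )
                rec.skipped = True
                report.n_skipped += 1
            else:
                rec.auc = auc(lab_bin.astype(bool), s)
                rec.aupr = aupr(lab_bin.astype(bool), s)
            if ds.value_kind == "affinity":
                yt = truth[eval_mask]
                if yt.min() != yt.max():
                    # lower Kd/Ki means stronger binding: a good score ranks
                    # the *high-affinity* (low-constant) pair first
                    rec.ci = concordance_index(-yt, s)
            rec.runtime_s = time.perf_counter() - t0
            report.folds.append(rec)
    return report
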