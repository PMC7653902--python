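"""Reading, writing and simulating labeled drug-target interaction datasets.

The on-disk dialect is the one used by the public Yamanishi gold-standard
files: whitespace- or tab-delimited text, first row holds column identifiers
(optionally preceded by a corner token), first column holds row identifiers.
Those files store the interaction matrix with targets in rows, so
:func:`load_dataset` detects orientation by matching row identifiers against
the drug-similarity matrix rather than assuming drugs-in-rows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "DTIDataset",
    "DatasetStats",
    "SyntheticConfig",
    "ValidationError",
    "MatrixParseError",
    "read_labeled_matrix",
    "write_labeled_matrix",
    "load_dataset",
    "dataset_statistics",
    "generate_synthetic",
    "write_ranked_predictions",
]

#: tolerance above which symmetrizing a similarity matrix emits a warning
SYMMETRY_WARN_TOL = 1e-6


class ValidationError(ValueError):
    """Raised when an input violates a dataset contract."""


class MatrixParseError(ValueError):
    """Raised when a labeled matrix file cannot be parsed."""


@dataclass
class DTIDataset:
    """A drug-target interaction dataset with aligned identifier orderings.

    Parameters
    ----------
    drug_ids, target_ids
        Ordered unique identifiers; ``Y`` rows are drugs, columns targets.
    Y
        ``(n_drugs, n_targets)`` interaction matrix.  Binary {0, 1} in
        ``binary`` mode; nonnegative affinities (nM) in ``affinity`` mode,
        where NaN marks a missing measurement.
    SD, ST
        Drug-drug chemical and target-target sequence similarity matrices,
        symmetric with unit diagonal, entries in [0, 1].
    value_kind
        Either ``"binary"`` or ``"affinity"``.
    """

    drug_ids: list
    target_ids: list
    Y: np.ndarray
    SD: np.ndarray
    ST: np.ndarray
    value_kind: str = "binary"

    def __post_init__(self):
        self.drug_ids = list(self.drug_ids)
        self.target_ids = list(self.target_ids)
        self.Y = np.asarray(self.Y, dtype=float)
        self.SD = np.asarray(self.SD, dtype=float)
        self.ST = np.asarray(self.ST, dtype=float)
        self.validate()

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    @property
    def Y_filled(self) -> np.ndarray:
        """Interaction matrix with missing affinities replaced by 0."""
        return np.nan_to_num(self.Y, nan=0.0)

    def validate(self) -> None:
        n, m = len(self.drug_ids), len(self.target_ids)
        if len(set(self.drug_ids)) != n:
            raise ValidationError("duplicate drug identifiers")
        if len(set(self.target_ids)) != m:
            raise ValidationError("duplicate target identifiers")
        if self.Y.shape != (n, m):
            raise ValidationError(
                f"Y has shape {self.Y.shape}, expected ({n}, {m})"
            )
        if self.SD.shape != (n, n) or self.ST.shape != (m, m):
            raise ValidationError("similarity matrix shape mismatch")
        for name, S in (("SD", self.SD), ("ST", self.ST)):
            if not np.allclose(S, S.T, atol=1e-8):
                raise ValidationError(f"{name} is not symmetric within 1e-8")
            if not np.allclose(np.diag(S), 1.0, atol=1e-8):
                raise ValidationError(f"{name} diagonal is not 1")
        if self.value_kind not in ("binary", "affinity"):
            raise ValidationError(f"unknown value_kind {self.value_kind!r}")
        if self.value_kind == "binary":
            vals = self.Y[np.isfinite(self.Y)]
            if not np.all(np.isin(vals, (0.0, 1.0))):
                raise ValidationError("binary mode requires Y entries in {0, 1}")

    def copy(self) -> "DTIDataset":
        return DTIDataset(
            list(self.drug_ids),
            list(self.target_ids),
            self.Y.copy(),
            self.SD.copy(),
            self.ST.copy(),
            self.value_kind,
        )


@dataclass(frozen=True)
class DatasetStats:
    n_drugs: int
    n_targets: int
    n_interactions: int
    avg_degree_drugs: float
    avg_degree_targets: float


def _trunc2(x: float) -> float:
    """Truncate toward zero at the second decimal (1.669 -> 1.66)."""
    return math.trunc(x * 100.0) / 100.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration for the block-structured synthetic generator.

    Drugs and targets are each partitioned into ``n_blocks`` groups of
    near-equal size.  Drug block ``g`` preferentially interacts with target
    block ``g`` (probability ``p_within``; ``p_background`` elsewhere), and
    similarity matrices take the value ``sim_within`` inside a block and
    ``sim_between`` outside, plus additive Gaussian noise clipped to [0, 1].
    """

    n_drugs: int = 60
    n_targets: int = 40
    n_blocks: int = 4
    p_within: float = 0.5
    p_background: float = 0.02
    sim_within: float = 0.8
    sim_between: float = 0.2
    sim_noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_blocks > min(self.n_drugs, self.n_targets):
            raise ValidationError(
                "n_blocks exceeds the smaller of n_drugs and n_targets"
            )
        if self.n_blocks < 1 or self.n_drugs < 1 or self.n_targets < 1:
            raise ValidationError("counts must be positive")
        for p in (self.p_within, self.p_background):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("interaction probabilities must lie in [0, 1]")
        if not self.p_within > self.p_background:
            raise ValidationError("p_within must exceed p_background")
        if not self.sim_within > self.sim_between:
            raise ValidationError("sim_within must exceed sim_between")
        if self.sim_noise_sd < 0:
            raise ValidationError("sim_noise_sd must be nonnegative")


def read_labeled_matrix(path) -> tuple[list, list, np.ndarray]:
    """Read a labeled matrix text file.

    Returns ``(row_ids, col_ids, values)`` with identifiers kept in file
    order.  The header row may or may not carry a leading corner token; the
    two cases are disambiguated by comparing the header length against the
    data rows.  Blank, ``NA``, ``NaN`` and ``nan`` cells parse as NaN.
    """
    path = Path(path)
    with path.open() as fh:
        raw_lines = fh.read().splitlines()
    lines = [(i + 1, ln) for i, ln in enumerate(raw_lines) if ln.strip()]
    if len(lines) < 2:
        raise MatrixParseError(f"{path}: need a header line and at least one data row")

    delim = "\t" if "\t" in lines[0][1] else None
    header = lines[0][1].split(delim)
    first_data = lines[1][1].split(delim)
    n_fields = len(first_data)

    if len(header) == n_fields - 1:
        col_ids = header  # no corner token
    elif len(header) == n_fields:
        col_ids = header[1:]  # leading corner token
    else:
        raise MatrixParseError(
            f"{path}: header has {len(header)} fields but data rows have "
            f"{n_fields} (line {lines[1][0]})"
        )

    row_ids: list = []
    rows: list = []
    for lineno, ln in lines[1:]:
        fields = ln.split(delim)
        if len(fields) != n_fields:
            raise MatrixParseError(
                f"{path}: line {lineno} has {len(fields)} fields, expected {n_fields}"
            )
        row_ids.append(fields[0])
        row = []
        for j, tok in enumerate(fields[1:]):
            if tok in ("", "NA", "NaN", "nan"):
                row.append(np.nan)
                continue
            try:
                row.append(float(tok))
            except ValueError:
                raise MatrixParseError(
                    f"{path}: non-numeric value {tok!r} at row {fields[0]!r}, "
                    f"column {col_ids[j]!r} (line {lineno})"
                ) from None
        rows.append(row)

    if len(set(row_ids)) != len(row_ids):
        dups = sorted({r for r in row_ids if row_ids.count(r) > 1})
        raise ValidationError(f"{path}: duplicate row identifiers {dups}")
    if len(set(col_ids)) != len(col_ids):
        dups = sorted({c for c in col_ids if col_ids.count(c) > 1})
        raise ValidationError(f"{path}: duplicate column identifiers {dups}")
    return row_ids, col_ids, np.asarray(rows, dtype=float)


def write_labeled_matrix(path, row_ids: Sequence, col_ids: Sequence,
                         values: np.ndarray) -> None:
    """Write a labeled matrix with 17 significant digits (lossless for float64)."""
    values = np.asarray(values, dtype=float)
    if values.shape != (len(row_ids), len(col_ids)):
        raise ValidationError(
            f"matrix shape {values.shape} does not match "
            f"({len(row_ids)}, {len(col_ids)}) identifiers"
        )
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(["id"] + [str(c) for c in col_ids]) + "\n")
        for rid, row in zip(row_ids, values):
            cells = ["NA" if np.isnan(v) else format(v, ".17g") for v in row]
            fh.write("\t".join([str(rid)] + cells) + "\n")


def _canonical_similarity(ids, S, name: str):
    """Symmetrize and force unit diagonal, warning on large adjustments."""
    adj = max(np.max(np.abs(S - S.T), initial=0.0),
              np.max(np.abs(np.diag(S) - 1.0), initial=0.0))
    if adj > SYMMETRY_WARN_TOL:
        warnings.warn(
            f"{name}: symmetrization/diagonal adjustment of {adj:.3g} "
            f"exceeds {SYMMETRY_WARN_TOL:g}",
            stacklevel=3,
        )
    S = 0.5 * (S + S.T)
    np.fill_diagonal(S, 1.0)
    return S


def load_dataset(y_path, sd_path, st_path, value_kind: str = "binary",
                 orientation: str | None = None) -> DTIDataset:
    """Load and align a dataset from three labeled matrix files.

    The interaction matrix is reoriented so rows are drugs, by matching its
    row-identifier set against the drug-similarity identifiers (with a
    fallback match against the target side).  All matrices are permuted to
    the drug/target order of the similarity files; similarity matrices are
    symmetrized with the diagonal forced to 1.

    Parameters
    ----------
    orientation
        ``"drugs-in-rows"`` or ``"targets-in-rows"`` to override detection;
        required when the interaction matrix is square with ambiguous ids.
    """
    sd_rows, sd_cols, SD = read_labeled_matrix(sd_path)
    st_rows, st_cols, ST = read_labeled_matrix(st_path)
    for nm, (r, c) in (("drug similarity", (sd_rows, sd_cols)),
                       ("target similarity", (st_rows, st_cols))):
        if set(r) != set(c):
            raise ValidationError(f"{nm}: row and column identifier sets differ")
    # permute similarity columns into row order
    SD = SD[:, [sd_cols.index(r) for r in sd_rows]]
    ST = ST[:, [st_cols.index(r) for r in st_rows]]
    drug_ids, target_ids = sd_rows, st_rows

    yr, yc, Y = read_labeled_matrix(y_path)
    rows_are_drugs = set(yr) <= set(drug_ids) and set(yc) <= set(target_ids)
    rows_are_targets = set(yr) <= set(target_ids) and set(yc) <= set(drug_ids)
    if orientation == "drugs-in-rows":
        rows_are_targets = False
    elif orientation == "targets-in-rows":
        rows_are_drugs = False
    elif rows_are_drugs and rows_are_targets:
        raise ValidationError(
            "interaction matrix orientation is ambiguous (identifier sets "
            "overlap both ways); pass orientation='drugs-in-rows' or "
            "'targets-in-rows'"
        )
    if not rows_are_drugs and not rows_are_targets:
        missing = sorted(
            (set(yr) | set(yc)) - (set(drug_ids) | set(target_ids))
        )
        raise ValidationError(
            f"interaction matrix identifiers absent from both similarity "
            f"matrices: {missing}"
        )
    if rows_are_targets:
        yr, yc, Y = yc, yr, Y.T

    missing_d = sorted(set(yr) - set(drug_ids))
    missing_t = sorted(set(yc) - set(target_ids))
    if missing_d or missing_t:
        raise ValidationError(
            f"identifiers missing from similarity matrices: {missing_d + missing_t}"
        )
    if set(yr) != set(drug_ids) or set(yc) != set(target_ids):
        extra = sorted((set(drug_ids) - set(yr)) | (set(target_ids) - set(yc)))
        raise ValidationError(
            f"identifiers present in similarity matrices but absent from the "
            f"interaction matrix: {extra}"
        )
    Y = Y[[yr.index(d) for d in drug_ids], :][:, [yc.index(t) for t in target_ids]]

    SD = _canonical_similarity(drug_ids, SD, "drug similarity")
    ST = _canonical_similarity(target_ids, ST, "target similarity")
    return DTIDataset(drug_ids, target_ids, Y, SD, ST, value_kind)


def dataset_statistics(ds: DTIDataset) -> DatasetStats:
    """Interaction counts and average degrees, truncated at two decimals.

    Average degrees are truncated toward zero (not rounded) at the second
    decimal, e.g. 90 interactions over 54 drugs gives 1.66.
    """
    n, m = ds.n_drugs, ds.n_targets
    if n == 0 or m == 0:
        raise ValidationError("empty dataset")
    n_int = int(np.count_nonzero(ds.Y_filled))
    return DatasetStats(
        n_drugs=n,
        n_targets=m,
        n_interactions=n_int,
        avg_degree_drugs=_trunc2(n_int / n),
        avg_degree_targets=_trunc2(n_int / m),
    )


def _block_assignments(n: int, n_blocks: int) -> np.ndarray:
    """Contiguous near-equal block labels, sizes differing by at most 1."""
    sizes = np.full(n_blocks, n // n_blocks)
    sizes[: n % n_blocks] += 1
    return np.repeat(np.arange(n_blocks), sizes)


def _block_similarity(groups: np.ndarray, cfg: SyntheticConfig,
                      rng: np.random.Generator) -> np.ndarray:
    same = groups[:, None] == groups[None, :]
    S = np.where(same, cfg.sim_within, cfg.sim_between).astype(float)
    if cfg.sim_noise_sd > 0:
        noise = rng.normal(0.0, cfg.sim_noise_sd, S.shape)
        S = S + 0.5 * (noise + noise.T)
    S = np.clip(0.5 * (S + S.T), 0.0, 1.0)
    np.fill_diagonal(S, 1.0)
    return S


def generate_synthetic(cfg: SyntheticConfig) -> DTIDataset:
    """Generate a block-structured dataset with planted interactions.

    Reproducible: identical configurations (including seed) give identical
    datasets.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    gd = _block_assignments(cfg.n_drugs, cfg.n_blocks)
    gt = _block_assignments(cfg.n_targets, cfg.n_blocks)
    SD = _block_similarity(gd, cfg, rng)
    ST = _block_similarity(gt, cfg, rng)
    p = np.where(gd[:, None] == gt[None, :], cfg.p_within, cfg.p_background)
    Y = (rng.random((cfg.n_drugs, cfg.n_targets)) < p).astype(float)
    drug_ids = [f"D{i + 1:05d}" for i in range(cfg.n_drugs)]
    target_ids = [f"hsa{j + 1:04d}" for j in range(cfg.n_targets)]
    return DTIDataset(drug_ids, target_ids, Y, SD, ST, "binary")


def write_ranked_predictions(scores: np.ndarray, ds: DTIDataset, path,
                             top_k: int) -> None:
    """Write the top-scoring drug-target pairs as a 4-column TSV.

    Rows are sorted by descending score; ties are broken by the
    lexicographic (drug_id, target_id) pair so output is deterministic.
    Known interactions (nonzero cells of Y) are flagged in the last column.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (ds.n_drugs, ds.n_targets):
        raise ValidationError(
            f"score matrix shape {scores.shape} does not match dataset "
            f"({ds.n_drugs}, {ds.n_targets})"
        )
    known = ds.Y_filled != 0
    records = [
        (-scores[i, j], str(ds.drug_ids[i]), str(ds.target_ids[j]),
         scores[i, j], int(known[i, j]))
        for i in range(ds.n_drugs) for j in range(ds.n_targets)
    ]
    records.sort(key=lambda r: (r[0], r[1], r[2]))
    k = min(int(top_k), len(records))
    with Path(path).open("w") as fh:
        fh.write("drug_id\ttarget_id\tscore\tknown\n")
        for _, d, t, s, kn in records[:k]:
            fh.write(f"{d}\t{t}\t{s:.12g}\t{kn}\n")
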