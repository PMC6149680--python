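"""Core domain types and tab-separated file I/O.

The canonical in-memory orientation is drugs-as-rows everywhere: an
interaction matrix is ``nd x nt`` (drugs by targets) and a feature matrix
is ``nd x p``.  Published benchmark files often list targets as rows; the
reader flag ``orientation="drugs_as_columns"`` transposes on ingestion so
that downstream code never has to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError, ValidationError

__all__ = [
    "InteractionMatrix",
    "FeatureMatrix",
    "DatasetStats",
    "read_interaction_matrix",
    "write_interaction_matrix",
    "read_feature_matrix",
    "interaction_profiles",
    "dataset_stats",
]


def _check_ids(ids: list[str], n: int, what: str) -> None:
    if len(ids) != n:
        raise ValidationError(
            f"{what}: {len(ids)} identifiers for {n} {what.split('_')[0]}s"
        )
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {what} identifier: {dup!r}")


@dataclass
class InteractionMatrix:
    """Binary drug-by-target adjacency matrix Y with aligned identifiers.

    ``values[i, j] == 1`` iff drug ``drug_ids[i]`` is known to interact with
    target ``target_ids[j]``.  Unobserved pairs are 0 — absence of evidence,
    not evidence of absence, which is why they form the prediction set.
    """

    values: np.ndarray
    drug_ids: list[str]
    target_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("interaction matrix must be 2-D")
        if not np.isfinite(self.values).all():
            raise ValidationError("interaction matrix contains missing values")
        if not np.isin(self.values, (0.0, 1.0)).all():
            bad = np.argwhere(~np.isin(self.values, (0.0, 1.0)))[0]
            raise ValidationError(
                f"non-binary interaction value at row {bad[0]}, column {bad[1]}"
            )
        nd, nt = self.values.shape
        if nd < 2 or nt < 1:
            raise ValidationError(f"need at least 2 drugs and 1 target, got {nd}x{nt}")
        self.drug_ids = [str(d) for d in self.drug_ids]
        self.target_ids = [str(t) for t in self.target_ids]
        _check_ids(self.drug_ids, nd, "drug")
        _check_ids(self.target_ids, nt, "target")

    @property
    def nd(self) -> int:
        return self.values.shape[0]

    @property
    def nt(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "InteractionMatrix":
        return InteractionMatrix(
            self.values.copy(), list(self.drug_ids), list(self.target_ids)
        )

    def masked(self, i: int, j: int) -> "InteractionMatrix":
        """Return a copy with entry (i, j) set to 0 (a held-out pair)."""
        out = self.copy()
        out.values[i, j] = 0.0
        return out


@dataclass
class FeatureMatrix:
    """Real-valued drug-by-feature matrix X (rows aligned with drug_ids).

    ``feature_kind`` records provenance: ``interaction_profile`` rows are the
    rows of an interaction matrix (and therefore change when labels are
    masked), ``fingerprint`` rows are chemical substructure bit vectors that
    do not depend on the labels.
    """

    values: np.ndarray
    drug_ids: list[str]
    feature_kind: str = "other"

    _KINDS = ("interaction_profile", "fingerprint", "other")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("feature matrix must be 2-D")
        if not np.isfinite(self.values).all():
            raise ValidationError("feature matrix contains non-finite entries")
        self.drug_ids = [str(d) for d in self.drug_ids]
        _check_ids(self.drug_ids, self.values.shape[0], "drug")
        if self.feature_kind not in self._KINDS:
            raise ValidationError(f"unknown feature_kind {self.feature_kind!r}")

    @property
    def nd(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class DatasetStats:
    """Descriptive statistics of an interaction dataset.

    ``edges`` is the number of known interactions Edt; the means are the
    average number of targets per drug (Edt/nd) and drugs per target
    (Edt/nt); sparsity is the fraction of observed pairs Edt/(nd*nt).
    """

    nd: int
    nt: int
    edges: int
    mean_targets_per_drug: float = field(init=False)
    mean_drugs_per_target: float = field(init=False)
    sparsity: float = field(init=False)

    def __post_init__(self) -> None:
        if self.nd <= 0 or self.nt <= 0 or self.edges < 0:
            raise ValidationError("counts must be positive (edges nonnegative)")
        if self.edges > self.nd * self.nt:
            raise ValidationError("more edges than drug-target pairs")
        self.mean_targets_per_drug = self.edges / self.nd
        self.mean_drugs_per_target = self.edges / self.nt
        self.sparsity = self.edges / (self.nd * self.nt)

    @classmethod
    def from_counts(cls, nd: int, nt: int, edges: int) -> "DatasetStats":
        return cls(nd=nd, nt=nt, edges=edges)


def read_interaction_matrix(
    path, orientation: str = "drugs_as_rows"
) -> InteractionMatrix:
    """Read a TSV adjacency file (header row = column IDs, first column = row IDs).

    ``orientation`` names what the file's *rows* are; the returned matrix is
    always drugs-by-targets.
    """
    if orientation not in ("drugs_as_rows", "drugs_as_columns"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty interaction file: {path}") from exc
    except pd.errors.ParserError as exc:
        raise FormatError(f"ragged or malformed interaction file {path}: {exc}") from exc
    if df.isna().any().any():
        r, c = next(zip(*np.where(df.isna().values)))
        raise FormatError(
            f"missing cell at row {df.index[r]!r}, column {df.columns[c]!r} "
            f"(ragged file?)"
        )
    values = np.empty(df.shape, dtype=float)
    for (r, c), cell in np.ndenumerate(df.values):
        s = str(cell).strip()
        if s not in ("0", "1"):
            raise ParseError(
                f"non-binary cell {s!r} at row {df.index[r]!r}, "
                f"column {df.columns[c]!r}"
            )
        values[r, c] = float(s)
    row_ids = [str(x) for x in df.index]
    col_ids = [str(x) for x in df.columns]
    if orientation == "drugs_as_columns":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    return InteractionMatrix(values=values, drug_ids=row_ids, target_ids=col_ids)


def write_interaction_matrix(Y: InteractionMatrix, path) -> None:
    """Write the drugs-as-rows TSV dialect read by :func:`read_interaction_matrix`."""
    df = pd.DataFrame(
        Y.values.astype(int), index=Y.drug_ids, columns=Y.target_ids
    )
    df.to_csv(path, sep="\t")


def read_feature_matrix(path) -> FeatureMatrix:
    """Read a headerless TSV of drug ID followed by numeric feature columns."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty feature file: {path}") from exc
    except pd.errors.ParserError as exc:
        raise FormatError(f"ragged or malformed feature file {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"feature file {path} has no feature columns")
    if df.isna().any().any():
        r = int(np.where(df.isna().any(axis=1))[0][0])
        raise FormatError(
            f"row {df.index[r]!r} has missing cells (ragged feature file?)"
        )
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.apply(pd.to_numeric, errors="coerce")
        r, c = next(zip(*np.where(bad.isna().values)))
        raise ParseError(
            f"non-numeric feature cell {df.iat[r, c]!r} in row {df.index[r]!r}"
        )
    return FeatureMatrix(
        values=values.astype(float),
        drug_ids=[str(x) for x in df.index],
        feature_kind="fingerprint",
    )


def write_feature_matrix(X: FeatureMatrix, path) -> None:
    pd.DataFrame(X.values, index=X.drug_ids).to_csv(
        path, sep="\t", header=False
    )


def interaction_profiles(Y: InteractionMatrix) -> FeatureMatrix:
    """The rows of Y used as drug feature vectors (p = nt)."""
    return FeatureMatrix(
        values=Y.values.copy(),
        drug_ids=list(Y.drug_ids),
        feature_kind="interaction_profile",
    )


def dataset_stats(Y: InteractionMatrix) -> DatasetStats:
    edges = int(round(Y.values.sum()))
    return DatasetStats(nd=Y.nd, nt=Y.nt, edges=edges)
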