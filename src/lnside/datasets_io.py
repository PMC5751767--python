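"""Reading, writing, validating and aligning the matrices of the frame.

All on-disk tables are TSV with one header row and one identifier column.
Binary matrices (feature views, drug–side-effect associations) use literal
``0``/``1`` characters; score matrices use decimal floats at full precision.
The header cell (0,0) is the label ``id`` and is ignored on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "AssociationMatrix",
    "DatasetBundle",
    "ScoreMatrix",
    "MatrixParseError",
    "AlignmentError",
    "read_matrix",
    "write_matrix",
    "write_scores",
    "read_scores",
    "align_bundle",
]


class MatrixParseError(ValueError):
    """A table on disk violates the binary-matrix contract."""


class AlignmentError(ValueError):
    """Member matrices of a bundle do not share a common drug set."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise MatrixParseError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


def _validate_binary(values: np.ndarray, row_ids: Sequence[str], col_ids: Sequence[str]) -> np.ndarray:
    values = np.asarray(values)
    bad = (values != 0) & (values != 1)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise MatrixParseError(
            f"non-binary entry {values[i, j]!r} at row {row_ids[i]!r}, column {col_ids[j]!r}"
        )
    return values.astype(np.int8)


@dataclass
class FeatureMatrix:
    """Binary drugs × descriptors table for one feature view.

    Rows are drugs, columns are descriptors (e.g. PubChem substructure keys,
    target proteins); entry 1 marks presence of the descriptor.
    """

    drug_ids: list[str]
    descriptor_ids: list[str]
    values: np.ndarray
    view_name: str = "view"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n, p = self.values.shape
        if n < 1:
            raise MatrixParseError(f"feature view {self.view_name!r} has no drugs")
        if p < 1:
            raise MatrixParseError(f"feature view {self.view_name!r} needs p >= 1 descriptors")
        if len(self.drug_ids) != n or len(self.descriptor_ids) != p:
            raise MatrixParseError("identifier lists do not match matrix shape")
        _check_unique(self.drug_ids, "drug")
        _check_unique(self.descriptor_ids, "descriptor")
        self.values = _validate_binary(self.values, self.drug_ids, self.descriptor_ids)
        zero_rows = np.flatnonzero(self.values.sum(axis=1) == 0)
        if zero_rows.size:
            names = [self.drug_ids[i] for i in zero_rows[:5]]
            warnings.warn(
                f"view {self.view_name!r}: {zero_rows.size} drug(s) with all-zero "
                f"feature rows (e.g. {names}); distances to them are degenerate",
                stacklevel=3,
            )

    @property
    def n_drugs(self) -> int:
        return self.values.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.values.shape[1]


@dataclass
class AssociationMatrix:
    """Binary drugs × side-effect-terms association table (the matrix A)."""

    drug_ids: list[str]
    side_effect_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n, m = self.values.shape
        if len(self.drug_ids) != n or len(self.side_effect_ids) != m:
            raise MatrixParseError("identifier lists do not match matrix shape")
        _check_unique(self.drug_ids, "drug")
        _check_unique(self.side_effect_ids, "side-effect")
        self.values = _validate_binary(self.values, self.drug_ids, self.side_effect_ids)

    @property
    def n_drugs(self) -> int:
        return self.values.shape[0]

    @property
    def n_side_effects(self) -> int:
        return self.values.shape[1]

    def as_feature_view(self, view_name: str = "association_profile") -> FeatureMatrix:
        """View the association profiles A(i,:) as a binary feature matrix."""
        return FeatureMatrix(
            drug_ids=list(self.drug_ids),
            descriptor_ids=list(self.side_effect_ids),
            values=self.values.copy(),
            view_name=view_name,
        )


@dataclass
class ScoreMatrix:
    """Real-valued drugs × side-effect-terms prediction scores."""

    drug_ids: list[str]
    side_effect_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, m = self.values.shape
        if len(self.drug_ids) != n or len(self.side_effect_ids) != m:
            raise MatrixParseError("identifier lists do not match matrix shape")


@dataclass
class DatasetBundle:
    """One or more feature views plus associations on a shared drug order."""

    views: list[FeatureMatrix]
    associations: AssociationMatrix
    cluster_labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        ref = self.associations.drug_ids
        for v in self.views:
            if v.drug_ids != ref:
                raise AlignmentError(
                    f"view {v.view_name!r} drug order differs from associations; "
                    "use align_bundle()"
                )

    @property
    def drug_ids(self) -> list[str]:
        return list(self.associations.drug_ids)

    @property
    def n_drugs(self) -> int:
        return self.associations.n_drugs


def read_matrix(path: str | Path, kind: str = "feature", view_name: str | None = None):
    """Read a TSV binary matrix as a :class:`FeatureMatrix` or :class:`AssociationMatrix`.

    First row holds column identifiers, first column drug identifiers; the
    corner cell is ignored. Body entries must parse exactly as 0 or 1.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    row_ids = [str(x) for x in df.index]
    col_ids = [str(x) for x in df.columns]
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise MatrixParseError(f"{path}: non-numeric entry ({exc})") from exc
    if not np.isfinite(values).all():
        raise MatrixParseError(f"{path}: missing or non-finite entries")
    if np.any(values != np.round(values)):
        i, j = map(int, np.argwhere(values != np.round(values))[0])
        raise MatrixParseError(
            f"{path}: non-integer entry {values[i, j]} at row {row_ids[i]!r}, column {col_ids[j]!r}"
        )
    values = values.astype(np.int64)
    bad = (values != 0) & (values != 1)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise MatrixParseError(
            f"{path}: non-binary entry {values[i, j]} at row {row_ids[i]!r}, column {col_ids[j]!r}"
        )
    if kind == "feature":
        return FeatureMatrix(row_ids, col_ids, values, view_name=view_name or path.stem)
    if kind == "association":
        return AssociationMatrix(row_ids, col_ids, values)
    raise ValueError(f"unknown kind {kind!r}; expected 'feature' or 'association'")


def _write_table(row_ids, col_ids, values, path, fmt) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(col_ids) + "\n")
        for rid, row in zip(row_ids, values):
            fh.write(rid + "\t" + "\t".join(fmt(v) for v in row) + "\n")


def write_matrix(matrix, path: str | Path) -> None:
    """Write a binary matrix (feature or association) as TSV."""
    if isinstance(matrix, FeatureMatrix):
        col_ids = matrix.descriptor_ids
    elif isinstance(matrix, AssociationMatrix):
        col_ids = matrix.side_effect_ids
    else:
        raise TypeError(f"cannot write {type(matrix).__name__} as a binary matrix")
    _write_table(matrix.drug_ids, col_ids, matrix.values, path, lambda v: str(int(v)))


def write_scores(scores: ScoreMatrix, path: str | Path) -> None:
    """Write a score matrix as TSV at full (>= 12 significant digits) precision."""
    if not np.isfinite(scores.values).all():
        raise ValueError("refusing to write non-finite scores")
    _write_table(
        scores.drug_ids, scores.side_effect_ids, scores.values, path, lambda v: format(v, ".17g")
    )


def read_scores(path: str | Path) -> ScoreMatrix:
    """Read back a TSV score matrix written by :func:`write_scores`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ScoreMatrix(
        [str(x) for x in df.index], [str(x) for x in df.columns], df.to_numpy(dtype=float)
    )


def align_bundle(
    views: Sequence[FeatureMatrix],
    associations: AssociationMatrix,
    cluster_labels: np.ndarray | None = None,
) -> DatasetBundle:
    """Reorder all matrices to a single canonical (lexicographic) drug order.

    Every matrix must cover exactly the same set of drugs; row order may
    differ between inputs. Raises :class:`AlignmentError` naming drugs that
    are present in some matrices but missing from others.
    """
    ref = set(associations.drug_ids)
    for v in views:
        s = set(v.drug_ids)
        if s != ref:
            missing = sorted(ref - s)[:10]
            extra = sorted(s - ref)[:10]
            raise AlignmentError(
                f"view {v.view_name!r} drug set mismatch: "
                f"missing={missing or 'none'}, unexpected={extra or 'none'}"
            )
    order = sorted(ref)
    a_pos = {d: i for i, d in enumerate(associations.drug_ids)}
    a_idx = [a_pos[d] for d in order]
    new_assoc = AssociationMatrix(
        list(order), list(associations.side_effect_ids), associations.values[a_idx]
    )
    new_views = []
    for v in views:
        pos = {d: i for i, d in enumerate(v.drug_ids)}
        idx = [pos[d] for d in order]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-row warning already issued on construction
            new_views.append(
                FeatureMatrix(list(order), list(v.descriptor_ids), v.values[idx], v.view_name)
            )
    labels = None
    if cluster_labels is not None:
        labels = np.asarray(cluster_labels)[a_idx]
    return DatasetBundle(new_views, new_assoc, labels)
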