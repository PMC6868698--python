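"""Reading, writing and validation of association and similarity matrices.

The canonical on-disk layout is a TSV with an identifier header row and an
identifier first column.  Association matrices are binary with rows =
diseases and columns = drugs; similarity matrices are square with matching
row/column identifiers and values in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationMatrix",
    "SimilarityMatrix",
    "DrugCatalog",
    "read_association_matrix",
    "write_association_matrix",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "read_drug_catalog",
    "write_ranked_predictions",
]

#: tolerance below which similarity values outside [0, 1] are clipped silently
CLIP_TOL = 1e-6
#: maximum tolerated asymmetry of a similarity matrix
SYMMETRY_TOL = 1e-9


class FormatError(ValueError):
    """A file does not follow the canonical layout (non-binary cell, bad shape...)."""


class IdentifierError(ValueError):
    """Duplicate, unknown or mismatched entity identifiers."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise IdentifierError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class AssociationMatrix:
    """Binary diseases x drugs adjacency matrix with identifier axes.

    Row i is the interaction profile of disease ``disease_ids[i]`` over all
    drugs; column j is the interaction profile of drug ``drug_ids[j]`` over
    all diseases.
    """

    disease_ids: list[str]
    drug_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise FormatError("association matrix must be 2-dimensional")
        if self.values.shape != (len(self.disease_ids), len(self.drug_ids)):
            raise FormatError(
                f"shape {self.values.shape} does not match "
                f"{len(self.disease_ids)} diseases x {len(self.drug_ids)} drugs"
            )
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"non-binary cell {self.values[i, j]!r} at "
                f"disease {self.disease_ids[i]!r} / drug {self.drug_ids[j]!r}"
            )
        _check_unique(self.disease_ids, "disease")
        _check_unique(self.drug_ids, "drug")
        self.values = self.values.astype(np.int8)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_associations(self) -> int:
        return int(self.values.sum())

    def drug_index(self, drug_id: str) -> int:
        try:
            return self.drug_ids.index(drug_id)
        except ValueError:
            raise IdentifierError(f"unknown drug identifier: {drug_id!r}") from None

    def disease_index(self, disease_id: str) -> int:
        try:
            return self.disease_ids.index(disease_id)
        except ValueError:
            raise IdentifierError(f"unknown disease identifier: {disease_id!r}") from None

    def drug_profile(self, drug_id: str) -> np.ndarray:
        """Binary association profile of a drug over all diseases (a column)."""
        return self.values[:, self.drug_index(drug_id)]

    def disease_profile(self, disease_id: str) -> np.ndarray:
        """Binary association profile of a disease over all drugs (a row)."""
        return self.values[self.disease_index(disease_id), :]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.disease_ids, columns=self.drug_ids)

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            list(self.disease_ids), list(self.drug_ids), self.values.copy()
        )


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity over one entity set, values in [0, 1]."""

    entity_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise FormatError(f"similarity matrix is not square: {self.values.shape}")
        if self.values.shape[0] != len(self.entity_ids):
            raise FormatError(
                f"dimension {self.values.shape[0]} != {len(self.entity_ids)} identifiers"
            )
        _check_unique(self.entity_ids, "entity")
        asym = np.abs(self.values - self.values.T).max() if self.values.size else 0.0
        if asym > SYMMETRY_TOL:
            raise FormatError(f"similarity matrix asymmetric (max |S - S^T| = {asym:.3g})")

    @property
    def n(self) -> int:
        return len(self.entity_ids)

    def index(self, entity_id: str) -> int:
        try:
            return self.entity_ids.index(entity_id)
        except ValueError:
            raise IdentifierError(f"unknown entity identifier: {entity_id!r}") from None

    def row(self, entity_id: str) -> np.ndarray:
        return self.values[self.index(entity_id), :]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.entity_ids, columns=self.entity_ids)

    def copy(self) -> "SimilarityMatrix":
        return SimilarityMatrix(list(self.entity_ids), self.values.copy())


@dataclass
class DrugCatalog:
    """Drug identifiers with (optional) canonical SMILES strings."""

    drug_ids: list[str]
    smiles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.drug_ids, "drug")
        unknown = set(self.smiles) - set(self.drug_ids)
        if unknown:
            raise IdentifierError(f"SMILES given for unknown drugs: {sorted(unknown)}")


def _read_table(path: str | Path, dialect: str = "auto") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        sep: str | None = "\t"
    elif dialect == "csv":
        sep = ","
    elif dialect == "auto":
        sep = None  # sniffed by the python engine
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return pd.read_csv(path, sep=sep, index_col=0, engine="python")


def read_association_matrix(
    path: str | Path, dialect: str = "auto", transpose: bool = False
) -> AssociationMatrix:
    """Read a binary diseases x drugs matrix (set ``transpose`` for drugs x diseases files)."""
    df = _read_table(path, dialect)
    if transpose:
        df = df.T
    raw = df.to_numpy()
    numeric = pd.to_numeric(pd.Series(raw.ravel()), errors="coerce").to_numpy()
    bad = ~np.isin(numeric, (0.0, 1.0)) | np.isnan(numeric)
    if bad.any():
        k = int(np.argwhere(bad)[0][0])
        i, j = divmod(k, raw.shape[1])
        raise FormatError(
            f"non-binary cell {raw[i, j]!r} at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    am = AssociationMatrix(
        [str(x) for x in df.index],
        [str(x) for x in df.columns],
        numeric.reshape(raw.shape).astype(np.int8),
    )
    logger.info(
        "read association matrix: %d diseases, %d drugs, %d associations",
        am.n_diseases, am.n_drugs, am.n_associations,
    )
    return am


def write_association_matrix(am: AssociationMatrix, path: str | Path) -> None:
    am.to_frame().to_csv(path, sep="\t")


def read_similarity_matrix(
    path: str | Path, dialect: str = "auto", on_asymmetric: str = "raise"
) -> SimilarityMatrix:
    """Read a square similarity matrix with matching row/column identifiers.

    Entries just outside [0, 1] (by <= 1e-6) are clipped silently; larger
    excursions are clipped with a warning.  ``on_asymmetric`` selects strict
    behaviour (``"raise"``) or averaging of S and S^T (``"average"``, logged).
    """
    df = _read_table(path, dialect)
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"similarity matrix is not square: {df.shape}")
    rows = [str(x) for x in df.index]
    cols = [str(x) for x in df.columns]
    if rows != cols:
        raise IdentifierError("row and column identifiers of similarity matrix differ")
    values = df.to_numpy(dtype=float)
    excess = max(float((-values).max(initial=0.0)), float((values - 1.0).max(initial=0.0)))
    if excess > CLIP_TOL:
        logger.warning("similarity values outside [0, 1] by up to %.3g; clipping", excess)
    values = np.clip(values, 0.0, 1.0)
    asym = float(np.abs(values - values.T).max()) if values.size else 0.0
    if asym > SYMMETRY_TOL:
        if on_asymmetric == "average":
            logger.warning("asymmetric similarity matrix (max %.3g); averaging with transpose", asym)
            values = (values + values.T) / 2.0
        else:
            raise FormatError(f"similarity matrix asymmetric (max |S - S^T| = {asym:.3g})")
    return SimilarityMatrix(rows, values)


def write_similarity_matrix(sm: SimilarityMatrix, path: str | Path) -> None:
    sm.to_frame().to_csv(path, sep="\t", float_format="%.10g")


def read_drug_catalog(path: str | Path, dialect: str = "auto") -> DrugCatalog:
    """Read a two-column (drug_id, smiles) table; the SMILES cell may be empty."""
    path = Path(path)
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FormatError("drug catalog needs at least two columns: drug_id, smiles")
    ids = [str(x) for x in df.iloc[:, 0]]
    smiles = {i: s for i, s in zip(ids, df.iloc[:, 1]) if s}
    return DrugCatalog(ids, smiles)


def write_ranked_predictions(
    scores: Iterable[tuple[str, str, float]], path: str | Path
) -> None:
    """Write (drug_id, disease_id, score) triples as a rank-ordered TSV.

    Sorted by descending score; ties broken lexicographically by drug_id so
    the output is stable across runs.
    """
    rows = list(scores)
    for drug_id, disease_id, s in rows:
        if not np.isfinite(s):
            raise ValueError(f"non-finite score for pair ({drug_id}, {disease_id}): {s}")
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"score outside [0, 1] for pair ({drug_id}, {disease_id}): {s}")
    rows.sort(key=lambda r: (-r[2], r[0]))
    df = pd.DataFrame(rows, columns=["drug_id", "disease_id", "score"])
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
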