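"""Core tabular containers shared by every pipeline stage.

The three primary artifacts of a cohort are

* :class:`ProteinMatrix` -- a sample x protein intensity grid with an
  explicit processing-state flag (``raw -> log2 -> imputed -> normalized``),
* :class:`ClinicalTable` -- a sample x clinical-feature grid (numeric values
  plus 0/1-encoded categoricals) with a feature-metadata sidecar,
* a label table mapping each sample to its group and cohort.

All three are thin wrappers around :class:`pandas.DataFrame` with validated
invariants and round-trippable plain-text serialization (TSV for protein
intensities, CSV elsewhere; an empty cell denotes a missing value).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedStratifiedKFold, StratifiedKFold

__all__ = [
    "GROUPS",
    "STATES",
    "StratomicError",
    "ConfigError",
    "DataError",
    "ProteinMatrix",
    "ClinicalTable",
    "CohortBundle",
    "CVScheme",
    "read_labels",
    "write_labels",
]

#: Fixed group vocabulary and tie-break order (CTRL < DLP < AT).
GROUPS = ("CTRL", "DLP", "AT")

#: Legal processing states of a protein matrix, in transition order.
STATES = ("raw", "log2", "imputed", "normalized")


class StratomicError(Exception):
    """Base class for all package errors."""


class ConfigError(StratomicError, ValueError):
    """Invalid configuration value."""


class DataError(StratomicError, ValueError):
    """Input data violates a documented precondition."""


def _check_frame(data: pd.DataFrame, what: str) -> pd.DataFrame:
    if not isinstance(data, pd.DataFrame):
        raise DataError(f"{what} must be a pandas DataFrame")
    if data.index.has_duplicates:
        raise DataError(f"{what} has duplicated sample ids")
    if data.columns.has_duplicates:
        raise DataError(f"{what} has duplicated feature ids")
    return data.astype(float)


@dataclass
class ProteinMatrix:
    """Sample x protein intensity grid with explicit missingness.

    ``data`` rows are samples, columns proteins; ``NaN`` marks a missing
    quantification.  ``state`` records how far along the processing chain
    the values are and may only advance in the order given by
    :data:`STATES`; filtering is allowed at any state.
    """

    data: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise DataError(f"unknown processing state {self.state!r}")
        self.data = _check_frame(self.data, "protein matrix")
        if self.state == "raw":
            bad = self.data.le(0)
            if bad.any().any():
                s, p = next(zip(*np.where(bad.to_numpy())))
                raise DataError(
                    "raw intensities must be strictly positive; offending cell "
                    f"sample={self.data.index[s]!r} protein={self.data.columns[p]!r}"
                )
        else:
            vals = self.data.to_numpy()
            if np.isinf(vals).any():
                raise DataError("post-log2 values must be finite")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.data.shape[1]

    def advanced(self, data: pd.DataFrame, state: str) -> "ProteinMatrix":
        """Return a copy at ``state``, enforcing the forward-only order."""
        if STATES.index(state) != STATES.index(self.state) + 1:
            raise DataError(
                f"illegal state transition {self.state!r} -> {state!r}; "
                f"order is {' -> '.join(STATES)}"
            )
        return ProteinMatrix(data, state=state)

    def filtered(self, protein_ids: Sequence[str]) -> "ProteinMatrix":
        return ProteinMatrix(self.data.loc[:, list(protein_ids)], state=self.state)

    # -- plain-text round trip -------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t", na_rep="")

    @classmethod
    def from_tsv(cls, path: str | Path, state: str = "raw") -> "ProteinMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        return cls(df, state=state)


@dataclass
class ClinicalTable:
    """Sample x clinical-feature grid with a feature-metadata sidecar.

    ``meta`` is indexed by feature id and carries a ``type`` column
    (``numeric`` or ``binary``) and an ``excluded`` flag marking columns
    (treatments, imaging-derived values) that must not feed the
    stratification models.
    """

    data: pd.DataFrame
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = _check_frame(self.data, "clinical table")
        if self.meta is None:
            self.meta = pd.DataFrame(
                {"type": "numeric", "excluded": False}, index=self.data.columns
            )
        self.meta = self.meta.reindex(self.data.columns)
        self.meta["type"] = self.meta["type"].fillna("numeric")
        self.meta["excluded"] = self.meta["excluded"].fillna(False).astype(bool)
        for feat in self.meta.index[self.meta["type"] == "binary"]:
            col = self.data[feat].dropna()
            if not col.isin([0.0, 1.0]).all():
                raise DataError(f"binary feature {feat!r} contains values outside {{0,1}}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    def modeling_view(self) -> pd.DataFrame:
        """Feature columns allowed into stratification models."""
        keep = self.meta.index[~self.meta["excluded"]]
        return self.data.loc[:, keep]

    def to_csv(self, path: str | Path, meta_path: str | Path | None = None) -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path, na_rep="")
        if meta_path is not None:
            meta = self.meta.copy()
            meta.index.name = "feature"
            meta.to_csv(meta_path)

    @classmethod
    def from_csv(cls, path: str | Path, meta_path: str | Path | None = None) -> "ClinicalTable":
        df = pd.read_csv(path, index_col="sample_id")
        meta = None
        if meta_path is not None and Path(meta_path).exists():
            meta = pd.read_csv(meta_path, index_col="feature")
        return cls(df, meta)


def write_labels(labels: pd.DataFrame, path: str | Path) -> None:
    out = labels.copy()
    out.index.name = "sample_id"
    out.to_csv(path)


def read_labels(path: str | Path) -> pd.DataFrame:
    labels = pd.read_csv(path, index_col="sample_id")
    bad = set(labels["group"]) - set(GROUPS)
    if bad:
        raise DataError(f"unknown group labels {sorted(bad)}; expected {GROUPS}")
    return labels


@dataclass
class CohortBundle:
    """One cohort: protein intensities, clinical table, and sample labels.

    Sample identifiers must be identical and identically ordered across the
    three members, and every sample carries exactly one group label.
    """

    proteins: ProteinMatrix
    clinical: ClinicalTable
    labels: pd.DataFrame  # index sample_id, columns group, cohort

    def __post_init__(self) -> None:
        ids = self.proteins.sample_ids
        if self.clinical.sample_ids != ids or list(self.labels.index) != ids:
            raise DataError("sample ids differ or are ordered differently across members")
        bad = set(self.labels["group"]) - set(GROUPS)
        if bad:
            raise DataError(f"unknown group labels {sorted(bad)}")

    @property
    def groups(self) -> pd.Series:
        return self.labels["group"]

    def write(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.proteins.to_tsv(d / "proteins.tsv")
        self.clinical.to_csv(d / "clinical.csv", d / "clinical_meta.csv")
        write_labels(self.labels, d / "labels.csv")

    @classmethod
    def read(cls, directory: str | Path, state: str = "raw") -> "CohortBundle":
        d = Path(directory)
        return cls(
            ProteinMatrix.from_tsv(d / "proteins.tsv", state=state),
            ClinicalTable.from_csv(d / "clinical.csv", d / "clinical_meta.csv"),
            read_labels(d / "labels.csv"),
        )


@dataclass(frozen=True)
class CVScheme:
    """Repeated (stratified) k-fold cross-validation layout."""

    n_repeats: int = 3
    n_folds: int = 5
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ConfigError("n_repeats must be >= 1")
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")

    def split(self, y: np.ndarray | pd.Series) -> Iterator[tuple[int, int, np.ndarray, np.ndarray]]:
        """Yield ``(repeat, fold, train_idx, test_idx)`` tuples.

        Raises :class:`DataError` if any class has fewer samples than
        ``n_folds`` (a stratified fold would then miss a class).
        """
        y = np.asarray(y)
        # stratify on first-appearance codes so fold layout is invariant to
        # class-label renaming
        y = pd.factorize(y)[0]
        if self.stratified:
            counts = pd.Series(y).value_counts()
            if (counts < self.n_folds).any():
                small = counts[counts < self.n_folds].index.tolist()
                raise DataError(f"classes {small} have fewer samples than n_folds={self.n_folds}")
            cv = RepeatedStratifiedKFold(
                n_splits=self.n_folds, n_repeats=self.n_repeats, random_state=self.seed
            )
        else:
            cv = RepeatedStratifiedKFold(  # pragma: no cover - stratified is the default
                n_splits=self.n_folds, n_repeats=self.n_repeats, random_state=self.seed
            )
        for i, (tr, te) in enumerate(cv.split(np.zeros_like(y, dtype=float), y)):
            yield i // self.n_folds, i % self.n_folds, tr, te

    def single_repeat(self, seed_offset: int = 0) -> StratifiedKFold:
        return StratifiedKFold(n_splits=self.n_folds, shuffle=True, random_state=self.seed + seed_offset)
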