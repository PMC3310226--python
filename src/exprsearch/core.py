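"""Domain types for the contrast database.

A *contrast* is a single control-vs-treated comparison inside a microarray
experiment, summarised per probe by a log2 fold change and a p-value.  The
database is the searchable collection of contrasts plus the annotation
tables (GO, GenBank→Unigene→probe, gene titles) used by the non-statistical
search modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExprSearchError",
    "FormatError",
    "ValidationError",
    "LoadError",
    "NotFoundError",
    "EmptyResultError",
    "ExpressionMatrix",
    "GroupDefinition",
    "ContrastRecord",
    "AnnotationSet",
    "ContrastDatabase",
    "Signature",
]


class ExprSearchError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(ExprSearchError):
    """A file does not conform to its expected tabular layout."""


class ValidationError(ExprSearchError):
    """An in-memory object violates a domain invariant."""


class LoadError(ExprSearchError):
    """A database directory is missing or corrupt."""


class NotFoundError(ExprSearchError):
    """A requested identifier does not exist."""


class EmptyResultError(ExprSearchError):
    """A query matched nothing that can be searched.

    Carries ``unmatched``: the identifiers that failed to map, when the
    emptiness is due to unmapped input.
    """

    def __init__(self, message: str, unmatched: list[str] | None = None):
        super().__init__(message)
        self.unmatched = list(unmatched) if unmatched else []


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what}: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Probe × sample intensity table for one experiment.

    ``scale`` declares whether ``values`` are raw-scale intensities
    ("linear", strictly positive) or already log2-transformed ("log2",
    the usual gcrma output).
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    experiment_id: str = ""
    scale: str = "log2"

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in ("linear", "log2"):
            raise ValidationError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        _check_unique(self.probe_ids, "probe ID")
        _check_unique(self.sample_ids, "sample ID")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must all be finite")
        if self.scale == "linear" and np.any(self.values <= 0):
            raise ValidationError("linear-scale expression values must be strictly positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    def sample_index(self, sample_ids: list[str]) -> np.ndarray:
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        try:
            return np.array([pos[s] for s in sample_ids], dtype=int)
        except KeyError as e:
            raise ValidationError(f"sample {e.args[0]!r} not in matrix {self.experiment_id!r}")


@dataclass
class GroupDefinition:
    """Assignment of an experiment's samples to control/treated groups.

    One group definition yields one contrast.  The inclusion rule requires
    at least two arrays on each side.
    """

    contrast_id: str
    control_samples: list[str]
    treated_samples: list[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.control_samples or not self.treated_samples:
            raise ValidationError(f"{self.contrast_id}: control and treated sets must be non-empty")
        overlap = set(self.control_samples) & set(self.treated_samples)
        if overlap:
            raise ValidationError(
                f"{self.contrast_id}: samples in both groups: {sorted(overlap)}"
            )

    @property
    def n_control(self) -> int:
        return len(self.control_samples)

    @property
    def n_treated(self) -> int:
        return len(self.treated_samples)

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        known = set(matrix.sample_ids)
        missing = [s for s in self.control_samples + self.treated_samples if s not in known]
        if missing:
            raise ValidationError(
                f"{self.contrast_id}: samples not in matrix "
                f"{matrix.experiment_id!r}: {missing}"
            )


@dataclass
class ContrastRecord:
    """One built contrast: per-probe log2 fold changes and p-values.

    ``fold`` and ``pvalue`` are pandas Series sharing the same probe index;
    missing measurements are NaN.
    """

    contrast_id: str
    study_title: str
    n_control: int
    n_treated: int
    design: str
    fold: pd.Series
    pvalue: pd.Series

    def __post_init__(self) -> None:
        self.fold = pd.Series(self.fold, dtype=float)
        self.pvalue = pd.Series(self.pvalue, dtype=float)
        if not self.fold.index.equals(self.pvalue.index):
            raise ValidationError(f"{self.contrast_id}: fold and pvalue probe indices differ")
        if self.fold.index.has_duplicates:
            raise ValidationError(f"{self.contrast_id}: duplicate probe IDs")
        pv = self.pvalue.dropna()
        if len(pv) and ((pv <= 0).any() or (pv > 1).any()):
            raise ValidationError(f"{self.contrast_id}: p-values must lie in (0, 1]")
        if self.n_control < 2 or self.n_treated < 2:
            raise ValidationError(
                f"{self.contrast_id}: needs >=2 control and >=2 treated arrays "
                f"(got {self.n_control}/{self.n_treated})"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.fold.index)


@dataclass
class AnnotationSet:
    """Annotation tables backing GO / title / GenBank searches.

    ``unknown_probes`` collects probe IDs referenced by annotation rows but
    absent from the database probe universe; they are warnings, never
    silently dropped rows.
    """

    go_terms: dict[int, str] = field(default_factory=dict)
    go2probe: dict[int, set[str]] = field(default_factory=dict)
    genbank2unigene: dict[str, str] = field(default_factory=dict)
    unigene2probe: dict[str, set[str]] = field(default_factory=dict)
    probe_titles: dict[str, str] = field(default_factory=dict)
    unknown_probes: list[str] = field(default_factory=list)

    def flag_unknown(self, probe_universe) -> list[str]:
        """Record annotation probes absent from ``probe_universe``."""
        universe = set(probe_universe)
        unknown: set[str] = set()
        for probes in self.go2probe.values():
            unknown |= probes - universe
        for probes in self.unigene2probe.values():
            unknown |= probes - universe
        unknown |= set(self.probe_titles) - universe
        self.unknown_probes = sorted(unknown)
        return self.unknown_probes


@dataclass
class Signature:
    """An expression signature: ordered (probe_id, log2 fold change) pairs.

    This is both the query object of the profile search and the shape of
    the per-contrast summary a user derives from their own experiment.
    """

    entries: list[tuple[str, float]]

    def __post_init__(self) -> None:
        self.entries = [(str(p), float(f)) for p, f in self.entries]
        if not self.entries:
            raise ValidationError("signature must contain at least one entry")
        _check_unique([p for p, _ in self.entries], "signature probe ID")
        if not all(np.isfinite(f) for _, f in self.entries):
            raise ValidationError("signature fold changes must be finite")

    @property
    def probe_ids(self) -> list[str]:
        return [p for p, _ in self.entries]

    @property
    def folds(self) -> np.ndarray:
        return np.array([f for _, f in self.entries], dtype=float)

    def __len__(self) -> int:
        return len(self.entries)


class ContrastDatabase:
    """The searchable store: contrasts keyed by id over a shared probe universe.

    Fold changes and p-values are exposed as probe × contrast DataFrames
    (``fold_table`` / ``pvalue_table``); a contrast that lacks a probe holds
    NaN there, and every search skips NaN rather than zero-filling.
    """

    def __init__(self, annotations: AnnotationSet | None = None):
        self.records: dict[str, ContrastRecord] = {}
        self.annotations = annotations if annotations is not None else AnnotationSet()
        self._probe_universe: list[str] = []
        self._fold: pd.DataFrame | None = None
        self._pvalue: pd.DataFrame | None = None

    def add_contrast(self, record: ContrastRecord) -> None:
        if record.contrast_id in self.records:
            raise ValidationError(f"duplicate contrast_id {record.contrast_id!r}")
        self.records[record.contrast_id] = record
        known = set(self._probe_universe)
        new = [p for p in record.probe_ids if p not in known]
        if new:
            self._probe_universe.extend(new)
        self._fold = self._pvalue = None

    @property
    def probe_universe(self) -> list[str]:
        return list(self._probe_universe)

    @property
    def contrast_ids(self) -> list[str]:
        return list(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def _build_tables(self) -> None:
        index = pd.Index(self._probe_universe, name="probe_id")
        if not self.records:
            self._fold = pd.DataFrame(index=index)
            self._pvalue = pd.DataFrame(index=index)
            return
        self._fold = pd.DataFrame(
            {cid: rec.fold.reindex(index) for cid, rec in self.records.items()}
        )
        self._pvalue = pd.DataFrame(
            {cid: rec.pvalue.reindex(index) for cid, rec in self.records.items()}
        )

    @property
    def fold_table(self) -> pd.DataFrame:
        if self._fold is None:
            self._build_tables()
        return self._fold

    @property
    def pvalue_table(self) -> pd.DataFrame:
        if self._pvalue is None:
            self._build_tables()
        return self._pvalue

    def study_title(self, contrast_id: str) -> str:
        return self.records[contrast_id].study_title

    def __eq__(self, other) -> bool:
        if not isinstance(other, ContrastDatabase):
            return NotImplemented
        if set(self.records) != set(other.records):
            return False
        for cid, rec in self.records.items():
            o = other.records[cid]
            meta_self = (rec.study_title, rec.n_control, rec.n_treated, rec.design)
            meta_other = (o.study_title, o.n_control, o.n_treated, o.design)
            if meta_self != meta_other:
                return False
        if self._probe_universe != other._probe_universe:
            return False
        # compare values on the shared universe alignment so that a record
        # covering fewer probes than the universe still round-trips equal
        for a, b in (
            (self.fold_table, other.fold_table),
            (self.pvalue_table, other.pvalue_table),
        ):
            b = b.reindex(index=a.index, columns=a.columns)
            av, bv = a.to_numpy(), b.to_numpy()
            same = (av == bv) | (np.isnan(av) & np.isnan(bv))
            if not same.all():
                return False
        ann_a, ann_b = self.annotations, other.annotations
        return (
            ann_a.go_terms == ann_b.go_terms
            and ann_a.go2probe == ann_b.go2probe
            and ann_a.genbank2unigene == ann_b.genbank2unigene
            and ann_a.unigene2probe == ann_b.unigene2probe
            and ann_a.probe_titles == ann_b.probe_titles
        )
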