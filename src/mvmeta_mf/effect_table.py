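"""Sparse multi-factor effect-size tables.

The single data currency of this package is a studies x risk-factors table
of log odds ratios with within-study standard errors, in which each study
reports only a subset of the factors.  Blank cells are *missing*, never
zero: a printed ``0.00`` is an observed estimate.

Two serializations are supported:

* **long** CSV — one row per observed (study, factor) cell with columns
  ``study, factor, log_or, se``;
* **wide** CSV — one row per study, one column per factor, cells written
  as ``"log_or (se)"`` with blanks for unreported factors.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TableFormatError",
    "TableValidationError",
    "FactorDef",
    "EffectEstimate",
    "StudyRecord",
    "EffectTable",
    "load_effect_table",
    "write_effect_table",
    "filter_factors_min_studies",
    "reporting_counts",
]


class TableFormatError(ValueError):
    """A file (or frame) does not conform to the long/wide table layout."""


class TableValidationError(ValueError):
    """A structurally readable table violates an invariant (e.g. se <= 0)."""


@dataclass(frozen=True)
class FactorDef:
    """A coded risk-factor contrast.

    ``contrast`` records the comparison whose log odds ratio is tabulated
    (e.g. ``"yes vs no"``); ``higher_is_risk`` is the orientation flag —
    True means a positive log OR indicates higher recurrence risk for the
    first level of the contrast.
    """

    factor_id: str
    display_name: str
    contrast: str
    higher_is_risk: bool = True

    def __post_init__(self) -> None:
        if not self.factor_id:
            raise TableValidationError("factor_id must be a non-empty token")
        if not self.contrast:
            raise TableValidationError(
                f"factor {self.factor_id!r}: contrast must be non-empty"
            )


@dataclass(frozen=True)
class EffectEstimate:
    """One study's log odds ratio and its within-study standard error."""

    log_or: float
    se: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_or):
            raise TableValidationError(f"log_or must be finite, got {self.log_or!r}")
        if not (math.isfinite(self.se) and self.se > 0):
            raise TableValidationError(f"se must be finite and > 0, got {self.se!r}")


@dataclass(frozen=True)
class StudyRecord:
    """One study's partial mapping of factor_id -> estimate."""

    study_id: str
    citation_label: str
    estimates: Mapping[str, EffectEstimate]

    def __post_init__(self) -> None:
        if not self.study_id:
            raise TableValidationError("study_id must be a non-empty token")
        if len(self.estimates) == 0:
            raise TableValidationError(
                f"study {self.study_id!r} carries no estimates"
            )
        object.__setattr__(self, "estimates", dict(self.estimates))


@dataclass(frozen=True)
class EffectTable:
    """An ordered collection of studies over an ordered list of factors.

    The missingness mask is implied: cell (i, j) is observed iff study i's
    ``estimates`` contains factor j.
    """

    studies: Sequence[StudyRecord]
    factors: Sequence[FactorDef]

    def __post_init__(self) -> None:
        object.__setattr__(self, "studies", tuple(self.studies))
        object.__setattr__(self, "factors", tuple(self.factors))
        fids = [f.factor_id for f in self.factors]
        if len(set(fids)) != len(fids):
            raise TableValidationError("duplicate factor_id in factor list")
        sids = [s.study_id for s in self.studies]
        if len(set(sids)) != len(sids):
            raise TableValidationError("duplicate study_id in study list")
        known = set(fids)
        for s in self.studies:
            unknown = set(s.estimates) - known
            if unknown:
                raise TableValidationError(
                    f"study {s.study_id!r} references undeclared factors {sorted(unknown)}"
                )

    # -- basic shape ---------------------------------------------------

    @property
    def factor_ids(self) -> list[str]:
        return [f.factor_id for f in self.factors]

    @property
    def study_ids(self) -> list[str]:
        return [s.study_id for s in self.studies]

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    def factor(self, factor_id: str) -> FactorDef:
        for f in self.factors:
            if f.factor_id == factor_id:
                return f
        raise KeyError(f"unknown factor {factor_id!r}")

    def study(self, study_id: str) -> StudyRecord:
        for s in self.studies:
            if s.study_id == study_id:
                return s
        raise KeyError(f"unknown study {study_id!r}")

    # -- matrix views ---------------------------------------------------

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean studies x factors frame: True where the cell is observed."""
        data = [
            [fid in s.estimates for fid in self.factor_ids] for s in self.studies
        ]
        return pd.DataFrame(data, index=self.study_ids, columns=self.factor_ids)

    @property
    def log_or(self) -> pd.DataFrame:
        """Studies x factors frame of log ORs, NaN where unreported."""
        return self._matrix("log_or")

    @property
    def se(self) -> pd.DataFrame:
        """Studies x factors frame of standard errors, NaN where unreported."""
        return self._matrix("se")

    def _matrix(self, attr: str) -> pd.DataFrame:
        data = [
            [
                getattr(s.estimates[fid], attr) if fid in s.estimates else np.nan
                for fid in self.factor_ids
            ]
            for s in self.studies
        ]
        return pd.DataFrame(
            data, index=self.study_ids, columns=self.factor_ids, dtype=float
        )

    def column(self, factor_id: str) -> list[tuple[str, EffectEstimate]]:
        """Observed (study_id, estimate) pairs for one factor, in study order."""
        self.factor(factor_id)
        return [
            (s.study_id, s.estimates[factor_id])
            for s in self.studies
            if factor_id in s.estimates
        ]

    # -- editing --------------------------------------------------------

    def without_cells(self, cells: Iterable[tuple[str, str]]) -> "EffectTable":
        """Drop individual (study_id, factor_id) cells (exclusion list).

        Studies left with no estimates are removed; the factor list is kept
        as-is.  Unknown cells raise ``KeyError``.
        """
        drop = set(cells)
        for sid, fid in drop:
            if fid not in self.study(sid).estimates:
                raise KeyError(f"cell ({sid!r}, {fid!r}) is not observed")
        studies = []
        for s in self.studies:
            est = {
                fid: e for fid, e in s.estimates.items() if (s.study_id, fid) not in drop
            }
            if est:
                studies.append(replace(s, estimates=est))
        return EffectTable(studies=studies, factors=self.factors)

    def subset_factors(self, factor_ids: Sequence[str]) -> "EffectTable":
        """Keep only the named factors (in the table's original order)."""
        keep = set(factor_ids)
        unknown = keep - set(self.factor_ids)
        if unknown:
            raise KeyError(f"unknown factors {sorted(unknown)}")
        factors = [f for f in self.factors if f.factor_id in keep]
        studies = []
        for s in self.studies:
            est = {fid: e for fid, e in s.estimates.items() if fid in keep}
            if est:
                studies.append(replace(s, estimates=est))
        return EffectTable(studies=studies, factors=factors)

    # -- serialization --------------------------------------------------

    def to_long_frame(self) -> pd.DataFrame:
        rows = [
            (s.study_id, fid, e.log_or, e.se)
            for s in self.studies
            for fid, e in ((f, s.estimates[f]) for f in self.factor_ids if f in s.estimates)
        ]
        return pd.DataFrame(rows, columns=["study", "factor", "log_or", "se"])

    def to_wide_frame(self) -> pd.DataFrame:
        def cell(s: StudyRecord, fid: str) -> str:
            if fid not in s.estimates:
                return ""
            e = s.estimates[fid]
            return f"{e.log_or:.10g} ({e.se:.10g})"

        data = {
            fid: [cell(s, fid) for s in self.studies] for fid in self.factor_ids
        }
        frame = pd.DataFrame(data, index=pd.Index(self.study_ids, name="study"))
        return frame


_WIDE_CELL_RE = re.compile(r"^\s*([^\s(]+)\s*\(\s*([^\s)]+)\s*\)\s*$")


def _to_float(token: object, where: str) -> float:
    if isinstance(token, (int, float, np.floating)):
        val = float(token)
    else:
        text = str(token).strip().replace("−", "-").replace("‐", "-")
        try:
            val = float(text)
        except ValueError:
            raise TableValidationError(f"{where}: non-numeric value {token!r}") from None
    return val


def _estimate(log_or: object, se: object, where: str) -> EffectEstimate:
    y = _to_float(log_or, where)
    s = _to_float(se, where)
    if not math.isfinite(y):
        raise TableValidationError(f"{where}: log_or must be finite, got {y!r}")
    if not (math.isfinite(s) and s > 0):
        raise TableValidationError(f"{where}: se must be > 0, got {s!r}")
    return EffectEstimate(log_or=y, se=s)


def _default_factor(fid: str) -> FactorDef:
    return FactorDef(factor_id=fid, display_name=fid, contrast="as coded")


def table_from_long_frame(
    frame: pd.DataFrame, factors: Sequence[FactorDef] | None = None
) -> EffectTable:
    """Build a table from a long frame with columns study/factor/log_or/se."""
    required = ["study", "factor", "log_or", "se"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise TableFormatError(f"long layout requires columns {required}, missing {missing}")
    seen: set[tuple[str, str]] = set()
    order: list[str] = []
    factor_order: list[str] = []
    records: dict[str, dict[str, EffectEstimate]] = {}
    for row in frame.itertuples(index=False):
        sid, fid = str(row.study), str(row.factor)
        if (sid, fid) in seen:
            raise TableFormatError(f"duplicate cell for study {sid!r}, factor {fid!r}")
        seen.add((sid, fid))
        if sid not in records:
            records[sid] = {}
            order.append(sid)
        if fid not in factor_order:
            factor_order.append(fid)
        records[sid][fid] = _estimate(
            row.log_or, row.se, f"study {sid!r}, factor {fid!r}"
        )
    if not records:
        raise TableFormatError("table contains no cells")
    if factors is None:
        factors = [_default_factor(fid) for fid in factor_order]
    studies = [
        StudyRecord(study_id=sid, citation_label=sid, estimates=records[sid])
        for sid in order
    ]
    return EffectTable(studies=studies, factors=factors)


def table_from_wide_frame(
    frame: pd.DataFrame, factors: Sequence[FactorDef] | None = None
) -> EffectTable:
    """Build a table from a wide frame ('log_or (se)' cells, blanks allowed)."""
    if frame.index.name != "study":
        if "study" in frame.columns:
            frame = frame.set_index("study")
        else:
            raise TableFormatError("wide layout requires a 'study' column or index")
    factor_order = [str(c) for c in frame.columns]
    studies = []
    for sid, row in frame.iterrows():
        est: dict[str, EffectEstimate] = {}
        for fid in factor_order:
            raw = row[fid]
            if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                continue
            text = str(raw).strip()
            if not text:
                continue
            m = _WIDE_CELL_RE.match(text)
            if m is None:
                raise TableFormatError(
                    f"study {sid!r}, factor {fid!r}: cell {text!r} is not 'log_or (se)'"
                )
            est[fid] = _estimate(m.group(1), m.group(2), f"study {sid!r}, factor {fid!r}")
        if est:
            studies.append(StudyRecord(study_id=str(sid), citation_label=str(sid), estimates=est))
    if not studies:
        raise TableFormatError("table contains no cells")
    if factors is None:
        factors = [_default_factor(fid) for fid in factor_order]
    return EffectTable(studies=studies, factors=factors)


def load_effect_table(
    path: str | Path,
    layout: str = "long",
    factors: Sequence[FactorDef] | None = None,
) -> EffectTable:
    """Read an effect table from CSV.

    Parameters
    ----------
    path : file path
    layout : {"long", "wide"}
    factors : optional factor definitions; by default minimal definitions
        are synthesized from the factor tokens found in the file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout == "long":
        frame = pd.read_csv(path, dtype={"study": str, "factor": str})
        return table_from_long_frame(frame, factors=factors)
    if layout == "wide":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        return table_from_wide_frame(frame, factors=factors)
    raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")


def write_effect_table(table: EffectTable, path: str | Path, layout: str = "long") -> None:
    """Write a table to CSV in the requested layout (round-trip safe)."""
    path = Path(path)
    if layout == "long":
        table.to_long_frame().to_csv(path, index=False)
    elif layout == "wide":
        table.to_wide_frame().to_csv(path, index=True)
    else:
        raise ValueError(f"layout must be 'long' or 'wide', got {layout!r}")


def reporting_counts(table: EffectTable) -> pd.Series:
    """Number of reporting studies per factor, in factor order.

    Note that for the built-in early-glottic dataset these counts are the
    tallies of the printed table and are known to exceed the study counts
    the original multivariate fit quotes for a handful of factors (ACI 9
    vs 8, T substage 7 vs 6, among others); see
    :data:`mvmeta_mf.datasets.TABLE2_STUDY_COUNTS`.
    """
    return table.mask.sum(axis=0)


def filter_factors_min_studies(table: EffectTable, k: int) -> EffectTable:
    """Keep factors reported by at least ``k`` studies.

    Studies left with no remaining estimates are dropped; original study
    and factor ordering is preserved.  Idempotent for fixed ``k``.
    """
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise ValueError(f"k must be an integer >= 1, got {k!r}")
    counts = reporting_counts(table)
    keep = [fid for fid in table.factor_ids if counts[fid] >= k]
    return table.subset_factors(keep)
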