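"""Plain-text tabular I/O for abundance matrices, sample designs and result tables.

All inputs and outputs are delimited text (``.tsv`` tab, ``.csv`` comma).
Missing values are empty cells or ``NA``; zeros are measured zeros, never
missing — data-independent acquisition reports absent precursors as blank
cells, so a literal 0 carries information and is kept.

Feature identifiers are opaque strings (gene symbols, metabolite feature
IDs); no accession parsing is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sample roles understood by the design table
ROLE_BIOLOGICAL = "biological"
ROLE_POOLED_QC = "pooled_qc"
ROLE_PROCESS_STANDARD = "process_standard"
_ROLES = {ROLE_BIOLOGICAL, ROLE_POOLED_QC, ROLE_PROCESS_STANDARD}

_NA_VALUES = ["", "NA"]


class ValidationError(ValueError):
    """Raised when an input table violates its contract."""


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


@dataclass
class SampleDesign:
    """Assignment of sample IDs to condition labels, pairing indices and roles.

    The underlying frame has columns ``sample_id``, ``condition``,
    ``replicate_index`` and ``role``.  ``replicate_index`` is the pairing key
    for paired comparisons: probe replicate *i* is matched with vehicle
    replicate *i* (same culture batch).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample_id", "condition", "replicate_index", "role"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValidationError(f"sample design missing columns: {missing}")
        t = self.table
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample_id(s): {dup}")
        bad_roles = set(t["role"]) - _ROLES
        if bad_roles:
            raise ValidationError(f"unknown role(s): {sorted(bad_roles)}")
        bio = t[t["role"] == ROLE_BIOLOGICAL]
        if bio["condition"].isna().any() or (bio["condition"] == "").any():
            raise ValidationError("biological sample without a condition label")
        if bio["replicate_index"].isna().any():
            raise ValidationError("biological sample without a replicate_index")
        # pairing key must be unique within a condition
        dup = bio.duplicated(subset=["condition", "replicate_index"])
        if dup.any():
            rows = bio.loc[dup, ["condition", "replicate_index"]]
            raise ValidationError(
                f"replicate_index repeated within a condition:\n{rows}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def conditions(self) -> list[str]:
        bio = self.table[self.table["role"] == ROLE_BIOLOGICAL]
        return sorted(bio["condition"].unique())

    def samples_for(self, condition: str) -> pd.DataFrame:
        """Biological samples of one condition, sorted by replicate_index."""
        t = self.table
        sel = t[(t["role"] == ROLE_BIOLOGICAL) & (t["condition"] == condition)]
        return sel.sort_values("replicate_index")

    def qc_sample_ids(self) -> list[str]:
        t = self.table
        return t.loc[t["role"] == ROLE_POOLED_QC, "sample_id"].tolist()

    @classmethod
    def read(cls, path: str | Path) -> "SampleDesign":
        df = pd.read_csv(
            path, sep=_sep_for(path), dtype={"sample_id": str, "condition": str},
            keep_default_na=False, na_values=_NA_VALUES,
        )
        if "replicate_index" in df.columns:
            df["replicate_index"] = pd.to_numeric(df["replicate_index"], errors="coerce")
        return cls(df.reset_index(drop=True))

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep=_sep_for(path), index=False, na_rep="NA")


@dataclass
class AbundanceMatrix:
    """Nonnegative feature x sample intensity matrix; NaN marks missing.

    ``data`` is features-in-rows, samples-in-columns.  ``scale`` is ``"raw"``
    (linear intensities) or ``"log2"``.
    """

    data: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate feature_id(s): {dup}")
        self.data = self.data.astype(float)
        if self.scale == "raw":
            vals = self.data.to_numpy()
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValidationError("raw-scale intensities must be >= 0")

    @property
    def feature_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    def all_missing_features(self) -> list[str]:
        mask = self.data.isna().all(axis=1)
        return self.data.index[mask].tolist()

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.data.copy(), self.scale)


#: metabolite identification confidence tiers, most to least confident
ANNOTATION_LEVELS = ("L1", "L2", "L3", "unannotated")


@dataclass
class MetaboliteTable:
    """AbundanceMatrix plus per-feature annotation metadata.

    ``annotations`` is indexed by feature_id with columns ``metabolite_name``,
    ``annotation_level`` (L1/L2/L3/unannotated) and ``qc_cv`` (pooled-QC
    coefficient of variation as a fraction, NaN until computed).
    """

    matrix: AbundanceMatrix
    annotations: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        idx = self.matrix.data.index
        if self.annotations is None:
            self.annotations = pd.DataFrame(index=idx)
        ann = self.annotations.reindex(idx)
        if "metabolite_name" not in ann.columns:
            ann["metabolite_name"] = pd.Series(idx, index=idx)
        if "annotation_level" not in ann.columns:
            ann["annotation_level"] = "unannotated"
        ann["annotation_level"] = ann["annotation_level"].fillna("unannotated")
        bad = set(ann["annotation_level"]) - set(ANNOTATION_LEVELS)
        if bad:
            raise ValidationError(f"unknown annotation level(s): {sorted(bad)}")
        if "qc_cv" not in ann.columns:
            ann["qc_cv"] = np.nan
        if (ann["qc_cv"].dropna() < 0).any():
            raise ValidationError("qc_cv must be >= 0")
        self.annotations = ann

    @property
    def feature_ids(self) -> list[str]:
        return self.matrix.feature_ids

    def subset(self, feature_ids: list[str]) -> "MetaboliteTable":
        return MetaboliteTable(
            AbundanceMatrix(self.matrix.data.loc[feature_ids], self.matrix.scale),
            self.annotations.loc[feature_ids],
        )


def _coerce_numeric(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    """Convert value columns to float, reporting the first offending cell."""
    out = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise ValidationError(
                f"{path}: non-numeric value {df.loc[row, col]!r} "
                f"at feature {row!r}, column {col!r}"
            )
        out[col] = converted
    return pd.DataFrame(out, index=df.index)


def read_abundance_table(
    path: str | Path,
    design: SampleDesign,
    orientation: str = "wide",
) -> AbundanceMatrix:
    """Read a raw-scale feature x sample table restricted to designed samples.

    ``wide``: first column holds feature IDs, remaining columns are samples.
    ``long``: three columns (feature, sample, value).  Columns/samples absent
    from the design are dropped with a warning; duplicate (feature, sample)
    entries in long format are an error.  Features whose row is all-missing
    are retained (and can be listed via ``AbundanceMatrix.all_missing_features``).
    """
    sep = _sep_for(path)
    known = set(design.sample_ids)
    if orientation == "wide":
        df = pd.read_csv(path, sep=sep, keep_default_na=False, na_values=_NA_VALUES)
        feat_col = df.columns[0]
        df = df.set_index(feat_col)
        df.index = df.index.astype(str)
        df.index.name = None
        extra = [c for c in df.columns if c not in known]
        if extra:
            logger.warning(
                "%s: dropping %d sample column(s) absent from design: %s",
                path, len(extra), extra,
            )
            df = df.drop(columns=extra)
        df = _coerce_numeric(df, path)
    elif orientation == "long":
        raw = pd.read_csv(path, sep=sep, keep_default_na=False, na_values=_NA_VALUES)
        if raw.shape[1] < 3:
            raise ValidationError(f"{path}: long format needs 3 columns")
        raw.columns = ["feature", "sample", "value", *raw.columns[3:]]
        dup = raw.duplicated(subset=["feature", "sample"])
        if dup.any():
            pair = raw.loc[dup, ["feature", "sample"]].iloc[0].tolist()
            raise ValidationError(f"{path}: duplicate (feature, sample) entry {pair}")
        extra = sorted(set(raw["sample"].astype(str)) - known)
        if extra:
            logger.warning(
                "%s: dropping %d sample(s) absent from design: %s",
                path, len(extra), extra,
            )
            raw = raw[~raw["sample"].astype(str).isin(extra)]
        df = raw.pivot(index="feature", columns="sample", values="value")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        df.columns.name = None
        df.index.name = None
        df = _coerce_numeric(df, path)
    else:
        raise ValidationError(f"unknown orientation {orientation!r}")
    # preserve design order for the samples that are present
    order = [s for s in design.sample_ids if s in df.columns]
    mat = AbundanceMatrix(df[order], scale="raw")
    empty = mat.all_missing_features()
    if empty:
        logger.warning("%s: %d feature(s) with all values missing", path, len(empty))
    return mat


def read_metabolite_table(path: str | Path, design: SampleDesign) -> MetaboliteTable:
    """Read a wide metabolite table with optional annotation columns.

    Columns named ``metabolite_name`` / ``annotation_level`` / ``qc_cv`` are
    captured as metadata; columns matching designed sample IDs are
    intensities; anything else is dropped with a warning.
    """
    sep = _sep_for(path)
    df = pd.read_csv(path, sep=sep, keep_default_na=False, na_values=_NA_VALUES)
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    meta_cols = [c for c in ("metabolite_name", "annotation_level", "qc_cv") if c in df.columns]
    ann = df[meta_cols].copy() if meta_cols else None
    df = df.drop(columns=meta_cols)
    known = set(design.sample_ids)
    extra = [c for c in df.columns if c not in known]
    if extra:
        logger.warning("%s: dropping non-sample column(s): %s", path, extra)
        df = df.drop(columns=extra)
    df = _coerce_numeric(df, path)
    order = [s for s in design.sample_ids if s in df.columns]
    if ann is not None and "qc_cv" in ann.columns:
        ann["qc_cv"] = pd.to_numeric(ann["qc_cv"], errors="coerce")
    return MetaboliteTable(AbundanceMatrix(df[order], scale="raw"), ann)


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table (one row per feature) as delimited text.

    Values round-trip at full ``repr`` precision; NaN is written as ``NA``.
    """
    table.to_csv(path, sep=_sep_for(path), index=False, na_rep="NA")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep_for(path), keep_default_na=False,
                       na_values=_NA_VALUES)
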