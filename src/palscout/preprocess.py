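"""Normalization, log transformation and QC filtering applied before statistics.

The processing order mirrors standard enrichment-proteomics practice: global
median normalization on raw intensities, then log2.  Zeros become missing on
log2 (no pseudocount), which keeps the complete-pair rule of the paired t-test
well defined; no imputation is performed anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tables import (
    AbundanceMatrix,
    MetaboliteTable,
    SampleDesign,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: default pooled-QC CV ceiling for metabolite features (fraction)
DEFAULT_QC_CV_MAX = 0.25
#: QA ceilings for process-standard and instrument variability (fractions)
DEFAULT_PROCESS_CV_MAX = 0.20
DEFAULT_INSTRUMENT_CV_MAX = 0.10


def global_median_normalize(m: AbundanceMatrix) -> AbundanceMatrix:
    """Scale each sample so its median matches the global median of medians.

    Each sample's non-missing values are multiplied by a single factor; after
    normalization every per-sample median equals the median of the input's
    per-sample medians.  Missing cells stay missing.  Idempotent, and
    equivariant under global rescaling of the matrix.
    """
    if m.scale != "raw":
        raise ValidationError("global_median_normalize expects a raw-scale matrix")
    medians = m.data.median(axis=0, skipna=True)
    empty = medians.index[medians.isna()].tolist()
    if empty:
        raise ValidationError(f"sample(s) with no non-missing values: {empty}")
    target = float(np.median(medians.to_numpy()))
    factors = target / medians
    out = m.data.mul(factors, axis=1)
    return AbundanceMatrix(out, scale="raw")


def log2_transform(m: AbundanceMatrix) -> AbundanceMatrix:
    """log2-transform a raw matrix; zeros become missing (no pseudocount)."""
    if m.scale == "log2":
        raise ValidationError("matrix is already log2-scale (double transform)")
    vals = m.data.to_numpy(copy=True)
    n_zero = int(np.nansum(vals == 0))
    if n_zero:
        logger.info("log2_transform: %d zero cell(s) set to missing", n_zero)
    with np.errstate(divide="ignore"):
        out = np.where(vals > 0, np.log2(np.where(vals > 0, vals, 1.0)), np.nan)
    return AbundanceMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns),
        scale="log2",
    )


def compute_cv(values) -> float:
    """Coefficient of variation: sample (n-1) standard deviation over mean.

    Computed on the raw intensity scale.  Requires at least two non-missing
    values and a nonzero mean.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        raise ValidationError("compute_cv needs at least 2 non-missing values")
    mean = arr.mean()
    if mean == 0:
        raise ValidationError("compute_cv undefined for mean 0")
    return float(arr.std(ddof=1) / mean)


@dataclass
class QCReport:
    """Per-feature pooled-QC CVs and per-standard QA CVs with pass flags."""

    qc_cv: pd.Series                       # per-feature pooled-QC CV
    cv_max: float
    feature_pass: pd.Series = field(default=None)  # type: ignore[assignment]
    process_cv: pd.Series | None = None    # per process standard
    instrument_cv: pd.Series | None = None
    process_cv_max: float = DEFAULT_PROCESS_CV_MAX
    instrument_cv_max: float = DEFAULT_INSTRUMENT_CV_MAX

    def __post_init__(self) -> None:
        if self.feature_pass is None:
            # strictly-greater CVs fail; undefined CVs pass by convention
            self.feature_pass = ~(self.qc_cv > self.cv_max)

    @property
    def process_pass(self) -> pd.Series | None:
        if self.process_cv is None:
            return None
        return ~(self.process_cv > self.process_cv_max)

    @property
    def instrument_pass(self) -> pd.Series | None:
        if self.instrument_cv is None:
            return None
        return ~(self.instrument_cv > self.instrument_cv_max)

    @property
    def n_removed(self) -> int:
        return int((~self.feature_pass).sum())


def qc_filter_metabolites(
    t: MetaboliteTable,
    design: SampleDesign,
    cv_max: float = DEFAULT_QC_CV_MAX,
) -> tuple[MetaboliteTable, QCReport]:
    """Drop features whose pooled-QC CV exceeds ``cv_max`` (strictly).

    The CV is computed on raw-scale intensities of the pooled-QC injections.
    Features whose QC CV cannot be computed (fewer than two QC values) are
    retained and flagged with a missing CV.  Returns the filtered table and a
    report listing every feature's CV and pass flag.
    """
    qc_ids = design.qc_sample_ids()
    if not qc_ids:
        raise ValidationError("design contains no pooled_qc samples")
    qc_cols = [s for s in qc_ids if s in t.matrix.sample_ids]
    if not qc_cols:
        raise ValidationError("no pooled_qc sample columns present in the table")
    if t.matrix.scale != "raw":
        raise ValidationError("qc_filter_metabolites expects raw-scale intensities")

    qc = t.matrix.data[qc_cols]
    cvs = {}
    for fid, row in qc.iterrows():
        try:
            cvs[fid] = compute_cv(row.to_numpy())
        except ValidationError:
            cvs[fid] = np.nan
    cv_series = pd.Series(cvs, name="qc_cv")
    report = QCReport(qc_cv=cv_series, cv_max=cv_max)
    keep = report.feature_pass[report.feature_pass].index.tolist()
    removed = report.feature_pass[~report.feature_pass].index.tolist()
    if removed:
        logger.info(
            "qc_filter_metabolites: removed %d/%d features with QC CV > %.3g",
            len(removed), len(cv_series), cv_max,
        )
    out = t.subset(keep)
    out.annotations["qc_cv"] = cv_series.loc[keep]
    return out, report
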