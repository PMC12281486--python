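"""Enrichment and specificity calling for competition photoaffinity labeling.

The decision procedure has two stages.  Stage 1 (probe vs vehicle): the bulk
of the log2 fold-change distribution is assumed to be a null Gaussian; a
nonlinear least-squares fit of the fold-change histogram yields (A, mu,
sigma), the fold-change cutoff is set at x0 = mu + 1*sigma, and a reciprocal
(hyperbolic) significance curve

    y > c / (x - x0),   x > x0

with curvature c = 0.8 selects enriched features on the volcano plot
(x = log2 fold change, y = -log10 p).  Stage 2 (probe vs competition): among
stage-1 enriched features, q-values are recomputed by the two-stage step-up
FDR over that subset, and a feature is called *specific* when q < 0.05 and
its probe-over-competition log2 fold change exceeds 1 — i.e. its enrichment
is lost when the parent compound competes for the binding site.  Enriched
features that survive competition are *nonspecific* binders.

All thresholds are strict inequalities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .diffstats import adjust_pvalues
from .io_tables import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_CURVATURE = 0.8
DEFAULT_SIGMA_MULTIPLIER = 1.0
DEFAULT_Q_MAX = 0.05
DEFAULT_MIN_X_COMPETITION = 1.0
MIN_FIT_VALUES = 50

CALL_SPECIFIC = "specific"
CALL_NONSPECIFIC = "nonspecific"
CALL_NOT_ENRICHED = "not_enriched"


@dataclass
class GaussianFit:
    """Least-squares Gaussian fit of a fold-change histogram."""

    amplitude: float
    mu: float
    sigma: float
    rss: float
    converged: bool
    n_bins: int

    def __post_init__(self) -> None:
        if self.converged and not self.sigma > 0:
            raise ValidationError("converged fit must have sigma > 0")
        if self.rss < 0:
            raise ValidationError("rss must be >= 0")


@dataclass
class CurveParams:
    """Reciprocal significance-curve parameters: y > c/(x - x0) for x > x0."""

    c: float = DEFAULT_CURVATURE
    x0: float = 0.0

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValidationError("curvature c must be > 0")
        if not np.isfinite(self.x0):
            raise ValidationError("x0 must be finite")


def _gauss(x, amplitude, mu, sigma):
    return amplitude * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_fc_gaussian(x_values, n_bins: int | None = None) -> GaussianFit:
    """Fit count ~ A*exp(-(x-mu)^2/(2 sigma^2)) to the fold-change histogram.

    Binning is Freedman-Diaconis (at least 20 bins) unless ``n_bins`` is
    given.  Initialization: A = max bin count, mu = sample median,
    sigma = sample standard deviation.  On non-convergence the fit falls back
    to a robust sigma (1.4826 * MAD) with ``converged = False``.
    """
    x = np.asarray(x_values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < MIN_FIT_VALUES:
        raise ValidationError(
            f"fit_fc_gaussian needs >= {MIN_FIT_VALUES} finite values, got {x.size}"
        )
    if n_bins is None:
        edges = np.histogram_bin_edges(x, bins="fd")
        if edges.size - 1 < 20:
            edges = np.histogram_bin_edges(x, bins=20)
    else:
        edges = np.histogram_bin_edges(x, bins=int(n_bins))
    counts, edges = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = (float(counts.max()), float(np.median(x)), float(x.std(ddof=1)))
    try:
        import warnings

        with np.errstate(divide="ignore", invalid="ignore"), \
                warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _gauss, centers, counts, p0=p0, xtol=1e-8, maxfev=1000 * 4
            )
        a, mu, sigma = popt
        sigma = abs(float(sigma))
        if sigma == 0 or not np.all(np.isfinite(popt)):
            raise RuntimeError("degenerate fit")
        rss = float(np.sum((counts - _gauss(centers, a, mu, sigma)) ** 2))
        return GaussianFit(float(a), float(mu), sigma, rss, True, counts.size)
    except RuntimeError:
        mad = np.median(np.abs(x - np.median(x)))
        sigma = 1.4826 * float(mad)
        logger.warning(
            "fit_fc_gaussian did not converge; falling back to robust "
            "sigma = %.4g", sigma,
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            fitted = _gauss(centers, p0[0], np.median(x), sigma)
        rss = float(np.nansum((counts - fitted) ** 2))
        return GaussianFit(p0[0], float(np.median(x)), sigma, rss, False, counts.size)


def curve_pass(x, y, params: CurveParams):
    """True iff the volcano point clears the reciprocal curve.

    Enrichment-side only: requires x > x0 and y > c/(x - x0).  Accepts
    scalars or arrays; the boundary x = x0 never passes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        dx = x - params.x0
        ok = (dx > 0) & (y * dx > params.c)
    if ok.ndim == 0:
        return bool(ok)
    return ok


def enriched_set(
    res: pd.DataFrame,
    fit: GaussianFit,
    c: float = DEFAULT_CURVATURE,
    sigma_multiplier: float = DEFAULT_SIGMA_MULTIPLIER,
) -> set[str]:
    """Features passing the curve with x0 = mu + sigma_multiplier * sigma."""
    params = CurveParams(c=c, x0=fit.mu + sigma_multiplier * fit.sigma)
    ok = curve_pass(res["log2fc"].to_numpy(), res["neglog10p"].to_numpy(), params)
    return set(res.loc[ok, "feature_id"])


def classify_targets(
    probe_vs_vehicle: pd.DataFrame,
    probe_vs_competition: pd.DataFrame,
    c: float = DEFAULT_CURVATURE,
    sigma_multiplier: float = DEFAULT_SIGMA_MULTIPLIER,
    q_max: float = DEFAULT_Q_MAX,
    min_x_comp: float = DEFAULT_MIN_X_COMPETITION,
    n_bins: int | None = None,
    stage1_q_max: float | None = None,
    competition_fdr_scope: str = "enriched",
    fdr_method: str = "bky",
) -> tuple[pd.DataFrame, GaussianFit]:
    """Two-stage classification into specific / nonspecific / not_enriched.

    Stage 1 fits the Gaussian to all probe-vs-vehicle fold changes and keeps
    curve-passing features (optionally also gated on the stage-1 q-value when
    ``stage1_q_max`` is set).  Stage 2 recomputes the FDR over the enriched
    subset's probe-vs-competition p-values (``competition_fdr_scope =
    "enriched"``, the default) or reuses the global q-values (``"all"``), and
    calls a feature specific iff q < q_max and probe-over-competition log2
    fold change > min_x_comp.

    Returns (calls, stage-1 GaussianFit); calls has one row per feature of
    the outer-joined universe.
    """
    fit = fit_fc_gaussian(probe_vs_vehicle["log2fc"].to_numpy(), n_bins=n_bins)
    enriched = enriched_set(probe_vs_vehicle, fit, c=c,
                            sigma_multiplier=sigma_multiplier)
    if stage1_q_max is not None:
        qpass = set(
            probe_vs_vehicle.loc[
                probe_vs_vehicle["q"] < stage1_q_max, "feature_id"
            ]
        )
        enriched &= qpass
    if not enriched:
        logger.warning("classify_targets: stage-1 enriched set is empty")

    pv = probe_vs_vehicle.set_index("feature_id")
    pc = probe_vs_competition.set_index("feature_id")
    universe = pv.index.union(pc.index)

    if competition_fdr_scope == "enriched":
        sub = pc.loc[pc.index.intersection(sorted(enriched))]
        if len(sub):
            q_sub, _ = adjust_pvalues(sub["p"].to_numpy(), method=fdr_method,
                                      alpha=q_max)
            q_comp = pd.Series(q_sub, index=sub.index)
        else:
            q_comp = pd.Series(dtype=float)
    elif competition_fdr_scope == "all":
        q_comp = pc["q"]
    else:
        raise ValidationError(
            f"unknown competition_fdr_scope {competition_fdr_scope!r}"
        )

    x_pv = pv["log2fc"].reindex(universe)
    y_pv = pv["neglog10p"].reindex(universe)
    x_pc = pc["log2fc"].reindex(universe)
    q_pc = q_comp.reindex(universe)
    is_enriched = universe.isin(enriched)
    competed = (
        (q_pc < q_max) & (x_pc > min_x_comp)
    ).fillna(False).to_numpy()
    call = np.where(
        ~is_enriched,
        CALL_NOT_ENRICHED,
        # enriched but retained under competition (or untestable there)
        np.where(competed, CALL_SPECIFIC, CALL_NONSPECIFIC),
    )
    calls = pd.DataFrame(
        {
            "feature_id": universe,
            "call": call,
            "x_probe_vehicle": x_pv.to_numpy(),
            "y_probe_vehicle": y_pv.to_numpy(),
            "x_probe_competition": x_pc.to_numpy(),
            "q_probe_competition": q_pc.to_numpy(),
        }
    ).reset_index(drop=True)
    return calls, fit
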