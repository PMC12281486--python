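"""Per-feature differential statistics and multiple-testing correction.

Two test families are provided: a paired Student t-test across matched
replicates (the enrichment-proteomics design, where probe replicate *i* and
vehicle replicate *i* come from the same culture batch) and an unpaired Welch
t-test (the metabolomics group design).  Both are two-sided and run on
log2-scale abundances.

FDR control uses the two-stage linear step-up procedure of Benjamini, Krieger
& Yekutieli (2006): a first Benjamini-Hochberg pass at level a/(1+a) estimates
the number of true nulls m0, and a second BH pass runs at the inflated level
a*m/m0.  The adaptive second stage makes the procedure uniformly no less
powerful than plain BH whenever some nulls are false.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import AbundanceMatrix, SampleDesign, ValidationError

logger = logging.getLogger(__name__)

#: smallest reported p-value; keeps -log10(p) finite for zero-variance,
#: nonzero-mean differences
P_FLOOR = 1e-300

RESULT_COLUMNS = ["feature_id", "log2fc", "p", "neglog10p", "q", "n_used"]


def paired_t_test(a, b, pairing=None) -> tuple[float, float]:
    """Two-sided paired Student t-test on differences a - b.

    ``pairing`` optionally gives (index_a, index_b) tuples; by default the
    arrays are paired positionally.  Pairs with a missing member are dropped.
    Returns (t, p); p = 1 when all differences are exactly zero, and p is
    floored at ``P_FLOOR`` when the differences are constant but nonzero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if pairing is not None:
        ia, ib = zip(*pairing)
        a, b = a[list(ia)], b[list(ib)]
    if a.shape != b.shape:
        raise ValidationError("paired_t_test: arrays must have equal length")
    d = a - b
    d = d[~np.isnan(d)]
    n = d.size
    if n < 2:
        raise ValidationError("paired_t_test needs >= 2 complete pairs")
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0.0:
        return (0.0, 1.0) if mean == 0.0 else (np.inf * np.sign(mean), P_FLOOR)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(max(p, P_FLOOR))


def two_sample_t_test(a, b) -> tuple[float, float]:
    """Two-sided Welch t-test (unequal variances) on log2 abundances."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValidationError("two_sample_t_test needs >= 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return np.inf * np.sign(a.mean() - b.mean()), P_FLOOR
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(max(p, P_FLOOR))


def _stepup_count(ps: np.ndarray, slope: float) -> int:
    """Number of BH step-up rejections: max i with p_(i) <= i * slope."""
    i = np.arange(1, ps.size + 1)
    ok = np.nonzero(ps <= i * slope)[0]
    return int(ok[-1] + 1) if ok.size else 0


def bky_fdr(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage step-up FDR (Benjamini-Krieger-Yekutieli 2006).

    Stage 1 runs BH at a' = alpha/(1+alpha) and estimates m0 = m - r1; stage 2
    runs BH at the inflated level a'*m/m0 (rejecting everything if m0 = 0,
    nothing if r1 = 0).  Returns ``(qvalues, reject)`` where each q-value is
    the smallest alpha at which the two-stage procedure would reject that
    hypothesis (capped at 1), so q-values are monotone in p-value rank and
    ``reject == (q <= alpha)`` up to floating-point ties.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("bky_fdr expects a non-empty 1-d p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ps = p[order]
    i = np.arange(1, m + 1)
    # u_j = min_{i >= j} p_(i)/i : BH rejects >= j hypotheses at level q
    # iff m * u_j <= q
    u = np.minimum.accumulate((ps / i)[::-1])[::-1]

    # --- rejection flags at the requested alpha (explicit two-stage rule)
    alpha_prime = alpha / (1.0 + alpha)
    r1 = _stepup_count(ps, alpha_prime / m)
    m0 = m - r1
    if r1 == 0:
        n_rej = 0
    elif m0 == 0:
        n_rej = m
    else:
        n_rej = _stepup_count(ps, alpha_prime / m0)
    reject_sorted = np.zeros(m, dtype=bool)
    reject_sorted[:n_rej] = True

    # --- q-values: smallest alpha at which hypothesis j is rejected.
    # Both stages work at a' = alpha/(1+alpha), i.e. the BH level v maps to
    # alpha = v/(1-v).  Stage-1 rejections reach r once alpha >= A_r with
    # A_r = g(m*u_r); given m0 = m - r, rejection of rank j needs
    # alpha >= g(u_j*(m - r)); hence q_j = min_r max(A_r, g(u_j*(m - r))).
    def g(v):
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(v < 1.0, v / (1.0 - v), np.inf)

    A_full = np.concatenate(([0.0], g(m * u)))   # A_r for r = 0..m
    m0_levels = (m - np.arange(m + 1)).astype(float)
    q_sorted = np.empty(m)
    chunk = max(1, int(2_000_000 // (m + 1)))
    for start in range(0, m, chunk):
        u_c = u[start:start + chunk, None]
        cand = np.maximum(A_full[None, :], g(u_c * m0_levels[None, :]))
        q_sorted[start:start + chunk] = cand.min(axis=1)
    q_sorted = np.minimum(q_sorted, 1.0)
    q_sorted = np.maximum.accumulate(q_sorted)   # guard monotonicity

    q = np.empty(m)
    q[order] = q_sorted
    reject = np.zeros(m, dtype=bool)
    reject[order] = reject_sorted
    return q, reject


def bh_fdr(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Plain Benjamini-Hochberg step-up (via statsmodels)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


_FDR_METHODS = {"bky": bky_fdr, "bh": bh_fdr}


def adjust_pvalues(pvalues, method: str = "bky", alpha: float = 0.05):
    try:
        fn = _FDR_METHODS[method]
    except KeyError:
        raise ValidationError(f"unknown fdr method {method!r}") from None
    return fn(pvalues, alpha=alpha)


def _paired_stats(A: np.ndarray, B: np.ndarray):
    """Vectorized paired t across feature rows of aligned matrices."""
    D = A - B
    valid = ~np.isnan(D)
    n = valid.sum(axis=1)
    Dn = np.where(valid, D, np.nan)
    ok = n >= 2
    mean = np.full(n.shape, np.nan, dtype=float)
    sd = np.full(n.shape, np.nan, dtype=float)
    with np.errstate(invalid="ignore"):
        mean[n >= 1] = np.nanmean(Dn[n >= 1], axis=1)
        sd[ok] = np.nanstd(Dn[ok], axis=1, ddof=1)
    t = np.full(mean.shape, np.nan)
    p = np.full(mean.shape, np.nan)
    pos_var = ok & (sd > 0)
    t[pos_var] = mean[pos_var] / (sd[pos_var] / np.sqrt(n[pos_var]))
    p[pos_var] = 2.0 * stats.t.sf(np.abs(t[pos_var]), df=n[pos_var] - 1)
    zero_var = ok & (sd == 0)
    zv_null = zero_var & (mean == 0)
    zv_shift = zero_var & (mean != 0)
    t[zv_null], p[zv_null] = 0.0, 1.0
    t[zv_shift] = np.inf * np.sign(mean[zv_shift])
    p[zv_shift] = P_FLOOR
    p = np.where(np.isnan(p), np.nan, np.maximum(p, P_FLOOR))
    return mean, t, p, n, ok


def _welch_stats(A: np.ndarray, B: np.ndarray):
    """Vectorized Welch t across feature rows; groups need >= 2 values."""
    def moments(X):
        valid = ~np.isnan(X)
        n = valid.sum(axis=1)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(X, axis=1)
            var = np.full(mean.shape, np.nan)
            ok = n >= 2
            var[ok] = np.nanvar(X[ok], axis=1, ddof=1)
        return mean, var, n

    ma, va, na = moments(A)
    mb, vb, nb = moments(B)
    ok = (na >= 2) & (nb >= 2)
    dx = ma - mb
    t = np.full(dx.shape, np.nan)
    p = np.full(dx.shape, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        se2 = va / na + vb / nb
        pos = ok & (se2 > 0)
        t[pos] = dx[pos] / np.sqrt(se2[pos])
        df = se2[pos] ** 2 / (
            (va[pos] / na[pos]) ** 2 / (na[pos] - 1)
            + (vb[pos] / nb[pos]) ** 2 / (nb[pos] - 1)
        )
        p[pos] = 2.0 * stats.t.sf(np.abs(t[pos]), df=df)
    degen = ok & (se2 == 0)
    eq = degen & (dx == 0)
    ne = degen & (dx != 0)
    t[eq], p[eq] = 0.0, 1.0
    t[ne] = np.inf * np.sign(dx[ne])
    p[ne] = P_FLOOR
    p = np.where(np.isnan(p), np.nan, np.maximum(p, P_FLOOR))
    n_used = np.minimum(na, nb)
    return dx, t, p, n_used, ok


def compare_conditions(
    m: AbundanceMatrix,
    design: SampleDesign,
    cond_a: str,
    cond_b: str,
    paired: bool = True,
    fdr_method: str = "bky",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature log2 fold change, p, -log10 p and q for cond_a vs cond_b.

    Positive ``log2fc`` means higher abundance in ``cond_a``.  For paired
    comparisons, samples are matched on ``replicate_index``; features with
    fewer than two complete pairs (or, unpaired, fewer than two values per
    group) are skipped and logged, not reported.  q-values are computed over
    all features tested in this comparison.
    """
    if m.scale != "log2":
        raise ValidationError("compare_conditions expects a log2-scale matrix")
    for cond in (cond_a, cond_b):
        if cond not in design.conditions:
            raise ValidationError(f"condition {cond!r} absent from design")
    sa = design.samples_for(cond_a)
    sb = design.samples_for(cond_b)
    if paired:
        common = sorted(
            set(sa["replicate_index"]).intersection(sb["replicate_index"])
        )
        if len(common) < 2:
            raise ValidationError(
                f"paired comparison {cond_a} vs {cond_b}: "
                f"fewer than 2 shared replicate indices"
            )
        cols_a = sa.set_index("replicate_index").loc[common, "sample_id"].tolist()
        cols_b = sb.set_index("replicate_index").loc[common, "sample_id"].tolist()
    else:
        cols_a = sa["sample_id"].tolist()
        cols_b = sb["sample_id"].tolist()

    A = m.data[cols_a].to_numpy()
    B = m.data[cols_b].to_numpy()
    if paired:
        x, t, p, n_used, tested = _paired_stats(A, B)
    else:
        x, t, p, n_used, tested = _welch_stats(A, B)

    n_skip = int((~tested).sum())
    if n_skip:
        logger.info(
            "compare_conditions %s vs %s: skipped %d feature(s) with "
            "insufficient data", cond_a, cond_b, n_skip,
        )
    feats = np.asarray(m.feature_ids)[tested]
    p_t = p[tested]
    q, _ = adjust_pvalues(p_t, method=fdr_method, alpha=alpha)
    res = pd.DataFrame(
        {
            "feature_id": feats,
            "log2fc": x[tested],
            "p": p_t,
            "neglog10p": -np.log10(p_t),
            "q": q,
            "n_used": n_used[tested].astype(int),
        }
    )
    return res.reset_index(drop=True)
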