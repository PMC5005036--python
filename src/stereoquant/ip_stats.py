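"""Immunoaffinity-purification statistics.

An AP-MS experiment compares specific-antibody eluates against the starting
detergent extract (the *total*) and against nonspecific-IgG control
eluates.  Two complementary readouts are produced:

* a binary specificity filter (detected in at least ``min_specific``
  specific runs and at most ``max_control`` control runs), the
  control-subtraction route for the enriched-protein list;
* a continuous route -- per-protein eluate/total enrichment ratio with an
  empirical-Bayes moderated t-test and Benjamini-Hochberg FDR across the
  log2-normalized run matrix -- which keeps control-detected proteins.

Bait-relative stoichiometry converts eluate riBAQ (a molar-fraction
estimate) into mol/mol ratios: unadjusted = prey/bait riBAQ in the eluate;
adjusted multiplies by the bait/prey riBAQ ratio in the total, estimating
the fraction of the prey pool bound to the bait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .types import QuantMatrix, StudyDesign, ValidationError


def filter_specific(
    m: QuantMatrix,
    design: StudyDesign,
    min_specific: int = 4,
    max_control: int = 0,
) -> list[str]:
    """Proteins detected in >= min_specific specific runs and <= max_control controls.

    The default (4 of 6 specific, absent from controls) is the
    detected-at-least-4/6-and-not-in-controls rule used for the
    enriched-protein list.
    """
    spec_runs = design.runs("specific")
    ctrl_runs = design.runs("control")
    if min_specific > len(spec_runs):
        raise ValidationError(
            f"min_specific={min_specific} exceeds the {len(spec_runs)} specific runs"
        )
    det = m.detected()
    n_spec = det[[r for r in spec_runs if r in det.columns]].sum(axis=1)
    n_ctrl = (
        det[[r for r in ctrl_runs if r in det.columns]].sum(axis=1)
        if ctrl_runs
        else pd.Series(0, index=det.index)
    )
    keep = (n_spec >= min_specific) & (n_ctrl <= max_control)
    return sorted(det.index[keep])


@dataclass
class IPStatResult:
    protein_id: str
    n_specific_detections: int
    n_control_detections: int
    n_total_detections: int
    mean_eluate: float
    mean_total: float
    enrichment_ratio: float
    log10_enrichment: float
    category: str  # both | eluate_only | total_only
    censored: bool = False
    moderated_t: float = np.nan
    p_value: float = np.nan
    fdr_adjusted_p: float = np.nan


def enrichment_ratio(
    m: QuantMatrix, design: StudyDesign, zero_impute: bool = False
) -> pd.DataFrame:
    """Per-protein immunoaffinity enrichment: mean eluate riBAQ / mean total riBAQ.

    Run means are taken over detected runs only (no zero imputation) unless
    ``zero_impute`` is set, in which case undetected runs count as zero.
    Proteins present on only one side are categorized ``eluate_only`` /
    ``total_only``; eluate-only proteins receive a censored lower-bound
    ratio against the smallest detected total riBAQ rather than an
    invented pseudo-count.  Proteins absent from both sides are excluded.
    """
    spec = [r for r in design.runs("specific") if r in m.samples]
    tot = [r for r in design.runs("total") if r in m.samples]
    ctrl = [r for r in design.runs("control") if r in m.samples]
    if not spec or not tot:
        raise ValidationError("design must provide specific and total runs")
    ev = m.values[spec]
    tv = m.values[tot]
    if zero_impute:
        mean_e, mean_t = ev.fillna(0.0).mean(axis=1), tv.fillna(0.0).mean(axis=1)
    else:
        mean_e, mean_t = ev.mean(axis=1), tv.mean(axis=1)
    det = m.detected()
    n_spec = det[spec].sum(axis=1)
    n_tot = det[tot].sum(axis=1)
    n_ctrl = det[ctrl].sum(axis=1) if ctrl else pd.Series(0, index=det.index)
    min_total = tv.min().min()

    rows = []
    for pid in m.proteins:
        ne, nt = int(n_spec[pid]), int(n_tot[pid])
        if ne == 0 and nt == 0:
            continue
        me, mt = mean_e[pid], mean_t[pid]
        if ne > 0 and nt > 0:
            cat, censored = "both", False
            ratio = me / mt
        elif ne > 0:
            cat, censored = "eluate_only", True
            ratio = me / min_total if np.isfinite(min_total) else np.nan
        else:
            cat, censored = "total_only", False
            ratio = np.nan
        rows.append(
            {
                "protein_id": pid,
                "n_specific_detections": ne,
                "n_total_detections": nt,
                "n_control_detections": int(n_ctrl[pid]),
                "mean_eluate": me,
                "mean_total": mt,
                "enrichment_ratio": ratio,
                "log10_enrichment": np.log10(ratio) if ratio and ratio > 0 else np.nan,
                "category": cat,
                "censored": censored,
            }
        )
    return pd.DataFrame(rows).set_index("protein_id")


def _trigamma_inverse(y: np.ndarray | float, max_iter: int = 50) -> np.ndarray:
    """Solve trigamma(x) = y by Newton iteration (monotone on (0, inf))."""
    y = np.atleast_1d(np.asarray(y, dtype=float))
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if np.max(np.abs(dif) / x) < 1e-12:
            break
    return x


def fit_f_dist(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment fit of a scaled F-distribution to observed sample variances.

    Under the hierarchical model the residual variances s_g^2 follow
    ``s0^2 * F(df_g, d0)``.  Matching the mean and variance of ``log s^2``
    (corrected via digamma/trigamma moments of log chi-square variables)
    yields the prior degrees of freedom ``d0`` and prior variance ``s0^2``.
    Returns ``(s0_squared, d0)`` with ``d0 = inf`` when the observed
    dispersion does not exceed its expectation under infinite prior df.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & (df > 0)
    s2, df = s2[ok], df[ok]
    if s2.size < 2:
        raise ValidationError("need >= 2 variances to fit the prior")
    # guard against exact zeros
    z = np.log(np.maximum(s2, 1e-300))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = np.sum((e - emean) ** 2) / (e.size - 1)
    evar = evar - np.mean(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = float(2.0 * _trigamma_inverse(evar)[0])
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(emean))
    return s0_sq, d0


def moderated_t_test(
    m: QuantMatrix,
    group1: list[str],
    group2: list[str],
    prior_df: float | None = None,
    prior_s2: float | None = None,
) -> pd.DataFrame:
    """Two-sample empirical-Bayes moderated t-test per protein.

    Per-protein pooled residual variances ``s_g^2`` (df ``n1+n2-2`` over
    detected runs) are shrunk toward the ensemble prior ``s0^2`` estimated
    by :func:`fit_f_dist`:

        s_tilde^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)
        t = (mean1 - mean2) / (s_tilde * sqrt(1/n1 + 1/n2))
        df = d0 + d_g

    ``prior_df`` (d0) and ``prior_s2`` may be forced for the no-shrinkage
    (d0 = 0, ordinary pooled t) and full-shrinkage (d0 = inf, fixed s0)
    limits.  Rows are kept whenever both groups have >= 1 detected value
    and the residual df is >= 1; rows with zero residual variance are
    omitted with a warning.
    """
    g1 = [c for c in group1 if c in m.samples]
    g2 = [c for c in group2 if c in m.samples]
    if len(g1) < 2 or len(g2) < 2:
        raise ValidationError("need >= 2 runs per group")
    v1 = m.values[g1].to_numpy(dtype=float)
    v2 = m.values[g2].to_numpy(dtype=float)

    n1 = np.isfinite(v1).sum(axis=1)
    n2 = np.isfinite(v2).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(v1, axis=1)
        m2 = np.nanmean(v2, axis=1)
        ss1 = np.nansum((v1 - m1[:, None]) ** 2, axis=1)
        ss2 = np.nansum((v2 - m2[:, None]) ** 2, axis=1)
    d_res = n1 + n2 - 2.0
    fit_ok = (n1 >= 1) & (n2 >= 1) & (d_res >= 1)
    s2 = np.where(fit_ok & (d_res > 0), (ss1 + ss2) / np.maximum(d_res, 1), np.nan)

    const = fit_ok & (s2 <= 0)
    if const.any():
        warnings.warn(
            f"omitting {int(const.sum())} all-constant protein row(s)", stacklevel=2
        )
        fit_ok &= ~const

    if prior_df is None or prior_s2 is None:
        s0_sq, d0 = fit_f_dist(s2[fit_ok], d_res[fit_ok])
        if prior_df is not None:
            d0 = prior_df
        if prior_s2 is not None:
            s0_sq = prior_s2
    else:
        s0_sq, d0 = prior_s2, prior_df

    with np.errstate(invalid="ignore", divide="ignore"):
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
        elif d0 == 0:
            s2_post = s2
        else:
            s2_post = (d0 * s0_sq + d_res * s2) / (d0 + d_res)
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        t = (m1 - m2) / se
    df_total = d0 + d_res
    p = np.where(
        np.isinf(df_total),
        2.0 * stats.norm.sf(np.abs(t)),
        2.0 * stats.t.sf(np.abs(t), np.where(np.isfinite(df_total), df_total, 1.0)),
    )

    out = pd.DataFrame(
        {
            "log2_fc": m1 - m2,
            "s2": s2,
            "s2_post": s2_post,
            "moderated_t": t,
            "df": df_total,
            "p_value": p,
        },
        index=m.proteins,
    )
    out = out[fit_ok]
    out.attrs["prior_s2"] = s0_sq
    out.attrs["prior_df"] = d0
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / (np.arange(n) + 1.0)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


@dataclass
class StoichiometryResult:
    protein_id: str
    unadjusted: float
    adjusted: float


def stoichiometry(
    eluate_ribaq: pd.Series, total_ribaq: pd.Series, bait: str
) -> pd.DataFrame:
    """Bait-relative stoichiometry from run-mean riBAQ values.

    unadjusted_i = eluate_i / eluate_bait;
    adjusted_i   = unadjusted_i * total_bait / total_i.
    The adjusted value is missing when the protein is absent from totals.
    The bait scores exactly 1 under both definitions.
    """
    if bait not in eluate_ribaq.index or not np.isfinite(eluate_ribaq[bait]):
        raise ValidationError(f"bait {bait!r} not detected in eluate")
    if bait not in total_ribaq.index or not np.isfinite(total_ribaq[bait]):
        raise ValidationError(f"bait {bait!r} not detected in total")
    unadj = eluate_ribaq / eluate_ribaq[bait]
    tot = total_ribaq.reindex(eluate_ribaq.index)
    with np.errstate(invalid="ignore", divide="ignore"):
        adj = unadj * total_ribaq[bait] / tot
    out = pd.DataFrame({"unadjusted": unadj, "adjusted": adj})
    out.loc[bait] = [1.0, 1.0]
    return out.dropna(subset=["unadjusted"]).sort_values("unadjusted", ascending=False)
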