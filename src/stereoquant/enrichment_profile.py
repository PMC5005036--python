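"""Fraction-profile analytics.

Across an ordered series of purification fractions the abundance of a
protein that co-enriches with the target membranes rises roughly
log-linearly, so the OLS slope of log riBAQ against fraction index (unit
spacing) -- the *enrichment slope* -- ranks proteins by co-enrichment.
A block average of transmembrane-helix flags over the slope-sorted protein
list diagnoses membrane enrichment, and Gaussian-mixture clustering of
row-standardized profiles groups proteins with shared behaviour across the
preparation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .types import QuantMatrix, StudyDesign, ValidationError


@dataclass
class EnrichmentSlopeResult:
    protein_id: str
    slope: float
    intercept: float
    n_fractions_detected: int
    rank: int = 0


@dataclass
class ClusterAssignment:
    protein_id: str
    cluster: int
    k_selected: int
    model: str


@dataclass
class ClusterSummary:
    assignments: list[ClusterAssignment]
    k_selected: int
    model: str
    bic: float
    means: np.ndarray  # k x n_samples, on the z scale, reordered by slope
    cluster_slopes: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": [a.protein_id for a in self.assignments],
                "cluster": [a.cluster for a in self.assignments],
                "k_selected": self.k_selected,
                "model": self.model,
            }
        )


def enrichment_slope(
    m: QuantMatrix,
    design: StudyDesign,
    min_detected: int = 3,
    log_base: float = 10.0,
) -> list[EnrichmentSlopeResult]:
    """Per-protein OLS slope of log riBAQ on fraction index.

    Only samples mapped to a fraction in ``design`` enter the fit; missing
    fractions are omitted (not imputed).  Proteins detected in fewer than
    ``min_detected`` fractions are dropped.  Results are ranked by slope
    descending (rank 1 = steepest), ties broken by protein id.

    ``min_detected`` defaults to 3, the detected-in-at-least-three-of-five
    convention for a five-fraction enrichment series; the companion
    at-least-four-of-six rule is the same parameter set to 4.
    """
    if min_detected < 2:
        raise ValidationError("min_detected must be >= 2 to define a slope")
    frac_samples = [s for s in m.samples if s in design.sample_fraction]
    if not frac_samples:
        raise ValidationError("no samples map onto the fraction order")
    x_all = np.array([design.fraction_index(s) for s in frac_samples], dtype=float)
    sub = m.values[frac_samples]
    logv = np.log(sub.to_numpy(dtype=float)) / np.log(log_base)

    results: list[EnrichmentSlopeResult] = []
    for i, pid in enumerate(sub.index):
        y = logv[i]
        ok = np.isfinite(y)
        # count detections per distinct fraction, not per technical replicate
        n_fr = len({design.sample_fraction[s] for s, o in zip(frac_samples, ok) if o})
        if n_fr < min_detected:
            continue
        slope, intercept = np.polyfit(x_all[ok], y[ok], 1)
        results.append(
            EnrichmentSlopeResult(
                protein_id=pid,
                slope=float(slope),
                intercept=float(intercept),
                n_fractions_detected=n_fr,
            )
        )
    results.sort(key=lambda r: (-r.slope, r.protein_id))
    for rank, r in enumerate(results, start=1):
        r.rank = rank
    return results


def slopes_frame(results: list[EnrichmentSlopeResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in results],
            "slope": [r.slope for r in results],
            "n_fractions_detected": [r.n_fractions_detected for r in results],
            "rank": [r.rank for r in results],
        }
    ).set_index("protein_id")


def tm_rolling_average(
    results: list[EnrichmentSlopeResult],
    tm_flags: pd.Series,
    window: int = 50,
) -> list[tuple[int, float]]:
    """Mean transmembrane-helix flag over consecutive slope-sorted blocks.

    ``results`` must already be sorted by slope (as ``enrichment_slope``
    returns them).  Non-overlapping blocks of ``window`` proteins are
    averaged; the final partial block is averaged over its actual size.
    """
    if window < 1:
        raise ValidationError("window must be >= 1")
    flags = np.array([float(bool(tm_flags.get(r.protein_id, False))) for r in results])
    out = []
    for b, start in enumerate(range(0, len(flags), window)):
        block = flags[start : start + window]
        out.append((b, float(block.mean())))
    return out


def row_standardize(m: QuantMatrix, ddof: int = 1) -> tuple[QuantMatrix, list[str]]:
    """Z-score each row: subtract the row mean, divide by the row SD.

    Uses the sample (n-1) standard deviation by default.  Constant rows
    cannot be standardized; they are excluded with a warning and returned
    as the second element.
    """
    vals = m.values
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=ddof)
    constant = sd.index[(sd == 0) | sd.isna()].tolist()
    if constant:
        warnings.warn(
            f"excluding {len(constant)} constant row(s) from standardization: "
            f"{constant[:5]}{'...' if len(constant) > 5 else ''}",
            stacklevel=2,
        )
    keep = ~vals.index.isin(constant)
    z = vals.loc[keep].sub(mean[keep], axis=0).div(sd[keep], axis=0)
    return (
        QuantMatrix(z, contaminant=m.contaminant[keep], tm_helix=m.tm_helix[keep], log_scale=True),
        constant,
    )


def cluster_profiles(
    z: QuantMatrix,
    k_range=range(1, 11),
    slopes: pd.Series | None = None,
    covariance_types: tuple[str, ...] = ("diag", "full", "tied", "spherical"),
    seed: int = 0,
    n_init: int = 10,
    reg_covar_frac: float = 1e-2,
) -> ClusterSummary:
    """Model-based clustering of z-scaled profiles with BIC model selection.

    Gaussian mixtures are fit for every (k, covariance structure) pair and
    the lowest-BIC model wins.  Requires complete rows (only proteins
    detected in every profiled sample are clustered).  Clusters are
    reindexed in descending order of the mean enrichment slope of their
    members (cluster 1 = steepest) when ``slopes`` is given, else by the
    mean of the cluster-mean profile slope proxy (profile trend).

    Rows are fit in protein-id order so the result is invariant to the
    input row permutation.
    """
    vals = z.values
    if vals.isna().any().any():
        raise ValidationError("clustering requires proteins detected in all samples")
    n = len(vals)
    ks = [int(k) for k in k_range]
    if max(ks) > n // 2:
        raise ValidationError(f"k_range max {max(ks)} exceeds n/2 = {n // 2}")

    order = vals.index.argsort()
    X = vals.to_numpy(dtype=float)[order]
    ids = vals.index.to_numpy()[order]

    # covariance regularization scaled to the data variance: keeps the
    # likelihood from blowing up on near-singular tiny components, which
    # would otherwise dominate BIC selection
    reg = reg_covar_frac * float(X.var())
    best = None
    for cov in covariance_types:
        for k in ks:
            gm = GaussianMixture(
                n_components=k,
                covariance_type=cov,
                n_init=n_init,
                init_params="k-means++",
                random_state=seed,
                reg_covar=reg,
            )
            gm.fit(X)
            bic = gm.bic(X)
            if best is None or bic < best[0]:
                best = (bic, k, cov, gm)
    bic, k_sel, cov_sel, gm = best
    labels = gm.predict(X)

    # order clusters by mean member enrichment slope, steepest first
    if slopes is not None:
        member_slope = np.array(
            [slopes.reindex(ids[labels == c]).mean() for c in range(k_sel)]
        )
    else:
        # fall back to the trend of the cluster mean profile
        xs = np.arange(X.shape[1], dtype=float)
        member_slope = np.array(
            [np.polyfit(xs, gm.means_[c], 1)[0] for c in range(k_sel)]
        )
    new_index = {old: rank + 1 for rank, old in enumerate(np.argsort(-member_slope))}
    assignments = [
        ClusterAssignment(pid, new_index[lab], k_sel, cov_sel)
        for pid, lab in zip(ids, labels)
    ]
    reorder = np.argsort(-member_slope)
    return ClusterSummary(
        assignments=assignments,
        k_selected=k_sel,
        model=cov_sel,
        bic=float(bic),
        means=gm.means_[reorder],
        cluster_slopes=member_slope[reorder],
    )
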