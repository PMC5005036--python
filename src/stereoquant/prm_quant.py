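"""Targeted-proteomics (PRM) quantitation.

A parallel-reaction-monitoring assay records an extracted-ion chromatogram
per monitored fragment ion of a target peptide.  Quantitation sums the
fragment traces, locates a candidate peak on the summed trace, accepts or
rejects it by rule, and integrates the accepted peak (trapezoid, zero
baseline).  Acceptance requires:

1. three or more co-eluting fragment ions contribute to the peak,
2. at least two data points collected across the peak, and
3. one or more MS2 spectra inside the peak matched to the peptide.

When criterion 3 fails, a fallback accepts the peak iff (a) its apex lies
within ``rt_tolerance`` (default 2.0 min) of the retention time of an
identified peak for the same peptide in another sample and (b) the set of
contributing fragment ions matches that identified peak.  A rejected peak
is zero-filled: its area is exactly 0.

Bait-peptide experiment normalization and the IP/total readout follow,
plus the per-µg fraction bookkeeping used to express a fraction's total
target-protein PRM signal as a percentage of the starting material.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import ValidationError


@dataclass
class Chromatogram:
    """One fragment-ion trace: strictly increasing times (min), counts >= 0."""

    run: str
    peptide: str
    fragment: str
    time: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.shape != self.intensity.shape:
            raise ValidationError(
                f"{self.run}/{self.peptide}/{self.fragment}: time and intensity lengths differ"
            )
        if self.time.size and np.any(np.diff(self.time) <= 0):
            raise ValidationError(
                f"{self.run}/{self.peptide}/{self.fragment}: times must be strictly increasing"
            )


@dataclass
class PeakCall:
    run: str
    peptide: str
    boundaries: tuple[float, float] | None
    area: float
    accepted: bool
    rejection_reasons: list[str] = field(default_factory=list)
    rt_apex: float | None = None
    contributing_fragments: tuple[str, ...] = ()


@dataclass
class IpOverTotalResult:
    peptide: str
    mean_specific: float
    mean_control: float
    mean_total: float
    ip_over_total: float
    control_over_total: float
    p_value: float
    ci95: tuple[float, float]


def sum_traces(traces: list[Chromatogram]) -> Chromatogram:
    """Pointwise sum of fragment traces for one peptide/run.

    Traces on different grids are linearly interpolated onto the densest
    grid (outside a trace's span it contributes zero).
    """
    if not traces:
        raise ValidationError("no traces to sum")
    grids = [t.time for t in traces]
    ref = max(grids, key=len)
    same = all(len(g) == len(ref) and np.array_equal(g, ref) for g in grids)
    if same:
        total = np.sum([t.intensity for t in traces], axis=0)
    else:
        total = np.zeros_like(ref)
        for t in traces:
            total += np.interp(ref, t.time, t.intensity, left=0.0, right=0.0)
    return Chromatogram(traces[0].run, traces[0].peptide, "sum", ref.copy(), total)


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or y.size < 2:
        return y.astype(float)
    w = min(window, y.size)
    kernel = np.ones(w) / w
    # reflect-pad so the ends are not biased low
    pad = w // 2
    ypad = np.concatenate([y[pad:0:-1], y, y[-2 : -2 - pad : -1]])
    sm = np.convolve(ypad, kernel, mode="same")[pad : pad + y.size]
    return sm


def locate_peak(
    summed: Chromatogram,
    reference_rt: float | None = None,
    smooth_window: int = 5,
    noise_floor: float = 0.0,
    search_halfwidth: float = 4.0,
    rel_threshold: float = 0.01,
) -> tuple[int, int, int]:
    """Deterministic candidate-peak localization on the summed trace.

    The smoothed trace's apex is the global maximum, restricted to within
    ``search_halfwidth`` of ``reference_rt`` when one is supplied (the
    search window is deliberately wider than the identification fallback
    tolerance, so an off-reference peak is still found and then judged).
    Boundaries extend outward until the smoothed trace drops below
    ``max(noise_floor, rel_threshold * apex)``.  Returns index triplet
    (apex, lo, hi) with inclusive bounds.
    """
    y = _smooth(summed.intensity, smooth_window)
    if reference_rt is not None:
        near = np.abs(summed.time - reference_rt) <= search_halfwidth
        if not near.any():
            near = np.ones_like(y, dtype=bool)
        cand = np.where(near, y, -np.inf)
        apex = int(np.argmax(cand))
    else:
        apex = int(np.argmax(y))
    thr = max(noise_floor, rel_threshold * y[apex])
    lo = apex
    while lo > 0 and y[lo - 1] >= thr:
        lo -= 1
    hi = apex
    while hi < y.size - 1 and y[hi + 1] >= thr:
        hi += 1
    return apex, lo, hi


def integrate_peak(trace: Chromatogram, boundaries: tuple[float, float]) -> float:
    """Trapezoidal integral of a trace between boundary times, zero baseline."""
    lo, hi = boundaries
    if hi < lo:
        raise ValidationError(f"inverted boundaries ({lo}, {hi})")
    mask = (trace.time >= lo) & (trace.time <= hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(trace.intensity[mask], trace.time[mask]))


def qualify_peak(
    traces: list[Chromatogram],
    ms2_times: np.ndarray | list[float],
    reference_rt: float | None = None,
    reference_fragments: set[str] | None = None,
    noise_floor: float = 0.0,
    rt_tolerance: float = 2.0,
    smooth_window: int = 5,
    coelution_width_factor: float = 1.0,
    fragment_match: str = "equal",
) -> PeakCall:
    """Apply the peak-qualification rules and integrate if accepted.

    ``ms2_times`` are the retention times of MS2 spectra matched to this
    peptide in this run.  ``reference_rt`` / ``reference_fragments``
    describe an identified peak for the same peptide from another sample
    and drive the retention-time fallback when no MS2 match falls inside
    the boundaries.  "Co-eluting" means a fragment's own apex lies within
    one peak-width (boundary half-span, scaled by
    ``coelution_width_factor``) of the summed apex and the fragment rises
    above the noise floor inside the boundaries.
    """
    summed = sum_traces(traces)
    run, peptide = summed.run, summed.peptide
    if summed.intensity.size == 0 or np.all(summed.intensity <= 0):
        return PeakCall(run, peptide, None, 0.0, False, ["no signal"])

    apex_i, lo_i, hi_i = locate_peak(
        summed,
        reference_rt,
        smooth_window,
        noise_floor,
        search_halfwidth=2.0 * rt_tolerance,
    )
    t_lo, t_hi = float(summed.time[lo_i]), float(summed.time[hi_i])
    rt_apex = float(summed.time[apex_i])
    width = max(t_hi - t_lo, 1e-9) / 2.0 * coelution_width_factor

    reasons: list[str] = []

    # criterion 1: >= 3 co-eluting fragments above the noise floor
    contributing: list[str] = []
    for tr in traces:
        inside = (tr.time >= t_lo) & (tr.time <= t_hi)
        if not inside.any() or np.nanmax(tr.intensity[inside]) <= noise_floor:
            continue
        # the fragment's own elution apex must sit inside the peak: a
        # fragment whose maximum lies elsewhere is not co-eluting even if
        # its tail leaks into the integration window
        frag_apex = tr.time[int(np.argmax(tr.intensity))]
        if abs(frag_apex - rt_apex) <= width:
            contributing.append(tr.fragment)
    if len(contributing) < 3:
        reasons.append(
            f"criterion 1: {len(contributing)} co-eluting fragment(s), need >= 3"
        )

    # criterion 2: >= 2 data points across the peak
    n_points = int(np.sum((summed.time >= t_lo) & (summed.time <= t_hi)))
    if n_points < 2:
        reasons.append(f"criterion 2: {n_points} data point(s) across peak, need >= 2")

    # criterion 3: matched MS2 spectrum inside the peak, else RT fallback
    ms2 = np.asarray(list(ms2_times), dtype=float)
    has_ms2 = bool(ms2.size and np.any((ms2 >= t_lo) & (ms2 <= t_hi)))
    if not has_ms2:
        fallback_ok = False
        if reference_rt is not None:
            rt_ok = abs(rt_apex - reference_rt) <= rt_tolerance
            if reference_fragments is None:
                frag_ok = False
            elif fragment_match == "equal":
                frag_ok = set(contributing) == set(reference_fragments)
            else:  # subset
                frag_ok = set(contributing) <= set(reference_fragments)
            fallback_ok = rt_ok and frag_ok
            if not rt_ok:
                reasons.append(
                    f"criterion 3 fallback: apex {abs(rt_apex - reference_rt):.3f} min "
                    f"from reference, limit {rt_tolerance} min"
                )
            elif not frag_ok:
                reasons.append("criterion 3 fallback: fragment-ion types do not match")
        else:
            reasons.append("criterion 3: no matched MS2 spectrum and no reference peak")
        if not fallback_ok and not any(r.startswith("criterion 3") for r in reasons):
            reasons.append("criterion 3: no matched MS2 spectrum inside peak")

    if reasons:
        return PeakCall(
            run, peptide, (t_lo, t_hi), 0.0, False, reasons, rt_apex, tuple(contributing)
        )
    area = integrate_peak(summed, (t_lo, t_hi))
    return PeakCall(run, peptide, (t_lo, t_hi), area, True, [], rt_apex, tuple(contributing))


def experiment_normalization(bait_areas: pd.DataFrame) -> pd.Series:
    """Experiment normalization factors from bait-peptide areas.

    ``bait_areas`` is a bait peptides x experiments table.  Each peptide's
    area in an experiment is divided by that peptide's mean across
    experiments; the per-peptide factors are then averaged across bait
    peptides.  Downstream areas are divided by their experiment's factor.
    """
    if bait_areas.isna().all(axis=1).any():
        raise ValidationError("bait peptide with no values in any experiment")
    missing = bait_areas.columns[bait_areas.isna().all(axis=0)]
    if len(missing):
        raise ValidationError(f"experiment {missing[0]!r} has no bait peptide values")
    per_pep = bait_areas.div(bait_areas.mean(axis=1, skipna=True), axis=0)
    return per_pep.mean(axis=0, skipna=True)


def ip_over_total(
    peptide: str,
    specific: np.ndarray | list[float],
    control: np.ndarray | list[float],
    total: np.ndarray | list[float],
) -> IpOverTotalResult:
    """IP/total readout with a two-tailed two-sample t-test (specific vs control).

    All inputs are experiment-normalized peptide areas.  The point
    estimates are mean(specific)/mean(total) and mean(control)/mean(total);
    the test compares specific against control eluates and reports the 95%
    confidence interval for the mean difference.
    """
    s = np.asarray(specific, dtype=float)
    c = np.asarray(control, dtype=float)
    t = np.asarray(total, dtype=float)
    if s.size < 2 or c.size < 2 or t.size < 1:
        raise ValidationError("need >= 2 specific, >= 2 control, >= 1 total replicates")
    mt = t.mean()
    if mt == 0:
        raise ValidationError("total replicates have zero mean")
    import warnings

    with warnings.catch_warnings():
        # degenerate zero-variance groups are legitimate here (zero-filled peaks)
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(s, c, equal_var=True)
    dof = s.size + c.size - 2
    sp2 = ((s.size - 1) * s.var(ddof=1) + (c.size - 1) * c.var(ddof=1)) / dof
    se = np.sqrt(sp2 * (1 / s.size + 1 / c.size))
    diff = s.mean() - c.mean()
    if se > 0:
        tcrit = stats.t.ppf(0.975, dof)
        ci = (diff - tcrit * se, diff + tcrit * se)
    else:
        ci = (diff, diff)
    return IpOverTotalResult(
        peptide=peptide,
        mean_specific=float(s.mean()),
        mean_control=float(c.mean()),
        mean_total=float(mt),
        ip_over_total=float(s.mean() / mt),
        control_over_total=float(c.mean() / mt),
        p_value=float(res.pvalue),
        ci95=(float(ci[0]), float(ci[1])),
    )


# ---------------------------------------------------------------------------
# per-µg fraction arithmetic


def total_intensity(assays: pd.DataFrame) -> pd.Series:
    """Total PRM intensity per fraction: per-µg intensity x total protein (µg).

    ``assays`` columns: ``total_protein_ug``, ``intensity_per_ug``;
    indexed by fraction label.
    """
    if (assays["total_protein_ug"] <= 0).any():
        bad = assays.index[assays["total_protein_ug"] <= 0][0]
        raise ValidationError(f"fraction {bad!r}: total protein must be > 0")
    return assays["intensity_per_ug"] * assays["total_protein_ug"]


def fraction_of_reference(assays: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Each fraction's total PRM intensity as a percentage of the reference.

    Returns columns ``total_intensity``, ``percent`` (float) and
    ``percent_rounded`` (nearest integer, the reporting convention).
    """
    if reference not in assays.index:
        raise ValidationError(f"reference fraction {reference!r} not present")
    totals = total_intensity(assays)
    ref = totals[reference]
    if ref == 0:
        raise ValidationError("reference fraction has zero total intensity")
    pct = 100.0 * totals / ref
    return pd.DataFrame(
        {
            "total_intensity": totals,
            "percent": pct,
            "percent_rounded": pct.round().astype(int),
        }
    )


def per_ug_fold_enrichment(
    assays: pd.DataFrame, from_fraction: str, to_fraction: str
) -> float:
    """Fold change in per-µg intensity between two fractions."""
    for f in (from_fraction, to_fraction):
        if f not in assays.index:
            raise ValidationError(f"fraction {f!r} not present")
    denom = assays.loc[from_fraction, "intensity_per_ug"]
    if denom == 0:
        raise ValidationError(f"fraction {from_fraction!r} has zero per-µg intensity")
    return float(assays.loc[to_fraction, "intensity_per_ug"] / denom)


def round_sig(x: float, sig: int = 1) -> float:
    """Round to ``sig`` significant figures (reporting convention for folds)."""
    if x == 0 or not np.isfinite(x):
        return x
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))
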