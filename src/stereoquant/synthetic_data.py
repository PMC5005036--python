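"""Ground-truthed synthetic data generators.

Three generators emulate the statistical structure the downstream analytics
assume, so every stage is testable without any deposited raw data:

* :func:`simulate_purification` -- an iBAQ matrix over ordered purification
  fractions in which a designated membrane subset rises log-linearly with
  fraction index (log-normal baseline abundances, logistic detection
  dropout, shared/isoform-unique peptides, flagged contaminants);
* :func:`simulate_ip` -- specific vs control immunoaffinity eluates with a
  planted bait and partner set, abundance-weighted nonspecific background
  sampled identically into both eluate types, and multiplicative
  log-normal replicate noise;
* :func:`simulate_prm` -- Gaussian fragment-ion elution peaks on a shared
  retention-time grid with additive noise and MS2-identification events
  near the apex; analytic per-fragment areas are kept as ground truth.

Every generator draws from one ``numpy`` generator seeded per call, so an
identical config yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import PeptideEvidence, QuantMatrix, StudyDesign, ValidationError

FRACTION_LABELS = ("S1", "P2", "M3", "P6", "S7")


@dataclass
class SimulationConfig:
    """Study conditions for the purification-series generator.

    Defaults emulate a five-fraction stereocilia-membrane enrichment
    series: a ~10% membrane subset gaining ~0.6 log10 units per fraction
    step (tens-fold over the series), log-normal baseline abundances
    spanning several decades, and logistic detection dropout for
    low-abundance proteins.
    """

    n_proteins: int = 500
    frac_membrane: float = 0.10
    n_fractions: int = 5
    slope_membrane: float = 0.6  # mean log10 gain per fraction step
    slope_sd: float = 0.15
    base_abundance_mu: float = 6.0  # log10 iBAQ
    base_abundance_sigma: float = 1.5
    noise_sigma: float = 0.25  # per-observation log10 measurement noise
    dropout_midpoint: float | None = 4.5  # log10 abundance at 50% detection
    dropout_steepness: float = 2.0
    n_isoform_groups: int = 5
    contaminant_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_proteins", "n_fractions"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("frac_membrane", "contaminant_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.n_isoform_groups < 0:
            raise ValidationError("n_isoform_groups must be >= 0")


@dataclass
class IPSimulationConfig:
    """Study conditions for the immunoaffinity-eluate generator.

    Six specific runs against six nonspecific-IgG control runs, a bait
    captured at full efficiency and partners at the listed capture
    efficiencies, a shared ~10^4-fold eluate concentration factor, and
    abundance-weighted nonspecific carry-over at ``nonspecific_rate``.
    """

    bait_id: str = ""
    true_partners: list[tuple[str, float]] = field(default_factory=list)
    n_specific_runs: int = 6
    n_control_runs: int = 6
    nonspecific_rate: float = 0.3
    nonspecific_level: float = 1e-5  # carried-over share of availability
    concentration_factor: float = 1e4
    eluate_noise_sigma: float = 0.3  # natural-log sigma
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_specific_runs <= 0 or self.n_control_runs < 0:
            raise ValidationError("run counts must be positive")
        if not 0.0 <= self.nonspecific_rate <= 1.0:
            raise ValidationError("nonspecific_rate must lie in [0, 1]")
        for pid, eff in self.true_partners:
            if not 0.0 < eff <= 1.0:
                raise ValidationError(
                    f"partner {pid!r}: capture efficiency must lie in (0, 1]"
                )


@dataclass
class PRMPeptide:
    sequence: str
    true_rt: float  # minutes
    fragments: dict[str, float]  # label -> relative intensity (sums to 1)
    amplitude: float = 1e6  # summed-apex height across fragments

    def __post_init__(self) -> None:
        total = sum(self.fragments.values())
        if self.fragments and abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"{self.sequence}: fragment relative intensities sum to {total}, expected 1"
            )


@dataclass
class PRMSimulationConfig:
    peptides: list[PRMPeptide] = field(default_factory=list)
    peak_width_sigma: float = 0.1  # minutes
    noise_floor: float = 0.0  # additive noise scale (counts)
    sampling_interval: float = 0.05  # minutes (~3 s cycle)
    ms2_event_prob_at_apex: float = 0.9
    run_window: tuple[float, float] = (0.0, 30.0)
    runs: tuple[str, ...] = ("run_1",)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.peptides:
            raise ValidationError("peptide list must not be empty")
        lo, hi = self.run_window
        for p in self.peptides:
            if not lo <= p.true_rt <= hi:
                raise ValidationError(
                    f"{p.sequence}: retention time {p.true_rt} outside run window {self.run_window}"
                )


@dataclass
class ChromatogramSet:
    chromatograms: list  # of prm_quant.Chromatogram
    ms2_events: pd.DataFrame  # run, peptide, time_min, matched
    ground_truth: pd.DataFrame  # run, peptide, fragment, true_area, true_rt

    def traces(self, run: str, peptide: str) -> list:
        return [
            c for c in self.chromatograms if c.run == run and c.peptide == peptide
        ]

    def matched_times(self, run: str, peptide: str) -> np.ndarray:
        ev = self.ms2_events
        sel = (ev["run"] == run) & (ev["peptide"] == peptide) & ev["matched"]
        return ev.loc[sel, "time_min"].to_numpy()


def _detection_prob(log10_abund: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    if cfg.dropout_midpoint is None:
        return np.ones_like(log10_abund)
    z = cfg.dropout_steepness * (log10_abund - cfg.dropout_midpoint)
    return 1.0 / (1.0 + np.exp(-z))


def simulate_purification(
    config: SimulationConfig,
) -> tuple[PeptideEvidence, QuantMatrix, pd.DataFrame]:
    """Generate a purification series with known enrichment slopes.

    Returns ``(peptides, ibaq_matrix, ground_truth)``.  Each membrane
    protein's expected log10 iBAQ rises linearly with fraction index at
    its assigned slope; background proteins get slopes drawn around zero;
    contaminants are flagged and flat.  Isoform groups pair two proteins
    of the same class into a single quantified group row backed by shared
    plus isoform-unique peptides (group intensity = sum of members).

    The companion :class:`StudyDesign` is available from
    :func:`purification_design`.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    ids = np.array([f"P{i:04d}" for i in range(1, n + 1)])

    n_mem = int(round(config.frac_membrane * n))
    is_membrane = np.zeros(n, dtype=bool)
    is_membrane[rng.choice(n, size=n_mem, replace=False)] = True
    n_cont = int(round(config.contaminant_rate * n))
    bg_idx = np.flatnonzero(~is_membrane)
    is_contaminant = np.zeros(n, dtype=bool)
    if n_cont and len(bg_idx):
        is_contaminant[rng.choice(bg_idx, size=min(n_cont, len(bg_idx)), replace=False)] = True

    slopes = np.where(
        is_membrane,
        rng.normal(config.slope_membrane, config.slope_sd, size=n),
        rng.normal(0.0, config.slope_sd, size=n),
    )
    slopes[is_contaminant] = 0.0
    base = rng.normal(config.base_abundance_mu, config.base_abundance_sigma, size=n)

    fractions = [
        FRACTION_LABELS[f] if f < len(FRACTION_LABELS) else f"F{f + 1}"
        for f in range(config.n_fractions)
    ]
    fidx = np.arange(config.n_fractions, dtype=float)
    true_log = base[:, None] + slopes[:, None] * fidx[None, :]
    obs_log = true_log + rng.normal(0.0, config.noise_sigma, size=true_log.shape)
    detected = rng.random(true_log.shape) < _detection_prob(true_log, config)
    member_ibaq = np.where(detected, 10.0**obs_log, np.nan)

    # isoform groups: pair proteins within the same (non-contaminant) class
    group_of = np.array([""] * n, dtype=object)
    groups: list[tuple[str, int, int]] = []
    eligible = np.flatnonzero(~is_contaminant)
    rng.shuffle(eligible)
    pool_mem = [i for i in eligible if is_membrane[i]]
    pool_bg = [i for i in eligible if not is_membrane[i]]
    for g in range(config.n_isoform_groups):
        pool = pool_mem if (g % 2 == 0 and len(pool_mem) >= 2) else pool_bg
        if len(pool) < 2:
            break
        a, b = pool.pop(), pool.pop()
        gid = f"G{g + 1:02d}"
        group_of[a] = group_of[b] = gid
        groups.append((gid, a, b))

    # assemble the quantified matrix: group rows replace member rows
    row_ids, rows, cont_flags, tm_flags = [], [], [], []
    grouped = {a for _, a, _ in groups} | {b for _, _, b in groups}
    for i in range(n):
        if i in grouped:
            continue
        row_ids.append(ids[i])
        rows.append(member_ibaq[i])
        cont_flags.append(is_contaminant[i])
        tm_flags.append(bool(is_membrane[i]))
    for gid, a, b in groups:
        row_ids.append(gid)
        with np.errstate(invalid="ignore"):
            merged = np.nansum(np.vstack([member_ibaq[a], member_ibaq[b]]), axis=0)
        merged[~(detected[a] | detected[b])] = np.nan
        rows.append(merged)
        cont_flags.append(False)
        tm_flags.append(bool(is_membrane[a] or is_membrane[b]))

    values = pd.DataFrame(np.vstack(rows), index=row_ids, columns=fractions)
    matrix = QuantMatrix(
        values,
        contaminant=pd.Series(cont_flags, index=row_ids),
        tm_helix=pd.Series(tm_flags, index=row_ids),
    )

    # peptide evidence: two shared + one isoform-unique peptide per member
    pep_rows = []
    for gid, a, b in groups:
        ia = np.nan_to_num(member_ibaq[a])
        ib = np.nan_to_num(member_ibaq[b])
        shared = 0.3 * (ia + ib)
        for k in range(2):
            pep_rows.append(
                {
                    "peptide_id": f"{gid}_sh{k + 1}",
                    "sequence": f"SHARED{gid}{k + 1}K",
                    "parent_group": gid,
                    "unique_to": np.nan,
                    **{fr: (v if v > 0 else np.nan) for fr, v in zip(fractions, shared)},
                }
            )
        for member, inten in ((ids[a], ia), (ids[b], ib)):
            pep_rows.append(
                {
                    "peptide_id": f"{gid}_{member}_u1",
                    "sequence": f"UNIQ{member}K",
                    "parent_group": gid,
                    "unique_to": member,
                    **{fr: (0.2 * v if v > 0 else np.nan) for fr, v in zip(fractions, inten)},
                }
            )
    pep_cols = ["peptide_id", "sequence", "parent_group", "unique_to", *fractions]
    peptides = PeptideEvidence(pd.DataFrame(pep_rows, columns=pep_cols))

    truth = pd.DataFrame(
        {
            "protein_id": ids,
            "is_membrane": is_membrane,
            "is_contaminant": is_contaminant,
            "true_slope": slopes,
            "base_log10": base,
            "isoform_group": [g if g else np.nan for g in group_of],
        }
    ).set_index("protein_id")
    return peptides, matrix, truth


def purification_design(config: SimulationConfig) -> StudyDesign:
    fractions = [
        FRACTION_LABELS[f] if f < len(FRACTION_LABELS) else f"F{f + 1}"
        for f in range(config.n_fractions)
    ]
    return StudyDesign(
        fraction_order=fractions,
        sample_fraction={f: f for f in fractions},
    )


def simulate_ip(
    config: IPSimulationConfig, totals: QuantMatrix
) -> tuple[QuantMatrix, StudyDesign]:
    """Generate specific and control immunoaffinity eluates.

    ``totals`` holds the starting-material runs (availability = run-mean
    intensity).  Specific runs contain the bait (full capture) and each
    partner at its capture efficiency, both concentrated by the shared
    eluate concentration factor; nonspecific background is sampled from
    the same abundance-weighted per-run Bernoulli process into control
    and specific runs alike.  All eluate values carry multiplicative
    log-normal noise.  Returns the combined eluate matrix plus a design
    covering the total, specific and control runs.
    """
    avail = totals.values.mean(axis=1)
    if config.bait_id not in avail.index or not np.isfinite(avail[config.bait_id]):
        raise ValidationError(f"bait {config.bait_id!r} not present in totals")
    for pid, _ in config.true_partners:
        if pid not in avail.index or not np.isfinite(avail[pid]):
            raise ValidationError(f"partner {pid!r} not present in totals")

    rng = np.random.default_rng(config.seed)
    spec_runs = [f"specific_{i + 1}" for i in range(config.n_specific_runs)]
    ctrl_runs = [f"control_{i + 1}" for i in range(config.n_control_runs)]
    proteins = avail.index
    n = len(proteins)
    eluate = pd.DataFrame(np.nan, index=proteins, columns=spec_runs + ctrl_runs)

    def noise(size):
        return np.exp(rng.normal(0.0, config.eluate_noise_sigma, size=size))

    capture = {config.bait_id: 1.0, **dict(config.true_partners)}
    for pid, eff in capture.items():
        level = eff * avail[pid] * config.concentration_factor
        eluate.loc[pid, spec_runs] = level * noise(len(spec_runs))

    # abundance-weighted nonspecific carry-over, identical process both sides:
    # per-run detection probability proportional to a protein's share of the
    # total signal, so the abundant proteins dominate the control eluates
    a = avail.fillna(0.0).to_numpy(dtype=float)
    weight = np.minimum(a / a.mean(), 1.0) if a.mean() > 0 else np.zeros(n)
    p_det = config.nonspecific_rate * weight
    for run in spec_runs + ctrl_runs:
        hit = rng.random(n) < p_det
        level = config.nonspecific_level * a * config.concentration_factor
        vals = np.where(hit, level * noise(n), np.nan)
        col = pd.Series(vals, index=proteins)
        if run in spec_runs:
            # nonspecific signal adds to any specific signal already present
            existing = eluate[run]
            eluate[run] = existing.where(col.isna(), existing.fillna(0.0) + col.fillna(0.0))
        else:
            eluate[run] = col
    eluate = eluate.mask(eluate <= 0)

    design = StudyDesign(
        ip_conditions={
            **{s: "total" for s in totals.samples},
            **{r: "specific" for r in spec_runs},
            **{r: "control" for r in ctrl_runs},
        }
    )
    return (
        QuantMatrix(eluate, contaminant=totals.contaminant, tm_helix=totals.tm_helix),
        design,
    )


def default_ip_dataset(
    seed: int,
    n_proteins: int = 200,
    n_total_runs: int = 3,
    n_partners: int = 5,
    eluate_noise_sigma: float = 0.3,
    nonspecific_rate: float = 0.3,
) -> tuple[QuantMatrix, QuantMatrix, StudyDesign, IPSimulationConfig]:
    """Canonical immunoaffinity fixture: a rare bait with planted partners.

    Totals are log-normal (log10 mean 6, sigma 1.5).  The bait and its
    partners sit in the lower-middle of the abundance range -- the regime
    the purification targets, where the complex is far less abundant than
    the nonspecific background.  Capture efficiencies span 0.1-0.9.
    Returns ``(totals, eluate, design, config)``; design covers total,
    specific and control runs.
    """
    rng = np.random.default_rng(seed)
    ids = [f"P{i:04d}" for i in range(1, n_proteins + 1)]
    base = rng.normal(6.0, 1.5, size=n_proteins)
    tot = pd.DataFrame(
        10.0 ** (base[:, None] + rng.normal(0.0, 0.2, size=(n_proteins, n_total_runs))),
        index=ids,
        columns=[f"total_{i + 1}" for i in range(n_total_runs)],
    )
    totals = QuantMatrix(tot)
    order = np.argsort(base)
    # bait and partners drawn from the 15th-50th abundance percentiles
    lo, hi = int(0.15 * n_proteins), int(0.50 * n_proteins)
    picks = order[np.linspace(lo, hi - 1, n_partners + 1).astype(int)]
    bait = ids[picks[0]]
    effs = np.linspace(0.9, 0.1, n_partners)
    partners = [(ids[i], float(e)) for i, e in zip(picks[1:], effs)]
    cfg = IPSimulationConfig(
        bait_id=bait,
        true_partners=partners,
        eluate_noise_sigma=eluate_noise_sigma,
        nonspecific_rate=nonspecific_rate,
        seed=seed,
    )
    eluate, design = simulate_ip(cfg, totals)
    return totals, eluate, design, cfg


def simulate_prm(config: PRMSimulationConfig) -> ChromatogramSet:
    """Generate fragment-ion chromatograms with Gaussian co-eluting peaks.

    Fragments of a peptide share the apex (``true_rt``) and width
    (``peak_width_sigma``); the fragment amplitude is the peptide
    amplitude times the fragment's relative intensity.  Additive noise is
    folded-normal with scale ``noise_floor`` (intensities stay >= 0).
    One matched MS2 event is drawn near the apex with probability
    ``ms2_event_prob_at_apex`` per run.  Ground truth stores the analytic
    Gaussian area ``A * sigma * sqrt(2*pi)`` per fragment.
    """
    from .prm_quant import Chromatogram  # local import to avoid a cycle

    rng = np.random.default_rng(config.seed)
    lo, hi = config.run_window
    t = np.arange(lo, hi + config.sampling_interval / 2, config.sampling_interval)
    sig = config.peak_width_sigma

    chroms, events, truth = [], [], []
    for run in config.runs:
        for pep in config.peptides:
            for frag, rel in pep.fragments.items():
                amp = pep.amplitude * rel
                y = amp * np.exp(-0.5 * ((t - pep.true_rt) / sig) ** 2)
                if config.noise_floor > 0:
                    y = y + np.abs(rng.normal(0.0, config.noise_floor, size=t.shape))
                chroms.append(Chromatogram(run, pep.sequence, frag, t.copy(), y))
                truth.append(
                    {
                        "run": run,
                        "peptide": pep.sequence,
                        "fragment": frag,
                        "true_area": amp * sig * np.sqrt(2.0 * np.pi),
                        "true_rt": pep.true_rt,
                    }
                )
            if rng.random() < config.ms2_event_prob_at_apex:
                events.append(
                    {
                        "run": run,
                        "peptide": pep.sequence,
                        "time_min": float(
                            np.clip(pep.true_rt + rng.normal(0.0, sig / 2), lo, hi)
                        ),
                        "matched": True,
                    }
                )
    ms2 = pd.DataFrame(events, columns=["run", "peptide", "time_min", "matched"])
    return ChromatogramSet(chroms, ms2, pd.DataFrame(truth))
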