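"""Core data containers shared across the pipeline.

The central currency of the label-free half is the :class:`QuantMatrix`, a
proteins x samples table of non-negative intensities (iBAQ or riBAQ) in which
missing values are explicit ``NaN`` -- a protein is *detected* in a sample iff
a positive intensity is present.  Zero intensities are coerced to missing so
that count-of-runs detection filters behave consistently.

:class:`StudyDesign` maps sample ids either onto an ordered series of
purification fractions (unit index spacing) or onto immunoprecipitation run
conditions (``total`` / ``control`` / ``specific``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

IP_CONDITIONS = ("total", "control", "specific")


class ValidationError(ValueError):
    """Raised when an input table violates a structural contract."""


@dataclass
class QuantMatrix:
    """Proteins x samples intensity table with per-protein annotation flags.

    Parameters
    ----------
    values
        DataFrame indexed by protein id with one column per sample id.
        ``NaN`` marks a value that was not detected; all present values
        must be positive.
    contaminant
        Boolean series (indexed like ``values``) flagging contaminant
        entries from the upstream search-engine output.
    tm_helix
        Boolean series flagging proteins annotated with a transmembrane
        helix.
    """

    values: pd.DataFrame
    contaminant: pd.Series = None
    tm_helix: pd.Series = None
    log_scale: bool = False

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate protein id: {dup!r}")
        if not self.values.columns.is_unique:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        if self.contaminant is None:
            self.contaminant = pd.Series(False, index=self.values.index)
        if self.tm_helix is None:
            self.tm_helix = pd.Series(False, index=self.values.index)
        self.contaminant = self.contaminant.reindex(self.values.index, fill_value=False).astype(bool)
        self.tm_helix = self.tm_helix.reindex(self.values.index, fill_value=False).astype(bool)
        if not self.log_scale:
            arr = self.values.to_numpy(dtype=float)
            if np.any(arr[np.isfinite(arr)] < 0):
                raise ValidationError("intensities must be non-negative")
            # zero intensity == not detected
            self.values = self.values.mask(self.values == 0.0)

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def detected(self) -> pd.DataFrame:
        """Boolean detection mask (positive intensity present)."""
        return self.values.notna()

    def subset_samples(self, samples) -> "QuantMatrix":
        return QuantMatrix(
            self.values[list(samples)].copy(),
            contaminant=self.contaminant.copy(),
            tm_helix=self.tm_helix.copy(),
            log_scale=self.log_scale,
        )

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(
            self.values.copy(),
            contaminant=self.contaminant.copy(),
            tm_helix=self.tm_helix.copy(),
            log_scale=self.log_scale,
        )


@dataclass
class StudyDesign:
    """Sample-to-condition mapping for both halves of the analysis.

    ``fraction_order`` lists purification-fraction labels in enrichment
    order; the integer index (0, 1, 2, ...) of a label is the regressor
    used by the enrichment-slope fit (unit spacing).  ``sample_fraction``
    maps sample ids onto fraction labels, so several technical-replicate
    samples may share a fraction.  ``ip_conditions`` maps IP run ids onto
    ``total`` / ``control`` / ``specific``.
    """

    fraction_order: list[str] = field(default_factory=list)
    sample_fraction: dict[str, str] = field(default_factory=dict)
    ip_conditions: dict[str, str] = field(default_factory=dict)
    replicate: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.fraction_order)) != len(self.fraction_order):
            raise ValidationError("fraction labels must be unique")
        for run, cond in self.ip_conditions.items():
            if cond not in IP_CONDITIONS:
                raise ValidationError(
                    f"run {run!r}: condition {cond!r} not one of {IP_CONDITIONS}"
                )
        for sample, frac in self.sample_fraction.items():
            if frac not in self.fraction_order:
                raise ValidationError(
                    f"sample {sample!r} maps to unknown fraction {frac!r}"
                )

    def fraction_index(self, sample: str) -> int:
        """Integer position of the sample's fraction in the enrichment order."""
        return self.fraction_order.index(self.sample_fraction[sample])

    def runs(self, condition: str) -> list[str]:
        if condition not in IP_CONDITIONS:
            raise ValidationError(f"unknown condition {condition!r}")
        return [r for r, c in self.ip_conditions.items() if c == condition]


@dataclass
class PeptideEvidence:
    """Peptide-level intensities with parent-group / isoform annotation.

    ``table`` columns: ``peptide_id``, ``sequence``, ``parent_group``,
    ``unique_to`` (isoform id, or NaN for a shared peptide), plus one
    intensity column per sample.
    """

    table: pd.DataFrame

    REQUIRED = ("peptide_id", "sequence", "parent_group", "unique_to")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"peptide table missing columns: {missing}")
        if self.table["peptide_id"].duplicated().any():
            dup = self.table.loc[self.table["peptide_id"].duplicated(), "peptide_id"].iloc[0]
            raise ValidationError(f"duplicate peptide id: {dup!r}")

    @property
    def sample_columns(self) -> list[str]:
        return [c for c in self.table.columns if c not in self.REQUIRED]

    def for_group(self, group: str) -> pd.DataFrame:
        return self.table[self.table["parent_group"] == group]
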