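"""Label-free quantitation primitives.

riBAQ (relative iBAQ) estimates the molar fraction of each protein in a
sample: a protein's iBAQ divided by the summed iBAQ of all non-contaminant
proteins detected in the same sample.  Isoform apportionment splits a
protein-group riBAQ between isoforms in proportion to the summed intensity
of the peptides unique to each isoform.  The log2/median-normalization step
prepares riBAQ matrices for moderated differential testing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import PeptideEvidence, QuantMatrix, ValidationError


def compute_ribaq(m: QuantMatrix) -> QuantMatrix:
    """Convert an iBAQ matrix to riBAQ, excluding contaminants.

    Per sample, ``ribaq_i = ibaq_i / sum_j ibaq_j`` where the sum runs over
    detected non-contaminant proteins.  Contaminant rows are dropped from
    the output.  Missing values stay missing.

    Raises
    ------
    ValidationError
        If a sample carries no non-contaminant signal (the message names
        the offending sample).
    """
    keep = ~m.contaminant
    vals = m.values.loc[keep]
    denom = vals.sum(axis=0, skipna=True)
    dead = denom[(denom <= 0) | denom.isna()]
    if len(dead):
        raise ValidationError(
            f"sample {dead.index[0]!r} has no non-contaminant signal; "
            "cannot normalize to riBAQ"
        )
    out = vals.div(denom, axis=1)
    return QuantMatrix(
        out,
        contaminant=m.contaminant.loc[keep],
        tm_helix=m.tm_helix.loc[keep],
    )


def apportion_isoforms(
    group_value: pd.Series, evidence: PeptideEvidence | pd.DataFrame
) -> pd.DataFrame:
    """Split a protein-group riBAQ across isoforms, per sample.

    For each sample, isoform ``k`` receives the share
    ``sum(intensity of peptides unique to k) / sum(intensity of all
    isoform-unique peptides in the group)`` of the group value.  Shared
    peptides never contribute to shares.  Samples with no detected
    isoform-unique peptide yield missing isoform values (not zero).

    Parameters
    ----------
    group_value
        Group riBAQ indexed by sample id.
    evidence
        Peptide rows of one group: ``unique_to`` column plus intensity
        columns matching ``group_value``'s index.

    Returns
    -------
    DataFrame indexed by isoform id, one column per sample.
    """
    table = evidence.table if isinstance(evidence, PeptideEvidence) else evidence
    uniq = table[table["unique_to"].notna()]
    if uniq.empty:
        raise ValidationError("group has no isoform-unique peptides")
    samples = list(group_value.index)
    inten = uniq[samples].astype(float).fillna(0.0)
    per_iso = inten.groupby(uniq["unique_to"]).sum()
    total = per_iso.sum(axis=0)
    shares = per_iso.div(total.where(total > 0), axis=1)  # NaN when nothing detected
    return shares.mul(group_value, axis=1)


def log2_median_normalize(m: QuantMatrix) -> QuantMatrix:
    """log2-transform and set every sample's median to zero.

    Detected values must be positive.  A sample with fewer than two
    detected values has no meaningful median and raises.
    """
    counts = m.detected().sum(axis=0)
    low = counts[counts < 2]
    if len(low):
        raise ValidationError(
            f"sample {low.index[0]!r} has {int(low.iloc[0])} detected values; "
            "need at least 2 for median normalization"
        )
    logged = np.log2(m.values)
    centered = logged.sub(logged.median(axis=0, skipna=True), axis=1)
    return QuantMatrix(
        centered, contaminant=m.contaminant, tm_helix=m.tm_helix, log_scale=True
    )
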