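"""Small bundled reference inputs.

The per-fraction protein assays and target-protein (PTPRQ) targeted-PRM
intensities of the published D10 stereocilia-membrane purification: total
protein per fraction (µg, mean of two ~1000-ear preparations) and the
fraction's total PRM intensity.  The per-µg intensity -- the quantity the
instrument measures on equal-load injections -- is total intensity divided
by total protein.
"""

from __future__ import annotations

import pandas as pd

# fraction -> (total protein µg, total PRM intensity)
_D10_PTPRQ = {
    "S1": (109_000.0, 2.63e10),  # post-nuclear supernatant (PNS)
    "S2": (100_000.0, 0.35e10),  # 7000 rpm supernatant
    "P2": (36_400.0, 2.56e10),  # dense membranes
    "M3": (2_680.0, 0.34e10),  # D10-bound
    "S6": (29_200.0, 0.32e10),  # cytoplasm
    "P6": (984.0, 0.28e10),  # membranes
    "S7": (1_037.0, 1.13e10),  # RIPA-soluble
}


def d10_ptprq_assays() -> pd.DataFrame:
    """PTPRQ fraction assays of the D10 purification.

    Returns a DataFrame indexed by fraction label with columns
    ``total_protein_ug`` and ``intensity_per_ug``, ready for
    :func:`stereoquant.prm_quant.fraction_of_reference` (reference: S1)
    and :func:`stereoquant.prm_quant.per_ug_fold_enrichment`.
    """
    rows = {
        frac: {"total_protein_ug": ug, "intensity_per_ug": total / ug}
        for frac, (ug, total) in _D10_PTPRQ.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "fraction"
    return df
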