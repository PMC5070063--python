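"""Comparative-Ct (2^-ddCt) relative quantification for qPCR confirmation.

Each sample's target-gene threshold cycle is normalized against a reference
(housekeeping) gene measured in the same sample:

    dCt_sample = Ct_target - Ct_reference

and the relative fold change between a case and a control group is

    fold = E^-(mean dCt_case - mean dCt_control)

with amplification efficiency E defaulting to 2.0 (100% efficiency, one
doubling per cycle).  Duplicate technical reactions are averaged on the Ct
scale before differencing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_REFERENCE = "GAPDH"
CT_COLUMNS = ["sample", "group", "gene", "ct"]


class QPCRError(ValueError):
    pass


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise QPCRError(f"Ct table missing columns: {missing}")
    ct = table["ct"].to_numpy(dtype=float)
    if not np.isfinite(ct).all() or (ct <= 0).any():
        raise QPCRError("Ct values must be positive and finite")
    return table


def _mean_ct(table: pd.DataFrame, gene: str) -> pd.Series:
    """Per-sample Ct for one gene, technical replicates averaged."""
    sub = table[table["gene"] == gene]
    if sub.empty:
        raise QPCRError(f"gene {gene!r} absent from Ct table")
    return sub.groupby("sample")["ct"].mean()


def delta_ct(
    table: pd.DataFrame, target_gene: str, reference_gene: str = DEFAULT_REFERENCE
) -> pd.Series:
    """Per-sample dCt = Ct_target - Ct_reference."""
    table = _validate(table)
    target = _mean_ct(table, target_gene)
    ref_rows = table[table["gene"] == reference_gene]
    reference = ref_rows.groupby("sample")["ct"].mean()
    missing_ref = [s for s in target.index if s not in reference.index]
    if missing_ref:
        raise QPCRError(
            f"sample(s) without reference-gene {reference_gene!r} Ct: "
            f"{missing_ref[:5]}"
        )
    out = target - reference.loc[target.index]
    out.name = "delta_ct"
    return out


def fold_change(
    table: pd.DataFrame,
    target_gene: str,
    case_label: str,
    control_label: str,
    reference_gene: str = DEFAULT_REFERENCE,
    efficiency: float = 2.0,
) -> float:
    """Relative fold change of the case group: efficiency**(-ddCt)."""
    if efficiency <= 1.0:
        raise QPCRError(f"amplification efficiency must exceed 1.0: {efficiency}")
    table = _validate(table)
    dct = delta_ct(table, target_gene, reference_gene)
    group_of = table.drop_duplicates("sample").set_index("sample")["group"]
    case = dct[group_of.loc[dct.index] == case_label]
    control = dct[group_of.loc[dct.index] == control_label]
    if case.empty or control.empty:
        raise QPCRError(
            f"empty group: case {case_label!r} n={len(case)}, "
            f"control {control_label!r} n={len(control)}"
        )
    ddct = case.mean() - control.mean()
    return float(efficiency ** (-ddct))


def read_ct_tsv(path) -> pd.DataFrame:
    return _validate(pd.read_csv(path, sep="\t"))
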