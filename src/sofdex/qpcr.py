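"""Relative expression from Cq tables via the comparative (ΔΔCq) method.

ΔCq normalizes each gene to a control gene within the same sample
(Cq_gene − Cq_control); ΔΔCq differences ΔCq between a test and a reference
condition; relative expression is 2^−ΔΔCq. Replicates are averaged on the
Cq scale by default (equivalent to a geometric mean of expression); averaging
on the expression scale is available via ``aggregate="expression"``.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

CQ_COLUMNS = ("sample_id", "condition", "gene", "cq")


def _check_table(cq: pd.DataFrame) -> None:
    missing = set(CQ_COLUMNS) - set(cq.columns)
    if missing:
        raise ValueError(f"Cq table missing columns: {sorted(missing)}")
    if not np.isfinite(cq["cq"].to_numpy(dtype=float)).all():
        raise ValueError("Cq values must be finite")


def delta_cq(cq: pd.DataFrame, control_gene: str) -> pd.DataFrame:
    """Per-sample, per-gene ΔCq = Cq_gene − Cq_control.

    The control gene's own ΔCq is 0 in every sample. Raises if any sample
    lacks the control gene.
    """
    _check_table(cq)
    ctrl = cq[cq["gene"] == control_gene].set_index("sample_id")["cq"]
    missing = [s for s in cq["sample_id"].unique() if s not in ctrl.index]
    if missing:
        raise ValueError(f"control gene {control_gene!r} missing in "
                         f"sample(s): {missing}")
    out = cq.copy()
    out["delta_cq"] = out["cq"].to_numpy() - ctrl.loc[out["sample_id"]].to_numpy()
    return out


def delta_delta_cq(dcq: pd.DataFrame, test_condition: str,
                   reference_condition: str, *,
                   aggregate: str = "cq") -> pd.Series:
    """Per-gene ΔΔCq = mean ΔCq(test) − mean ΔCq(reference).

    ``aggregate="cq"`` (default) averages replicate ΔCq values on the cycle
    scale; ``"expression"`` averages 2^−ΔCq and converts back. Raises if a
    gene lacks either condition.
    """
    if "delta_cq" not in dcq.columns:
        raise ValueError("input must come from delta_cq()")
    if aggregate not in ("cq", "expression"):
        raise ValueError(f"unknown aggregate mode {aggregate!r}")

    out = {}
    for gene, grp in dcq.groupby("gene", sort=True):
        parts = {}
        for cond in (test_condition, reference_condition):
            vals = grp.loc[grp["condition"] == cond, "delta_cq"].to_numpy()
            if vals.size == 0:
                raise ValueError(f"gene {gene!r} has no measurements in "
                                 f"condition {cond!r}")
            if aggregate == "cq":
                parts[cond] = vals.mean()
            else:
                parts[cond] = -np.log2(np.mean(2.0 ** (-vals)))
        out[gene] = parts[test_condition] - parts[reference_condition]
    return pd.Series(out, name="delta_delta_cq")


def rel_expression(ddcq) -> pd.Series:
    """Relative expression 2^−ΔΔCq (strictly positive; 1 iff ΔΔCq = 0)."""
    arr = np.asarray(ddcq, dtype=float)
    vals = 2.0 ** (-arr)
    if isinstance(ddcq, pd.Series):
        return pd.Series(vals, index=ddcq.index, name="rel_expression")
    return vals


def quantify(cq: pd.DataFrame, control_gene: str, test_condition: str,
             reference_condition: str, *, aggregate: str = "cq") -> pd.DataFrame:
    """ΔCq → ΔΔCq → 2^−ΔΔCq in one call; one row per gene."""
    dcq = delta_cq(cq, control_gene)
    ddcq = delta_delta_cq(dcq, test_condition, reference_condition,
                          aggregate=aggregate)
    return pd.DataFrame({"delta_delta_cq": ddcq,
                         "rel_expression": rel_expression(ddcq)})
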