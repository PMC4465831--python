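"""Affinity bookkeeping: per-domain ΔG tables and DNA-binding cooperativity.

The binding cooperativity between two DNA-bound transcription factors is
estimated as the sum of the partner-induced changes in the binding free
energy of each domain:

    ΔΔG_coop = [ΔG_S(+partner) − ΔG_S(−partner)]
             + [ΔG_HD(+partner) − ΔG_HD(−partner)]

which assumes the partner alters neither the inter-domain cooperativity nor
the linker contribution.  Errors combine in quadrature (the four profiles are
independent).  A packaged reference table for the OCT4/SOX2/UTF1 system is
included for regression checks; an audit routine recomputes the cooperativity
column from the four ΔG columns and flags internally inconsistent rows.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "AFFINITY_COLUMNS",
    "load_affinity_table",
    "reference_affinity_table",
    "cooperativity",
    "cooperativity_error",
    "domain_deltas",
    "table_audit",
    "round2",
]

#: required ΔG/error columns of an affinity table ("apo" = without partner)
AFFINITY_COLUMNS = (
    "dG_pou_s_apo", "dG_pou_hd_apo", "dG_pou_s_sox2", "dG_pou_hd_sox2",
)
ERROR_COLUMNS = (
    "err_pou_s_apo", "err_pou_hd_apo", "err_pou_s_sox2", "err_pou_hd_sox2",
)


def round2(x) -> np.ndarray:
    """Round to 2 decimals, half away from zero (table convention)."""
    x = np.asarray(x, dtype=float)
    # the epsilon absorbs binary representation error of exact .xx5 inputs
    return np.sign(x) * np.floor(np.abs(x) * 100 + 0.5 + 1e-9) / 100


def _validate(table: pd.DataFrame, need_errors: bool = False) -> None:
    for col in AFFINITY_COLUMNS:
        if col not in table:
            raise KeyError(f"missing affinity column {col!r}")
        if table[col].isna().any():
            row = table.loc[table[col].isna(), "threshold"].iloc[0]
            raise ValueError(f"missing {col!r} value at threshold {row}")
    if need_errors:
        for col in ERROR_COLUMNS:
            if col not in table:
                raise KeyError(f"missing error column {col!r}")
            if (table[col] < 0).any():
                raise ValueError(f"negative error in {col!r}")
    thr = table["threshold"].to_numpy()
    if len(thr) > 1 and not np.all(np.diff(thr) > 0):
        raise ValueError("thresholds must be strictly increasing")


def load_affinity_table(path: Union[str, Path]) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    _validate(table)
    return table


def reference_affinity_table() -> pd.DataFrame:
    """The packaged per-domain affinity table of the OCT4/SOX2/UTF1 system
    (ΔG ± error per bound/unbound threshold, with and without SOX2, plus the
    published cooperativity column for auditing)."""
    with resources.as_file(
        resources.files("coopbind.data") / "oct4_sox2_utf1_affinities.tsv"
    ) as p:
        return load_affinity_table(p)


def cooperativity(table: pd.DataFrame) -> pd.DataFrame:
    """ΔΔG_coop per threshold: sum of the partner-induced per-domain changes,
    reported to 2 decimals."""
    _validate(table)
    delta_s = table["dG_pou_s_sox2"] - table["dG_pou_s_apo"]
    delta_hd = table["dG_pou_hd_sox2"] - table["dG_pou_hd_apo"]
    out = pd.DataFrame(
        {"threshold": table["threshold"],
         "ddG_coop": round2(delta_s + delta_hd)}
    )
    return out


def cooperativity_error(table: pd.DataFrame) -> pd.DataFrame:
    """Quadrature combination of the four per-domain errors, 2 decimals."""
    _validate(table, need_errors=True)
    err = np.sqrt(sum(table[c].to_numpy() ** 2 for c in ERROR_COLUMNS))
    return pd.DataFrame(
        {"threshold": table["threshold"], "ddG_coop_err": round2(err)}
    )


def domain_deltas(table: pd.DataFrame) -> pd.DataFrame:
    """Per-threshold signed differences (2 decimals, quadrature errors):

    * ``delta_s`` / ``delta_hd`` — partner-induced affinity change per domain
    * ``hd_minus_s_apo`` — ΔG_HD − ΔG_S without the partner (negative when
      the homeodomain binds stronger)
    * ``s_minus_hd_sox2`` — ΔG_S − ΔG_HD with the partner
    """
    _validate(table, need_errors=True)

    def q(*cols):
        return np.sqrt(sum(table[c].to_numpy() ** 2 for c in cols))

    return pd.DataFrame(
        {
            "threshold": table["threshold"],
            "delta_s": round2(table["dG_pou_s_sox2"] - table["dG_pou_s_apo"]),
            "delta_s_err": round2(q("err_pou_s_sox2", "err_pou_s_apo")),
            "delta_hd": round2(table["dG_pou_hd_sox2"] - table["dG_pou_hd_apo"]),
            "delta_hd_err": round2(q("err_pou_hd_sox2", "err_pou_hd_apo")),
            "hd_minus_s_apo": round2(
                table["dG_pou_hd_apo"] - table["dG_pou_s_apo"]
            ),
            "hd_minus_s_apo_err": round2(q("err_pou_hd_apo", "err_pou_s_apo")),
            "s_minus_hd_sox2": round2(
                table["dG_pou_s_sox2"] - table["dG_pou_hd_sox2"]
            ),
            "s_minus_hd_sox2_err": round2(
                q("err_pou_s_sox2", "err_pou_hd_sox2")
            ),
        }
    )


def table_audit(table: pd.DataFrame,
                tolerance: float = 0.01) -> pd.DataFrame:
    """Internal-consistency report for an affinity table.

    Recomputes the cooperativity from the four ΔG columns and flags rows
    where a provided ``printed_cooperativity`` column disagrees by more than
    ``tolerance``; also flags thresholds at which any ΔG column breaks the
    monotone trend of its neighbors.  Inconsistent rows are reported, never
    silently corrected.
    """
    _validate(table)
    recomputed = cooperativity(table)["ddG_coop"].to_numpy()
    out = pd.DataFrame(
        {"threshold": table["threshold"], "recomputed_cooperativity": recomputed}
    )
    if "printed_cooperativity" in table:
        printed = table["printed_cooperativity"].to_numpy()
        out["printed_cooperativity"] = printed
        out["consistent"] = np.abs(printed - recomputed) <= tolerance + 1e-12
    else:
        out["consistent"] = True

    # monotonicity: a column that reverses direction between neighbors is
    # suspicious for a threshold sweep of a single profile
    flags = np.zeros(len(table), dtype=bool)
    for col in AFFINITY_COLUMNS:
        v = table[col].to_numpy()
        d = np.diff(v)
        for i in range(1, len(d)):
            if d[i] * d[i - 1] < 0:  # direction reversal at row i
                flags[i] = True
                flags[i + 1] = True
    out["non_monotone"] = flags
    return out
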