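"""Report tables: chemical-space summaries and benchmark/importance exports."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .descriptors import lipinski_profile, mol_from_smiles


def chemical_space_table(compounds: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-compound rule-of-five profile plus per-class box-plot statistics.

    Returns ``(table, summary)``: the table holds MW, ALogP, nHBDon, nHBAcc
    and activity_class per compound; the summary holds min / quartiles / max
    per activity class and descriptor.  Classes absent from the input are
    absent from the summary, not zero-filled.
    """
    profiles = []
    for cid, smi, cls in zip(
        compounds["compound_id"], compounds["smiles"], compounds["activity_class"]
    ):
        p = lipinski_profile(mol_from_smiles(smi, compound_id=str(cid)))
        profiles.append(
            {
                "compound_id": cid,
                "MW": p.MW,
                "ALogP": p.ALogP,
                "nHBDon": p.nHBDon,
                "nHBAcc": p.nHBAcc,
                "activity_class": cls,
            }
        )
    table = pd.DataFrame(profiles)
    rows = []
    for cls, grp in table.groupby("activity_class", sort=False):
        for desc in ("MW", "ALogP", "nHBDon", "nHBAcc"):
            q1, med, q3 = np.percentile(grp[desc], [25, 50, 75])
            rows.append(
                {
                    "activity_class": cls,
                    "descriptor": desc,
                    "min": float(grp[desc].min()),
                    "q1": float(q1),
                    "median": float(med),
                    "q3": float(q3),
                    "max": float(grp[desc].max()),
                    "n": len(grp),
                }
            )
    return table, pd.DataFrame(rows)


def benchmark_row(report, family: str) -> dict:
    """One benchmark-table row (mean +/- SD of the six metrics, margins)."""
    out = {"family": family, "n_descriptors": len(report.mean_importance), "n_runs": report.n_runs}
    for m in ("R2_tr", "RMSE_tr", "Q2_cv", "RMSE_cv", "Q2_ext", "RMSE_ext"):
        out[f"{m}_mean"] = report.mean[m]
        out[f"{m}_sd"] = report.sd[m]
    out["margin_cv"] = report.margin_cv
    out["margin_ext"] = report.margin_ext
    return out
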