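"""Relative expression from qPCR cycle thresholds by the 2^-ddCt (Livak) method.

Technical replicates are averaged on the Ct scale per (sample, gene); each
sample's dCt is the target Ct minus the reference-gene Ct; the group-level
ddCt subtracts the calibrator group's mean dCt; fold change is 2^-ddCt, so
the calibrator's own fold is 1 by construction and one cycle of dCt
difference corresponds to a two-fold change.  Per-sample fold changes
(2^-(dCt_sample - mean dCt_calibrator)) are emitted alongside the group
summary so any downstream statistics package can consume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CT_COLUMNS = ["sample_id", "group", "tissue", "gene", "replicate", "ct"]


@dataclass
class RelativeExpression:
    """2^-ddCt results for one target gene against one calibrator group.

    ``summary``: per (group, tissue) mean dCt, ddCt and fold change.
    ``per_sample``: each sample's dCt and fold change.
    """

    target_gene: str
    reference_gene: str
    calibrator_group: str
    summary: pd.DataFrame = field(repr=False)
    per_sample: pd.DataFrame = field(repr=False)


def _validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive cycle counts")
    return table


def delta_delta_ct(
    table: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    calibrator_group: str,
) -> RelativeExpression:
    """Relative expression of ``target_gene`` normalized to ``reference_gene``.

    ``table`` needs columns ``sample_id, group, tissue, gene, replicate, ct``.
    ddCt is computed per tissue: within each tissue, every group's mean dCt
    is referenced to the calibrator group's mean dCt in that same tissue.
    Raises if the reference gene is missing for any sample that has the
    target, or if the calibrator group is absent.
    """
    table = _validate_ct_table(table)
    sub = table[table["gene"].isin([target_gene, reference_gene])]
    if target_gene not in set(sub["gene"]):
        raise ValueError(f"target gene {target_gene!r} absent from Ct table")
    if calibrator_group not in set(table["group"]):
        raise ValueError(f"calibrator group {calibrator_group!r} absent")

    # average technical replicates on the Ct scale
    mean_ct = (
        sub.groupby(["sample_id", "group", "tissue", "gene"], sort=False)["ct"]
        .mean()
        .unstack("gene")
    )
    for gene in (target_gene, reference_gene):
        if gene not in mean_ct.columns:
            raise ValueError(f"gene {gene!r} absent from Ct table")
    lacking = mean_ct[mean_ct[reference_gene].isna()]
    if len(lacking):
        sample = lacking.index[0][0]
        raise ValueError(
            f"sample {sample!r} lacks reference gene {reference_gene!r}"
        )
    mean_ct = mean_ct.dropna(subset=[target_gene])

    per_sample = mean_ct.reset_index()
    per_sample["delta_ct"] = per_sample[target_gene] - per_sample[reference_gene]

    rows = []
    sample_rows = []
    for tissue, grp in per_sample.groupby("tissue", sort=False):
        cal = grp[grp["group"] == calibrator_group]
        if len(cal) == 0:
            raise ValueError(
                f"calibrator group {calibrator_group!r} has no samples "
                f"for tissue {tissue!r}"
            )
        cal_mean = cal["delta_ct"].mean()
        for group, g in grp.groupby("group", sort=False):
            ddct = g["delta_ct"].mean() - cal_mean
            rows.append(
                {
                    "group": group,
                    "tissue": tissue,
                    "n_samples": len(g),
                    "mean_delta_ct": g["delta_ct"].mean(),
                    "delta_delta_ct": ddct,
                    "fold_change": float(2.0 ** (-ddct)),
                }
            )
        g2 = grp.copy()
        g2["fold_change"] = 2.0 ** (-(g2["delta_ct"] - cal_mean))
        sample_rows.append(g2)

    summary = pd.DataFrame(rows)
    per_sample_out = pd.concat(sample_rows, ignore_index=True)[
        ["sample_id", "group", "tissue", "delta_ct", "fold_change"]
    ]
    return RelativeExpression(
        target_gene=target_gene,
        reference_gene=reference_gene,
        calibrator_group=calibrator_group,
        summary=summary,
        per_sample=per_sample_out,
    )


def read_ct_table(path: str) -> pd.DataFrame:
    """Read a TSV Ct table with columns sample_id, group, tissue, gene, replicate, ct."""
    return _validate_ct_table(pd.read_csv(path, sep="\t"))
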