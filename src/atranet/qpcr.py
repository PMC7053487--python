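"""Relative-expression (ddCt) and ChIP percent-of-input quantification.

Target Ct values are normalised to a reference gene within each
replicate (dCt = Ct_target - Ct_reference); the group-level ddCt is the
difference of mean dCt between a group and the control group, and the
relative quantity is 2**(-ddCt) (amplification efficiency fixed at 2).
Significance is a two-sided Student's t-test on the replicate dCt
values, performed on the dCt (log) scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CtTable


@dataclass
class RelExpression:
    """ddCt result for one target gene across sample groups."""

    gene: str
    reference_gene: str
    control_group: str
    table: pd.DataFrame  # group, n, mean_dct, ddct, rq, p
    errors: list[str]


def _delta_ct(
    table: CtTable, gene: str, reference_gene: str, group: str
) -> np.ndarray | None:
    rows = table.rows
    grp = rows[rows["sample_group"] == group]
    tgt = grp[grp["gene"] == gene].set_index("replicate")["ct"]
    ref = grp[grp["gene"] == reference_gene].set_index("replicate")["ct"]
    reps = tgt.index.intersection(ref.index)
    if len(ref) == 0 or len(reps) == 0:
        return None
    return (tgt.loc[reps] - ref.loc[reps]).to_numpy(dtype=float)


def delta_delta_ct(
    table: CtTable,
    target: str,
    reference_gene: str = "GAPDH",
    control_group: str = "C",
) -> RelExpression:
    """ddCt relative expression of ``target`` in every sample group.

    Groups missing the reference gene are skipped with an error record.
    The control group has rq = 1 by construction.
    """
    control_dct = _delta_ct(table, target, reference_gene, control_group)
    if control_dct is None:
        raise ValueError(
            f"reference or target missing in control group {control_group!r}"
        )
    errors: list[str] = []
    rows = []
    for group in table.groups():
        dct = _delta_ct(table, target, reference_gene, group)
        if dct is None:
            errors.append(f"group {group!r}: reference gene not measured; skipped")
            continue
        ddct = float(dct.mean() - control_dct.mean())
        if group == control_group:
            p = 1.0
        elif len(dct) >= 2 and len(control_dct) >= 2:
            import warnings

            with warnings.catch_warnings():
                # near-zero replicate variance is legitimate here (noiseless
                # simulations); the degenerate p is resolved below
                warnings.simplefilter("ignore", RuntimeWarning)
                p = float(stats.ttest_ind(dct, control_dct, equal_var=True).pvalue)
            if not np.isfinite(p):  # zero variance in both groups
                p = 1.0 if ddct == 0 else 0.0
        else:
            p = np.nan
        rows.append(
            {
                "group": group,
                "n": len(dct),
                "mean_dct": float(dct.mean()),
                "ddct": ddct,
                "rq": float(2.0 ** (-ddct)),
                "p": p,
            }
        )
    return RelExpression(
        gene=target,
        reference_gene=reference_gene,
        control_group=control_group,
        table=pd.DataFrame(rows, columns=["group", "n", "mean_dct", "ddct", "rq", "p"]),
        errors=errors,
    )


@dataclass(frozen=True)
class PercentInput:
    region: str
    condition: str
    percent: float
    input_fraction: float


def percent_input(
    ct_ip: float,
    ct_input: float,
    input_fraction: float = 0.01,
    region: str = "",
    condition: str = "",
) -> PercentInput:
    """ChIP enrichment as percent of the dilution-adjusted input signal.

    The input Ct is first adjusted for the fraction of chromatin used as
    input (``ct_input - log2(1/input_fraction)``); the IP signal is then
    ``100 * 2**(ct_input_adj - ct_ip)``.
    """
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must be in (0, 1]")
    ct_input_adj = ct_input - np.log2(1.0 / input_fraction)
    pct = float(100.0 * 2.0 ** (ct_input_adj - ct_ip))
    return PercentInput(
        region=region,
        condition=condition,
        percent=pct,
        input_fraction=input_fraction,
    )
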