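"""Per-cell-line differential expression and the cross-line signature.

A probe is differentially expressed when its anti-logged fold change is
above ``fc_hi`` or below ``fc_lo`` (strict inequalities) and its BH-
adjusted permutation p-value is below ``fdr_max``.  Genes differentially
expressed, with a consistent direction, in every cell line form the
differentiation signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import DIFF, UNDIFF, ExpressionMatrix

DEG_COLUMNS = [
    "probe",
    "gene",
    "fold_change",
    "t_stat",
    "p",
    "fdr",
    "is_deg",
    "direction",
]


@dataclass
class SignatureSet:
    """Genes differentially expressed in every cell line, one direction each."""

    direction: dict[str, str]
    conflicts: list[str] = field(default_factory=list)
    provenance: list[dict[str, str]] = field(default_factory=list)

    @property
    def genes(self) -> set[str]:
        return set(self.direction)

    def __len__(self) -> int:
        return len(self.direction)


def _welch_t(
    sum1: np.ndarray,
    sumsq1: np.ndarray,
    n1: int,
    sum2: np.ndarray,
    sumsq2: np.ndarray,
    n2: int,
) -> np.ndarray:
    """Welch t from per-group sums; 0/0 (no variance, no difference) -> nan."""
    m1, m2 = sum1 / n1, sum2 / n2
    v1 = np.maximum(sumsq1 / n1 - m1**2, 0.0) * n1 / (n1 - 1)
    v2 = np.maximum(sumsq2 / n2 - m2**2, 0.0) * n2 / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m2 - m1) / np.sqrt(se2)
    return t


def call_degs(
    matrix: ExpressionMatrix,
    fc_hi: float = 2.0,
    fc_lo: float = 0.5,
    fdr_max: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Call differentially expressed probes for one cell line.

    The fold change is ``2**(mean(differentiated) - mean(undifferentiated))``
    (intensities are log2).  Significance is a two-sided permutation test of
    the Welch t statistic over condition labels — exhaustive when the number
    of distinct label splits is at most ``n_perm``, otherwise ``n_perm``
    random splits — with Benjamini-Hochberg adjustment over all probes.
    """
    und = matrix.samples_in(UNDIFF)
    dif = matrix.samples_in(DIFF)
    if len(und) < 2 or len(dif) < 2:
        raise ValueError("need at least two samples per condition")
    x = matrix.data[und + dif].to_numpy(dtype=float)
    n1, n2 = len(und), len(dif)
    n = n1 + n2

    sum_all = x.sum(axis=1)
    sumsq_all = (x**2).sum(axis=1)

    def group_t(mask: np.ndarray) -> np.ndarray:
        # mask selects the 'differentiated-like' group of size n2
        s2 = x[:, mask].sum(axis=1)
        q2 = (x[:, mask] ** 2).sum(axis=1)
        return _welch_t(sum_all - s2, sumsq_all - q2, n1, s2, q2, n2)

    obs_mask = np.zeros(n, dtype=bool)
    obs_mask[n1:] = True
    t_obs = group_t(obs_mask)
    mean_diff = x[:, n1:].mean(axis=1) - x[:, :n1].mean(axis=1)
    fold = np.power(2.0, mean_diff)

    degenerate = ~np.isfinite(t_obs)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} probe(s) with zero variance in both "
            "groups; permutation p set to 1",
            stacklevel=2,
        )

    n_distinct = comb(n, n2)
    abs_obs = np.abs(np.where(degenerate, 0.0, t_obs))
    exceed = np.zeros(x.shape[0])
    if n_distinct <= n_perm:
        masks = np.zeros((n_distinct, n), dtype=bool)
        for i, idx in enumerate(combinations(range(n), n2)):
            masks[i, list(idx)] = True
        total = n_distinct
        for mask in masks:
            t_p = group_t(mask)
            t_p = np.where(np.isfinite(t_p), np.abs(t_p), 0.0)
            exceed += t_p >= abs_obs - 1e-12
        p = exceed / total
    else:
        rng = np.random.default_rng(seed)
        # batched permutations via indicator matmul
        perm_ind = np.zeros((n, n_perm))
        for j in range(n_perm):
            perm_ind[rng.choice(n, size=n2, replace=False), j] = 1.0
        s2 = x @ perm_ind
        q2 = (x**2) @ perm_ind
        t_p = _welch_t(
            sum_all[:, None] - s2, sumsq_all[:, None] - q2, n1, s2, q2, n2
        )
        t_p = np.where(np.isfinite(t_p), np.abs(t_p), 0.0)
        exceed = (t_p >= abs_obs[:, None] - 1e-12).sum(axis=1)
        p = (1.0 + exceed) / (n_perm + 1.0)
    p = np.where(degenerate, 1.0, p)

    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    flagged = ((fold > fc_hi) | (fold < fc_lo)) & (fdr < fdr_max)
    direction = np.where(fold >= 1.0, "up", "down")

    return pd.DataFrame(
        {
            "probe": matrix.probe_ids,
            "gene": matrix.probe_ids,
            "fold_change": fold,
            "t_stat": np.where(degenerate, np.nan, t_obs),
            "p": p,
            "fdr": fdr,
            "is_deg": flagged,
            "direction": direction,
        },
        columns=DEG_COLUMNS,
    )


def collapse_probes(
    records: pd.DataFrame, mapping: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse probe-level records to genes, keeping the probe with the
    largest absolute t statistic per gene; unmapped probes are dropped."""
    unmapped = [p for p in records["probe"] if p not in mapping]
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} unmapped probe(s) dropped during collapse",
            stacklevel=2,
        )
    kept = records[records["probe"].isin(mapping)].copy()
    kept["gene"] = kept["probe"].map(dict(mapping))
    kept["_abs_t"] = kept["t_stat"].abs().fillna(-np.inf)
    kept = (
        kept.sort_values(["_abs_t", "probe"], ascending=[False, True])
        .drop_duplicates("gene", keep="first")
        .drop(columns="_abs_t")
        .sort_values("gene")
        .reset_index(drop=True)
    )
    return kept


def intersect_signatures(
    per_line: Sequence[pd.DataFrame | Mapping[str, str]],
) -> SignatureSet:
    """Intersect per-cell-line DEG gene sets into the signature.

    Accepts either gene-level DEG record frames (rows with ``is_deg``)
    or plain ``gene -> direction`` mappings.  Genes present in every
    line but with conflicting directions are excluded and listed in
    ``conflicts``.
    """
    if len(per_line) < 2:
        raise ValueError("need at least two cell lines to intersect")
    maps: list[dict[str, str]] = []
    for entry in per_line:
        if isinstance(entry, pd.DataFrame):
            sub = entry[entry["is_deg"]]
            maps.append(dict(zip(sub["gene"], sub["direction"])))
        else:
            maps.append(dict(entry))
    common = set(maps[0])
    for m in maps[1:]:
        common &= set(m)
    direction: dict[str, str] = {}
    conflicts: list[str] = []
    for gene in sorted(common):
        dirs = {m[gene] for m in maps}
        if len(dirs) == 1:
            direction[gene] = dirs.pop()
        else:
            conflicts.append(gene)
    return SignatureSet(direction=direction, conflicts=conflicts, provenance=maps)
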