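"""Relative expression from qPCR Ct values by the 2^(-ddCt) method.

For a target gene, a reference gene (e.g. ACT1), a test condition and a
control condition:

    dCt(sample)  = mean Ct(target, sample) - mean Ct(reference, sample)
    ddCt         = dCt(test) - dCt(control)
    fold change  = 2^(-ddCt),   log2 fold = -ddCt

Replicate Ct values are averaged before differencing (the standard Livak
formulation); the SEM of ddCt is propagated from the four group-mean
standard errors by the delta method, which is exact on the log2 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RelativeExpression",
    "load_ct_table",
    "delta_delta_ct",
    "expression_report",
]

_REQUIRED_COLS = ("sample", "gene", "replicate", "ct")


def load_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format Ct TSV with columns sample, gene, replicate, ct."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table missing column(s): {', '.join(missing)}")
    df["ct"] = df["ct"].astype(float)
    if (df["ct"] <= 0).any():
        raise ValueError("Ct values must be > 0")
    return df


@dataclass
class RelativeExpression:
    """2^(-ddCt) result for one gene and one (test, control) condition pair.

    ``sem`` is the delta-method SEM of ``log2_fold`` (= the SEM of ddCt);
    ``sem_fold`` translates it to the fold-change scale as fold * ln2 * sem.
    """

    gene: str
    condition_pair: tuple[str, str]
    delta_delta_ct: float
    fold_change: float
    log2_fold: float
    sem: float

    @property
    def sem_fold(self) -> float:
        return self.fold_change * math.log(2.0) * self.sem


def _group_ct(table: pd.DataFrame, sample: str, gene: str) -> pd.Series:
    sub = table[(table["sample"] == sample) & (table["gene"] == gene)]["ct"]
    if len(sub) == 0:
        raise ValueError(f"no Ct replicates for gene {gene!r} in sample {sample!r}")
    return sub


def delta_delta_ct(
    table: pd.DataFrame,
    gene: str,
    reference_gene: str,
    test: str,
    control: str,
) -> RelativeExpression:
    """Compute relative expression of ``gene`` in ``test`` vs ``control``.

    Requires replicate Ct values for both the target and the reference gene
    in both samples; a missing reference group is an error, never silently
    substituted.  SEM of ddCt is sqrt of the summed squared standard errors
    of the four group means (zero for single-replicate groups).
    """
    groups = {
        (s, g): _group_ct(table, s, g)
        for s in (test, control)
        for g in (gene, reference_gene)
    }
    d_test = groups[(test, gene)].mean() - groups[(test, reference_gene)].mean()
    d_ctrl = groups[(control, gene)].mean() - groups[(control, reference_gene)].mean()
    ddct = float(d_test - d_ctrl)
    sem_sq = sum(
        (g.std(ddof=1) / math.sqrt(len(g))) ** 2 if len(g) > 1 else 0.0
        for g in groups.values()
    )
    return RelativeExpression(
        gene=gene,
        condition_pair=(test, control),
        delta_delta_ct=ddct,
        fold_change=float(2.0 ** (-ddct)),
        log2_fold=-ddct,
        sem=float(math.sqrt(sem_sq)),
    )


def expression_report(
    table: pd.DataFrame,
    genes: list[str],
    reference_gene: str,
    test: str,
    control: str,
) -> pd.DataFrame:
    """Tabulate 2^(-ddCt) results for several genes, with a t-test column.

    The p-value column is a Welch t-test comparing per-replicate dCt values
    (replicate Ct minus the sample's mean reference Ct) between test and
    control — a standard report column, NaN when either side has fewer than
    two replicates.
    """
    rows = []
    for gene in genes:
        res = delta_delta_ct(table, gene, reference_gene, test, control)
        p = np.nan
        dct = {}
        for s in (test, control):
            ref_mean = _group_ct(table, s, reference_gene).mean()
            dct[s] = (_group_ct(table, s, gene) - ref_mean).to_numpy()
        if len(dct[test]) > 1 and len(dct[control]) > 1:
            p = float(stats.ttest_ind(dct[test], dct[control], equal_var=False).pvalue)
        rows.append(
            {
                "gene": gene,
                "test": test,
                "control": control,
                "delta_delta_ct": res.delta_delta_ct,
                "fold_change": res.fold_change,
                "log2_fold": res.log2_fold,
                "sem": res.sem,
                "p_ttest": p,
            }
        )
    return pd.DataFrame(rows)
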