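"""Per-gene expression comparison and ddCt relative quantification.

Off-target assessment: for each candidate gene from the off-target screen,
group FPKM values are compared with a two-sided Welch (unequal-variance)
unpaired t-test, gene by gene ("multiple unpaired t-tests"). Genes with
zero FPKM in every sample of both groups are flagged undetected and not
tested. Raw p-values drive the significance call at alpha = 0.05;
Benjamini–Hochberg adjusted p-values are reported alongside.

RT-qPCR: relative expression by the ddCt method with amplification
efficiency fixed at 2 (perfect doubling):

    dCt   = Ct_target - Ct_reference          (per sample)
    ddCt  = dCt - mean(dCt over control samples)
    rel   = 2 ** (-ddCt)

so the control group has geometric-mean relative expression 1 by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

ALPHA = 0.05

CONDITIONS = ("treated", "control")


class StatsError(ValueError):
    """Invalid expression or Ct input."""


@dataclass(frozen=True)
class GeneTestResult:
    """One candidate gene's Welch-test outcome.

    ``detected`` is False iff the gene is zero in every sample of both
    groups (then no test is run). ``note`` is "degenerate" when both
    groups have zero variance and equal means, leaving the t statistic
    undefined; such genes are skipped and excluded from the adjustment
    family.
    """

    gene: str
    mean_a: float
    mean_b: float
    t_stat: float | None
    df: float | None
    p_raw: float | None
    p_adj: float | None
    detected: bool
    significant: bool | None = None
    note: str = ""


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch t, Satterthwaite df, two-sided p."""
    t, p = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    df = (va + vb) ** 2 / (
        va**2 / (len(a) - 1) + vb**2 / (len(b) - 1)
    )
    return float(t), float(df), float(p)


def compare_candidate_genes(
    expr: pd.DataFrame,
    groups: Mapping[str, str],
    group_a: str,
    group_b: str,
    gene_list: Sequence[str],
) -> list[GeneTestResult]:
    """Welch-test each candidate gene between two sample groups.

    Parameters
    ----------
    expr
        Gene x sample FPKM matrix (genes as index, samples as columns);
        nonnegative, no missing cells.
    groups
        Sample id -> group label; each compared group needs >= 2 samples.
    gene_list
        Candidate genes (e.g. off-target hits); must all be in ``expr``.
    """
    if expr.isna().any().any():
        raise StatsError("expression table contains missing cells")
    if (expr.to_numpy() < 0).any():
        raise StatsError("expression values must be nonnegative")
    missing = [g for g in gene_list if g not in expr.index]
    if missing:
        raise StatsError(f"gene(s) absent from expression table: {missing}")
    samples_a = [s for s, g in groups.items() if g == group_a and s in expr.columns]
    samples_b = [s for s, g in groups.items() if g == group_b and s in expr.columns]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise StatsError(
            f"each group needs >= 2 samples "
            f"({group_a}: {len(samples_a)}, {group_b}: {len(samples_b)})"
        )

    results: list[GeneTestResult] = []
    for gene in gene_list:
        a = expr.loc[gene, samples_a].to_numpy(dtype=float)
        b = expr.loc[gene, samples_b].to_numpy(dtype=float)
        if (a == 0).all() and (b == 0).all():
            results.append(
                GeneTestResult(
                    gene=gene,
                    mean_a=0.0,
                    mean_b=0.0,
                    t_stat=None,
                    df=None,
                    p_raw=None,
                    p_adj=None,
                    detected=False,
                    note="not detected",
                )
            )
            continue
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
            results.append(
                GeneTestResult(
                    gene=gene,
                    mean_a=float(a.mean()),
                    mean_b=float(b.mean()),
                    t_stat=None,
                    df=None,
                    p_raw=None,
                    p_adj=None,
                    detected=True,
                    note="degenerate",
                )
            )
            continue
        t, df, p = _welch(a, b)
        results.append(
            GeneTestResult(
                gene=gene,
                mean_a=float(a.mean()),
                mean_b=float(b.mean()),
                t_stat=t,
                df=df,
                p_raw=p,
                p_adj=None,
                detected=True,
                significant=bool(p < ALPHA),
            )
        )

    tested = [i for i, r in enumerate(results) if r.p_raw is not None]
    if tested:
        p_adj = multipletests(
            [results[i].p_raw for i in tested], method="fdr_bh"
        )[1]
        for i, padj in zip(tested, p_adj):
            r = results[i]
            results[i] = GeneTestResult(
                gene=r.gene,
                mean_a=r.mean_a,
                mean_b=r.mean_b,
                t_stat=r.t_stat,
                df=r.df,
                p_raw=r.p_raw,
                p_adj=float(padj),
                detected=r.detected,
                significant=r.significant,
                note=r.note,
            )
    return results


def results_to_frame(results: Sequence[GeneTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "mean_a": r.mean_a,
                "mean_b": r.mean_b,
                "t_stat": np.nan if r.t_stat is None else r.t_stat,
                "df": np.nan if r.df is None else r.df,
                "p_raw": np.nan if r.p_raw is None else r.p_raw,
                "p_adj": np.nan if r.p_adj is None else r.p_adj,
                "detected": r.detected,
                "significant": r.significant,
                "note": r.note,
            }
            for r in results
        ]
    )


def validate_ct_table(ct: pd.DataFrame) -> pd.DataFrame:
    """Check a Ct table: sample, condition, ct_target, ct_reference."""
    required = {"sample", "condition", "ct_target", "ct_reference"}
    missing = required - set(ct.columns)
    if missing:
        raise StatsError(f"Ct table missing column(s): {sorted(missing)}")
    bad = set(ct["condition"]) - set(CONDITIONS)
    if bad:
        raise StatsError(f"unknown condition label(s): {sorted(bad)}")
    for col in ("ct_target", "ct_reference"):
        vals = ct[col]
        if vals.isna().any():
            sample = ct.loc[vals.isna(), "sample"].iloc[0]
            raise StatsError(f"missing {col} for sample {sample!r}")
        if not np.isfinite(vals).all() or (vals <= 0).any():
            sample = ct.loc[~np.isfinite(vals) | (vals <= 0), "sample"].iloc[0]
            raise StatsError(f"non-finite or non-positive {col} for sample {sample!r}")
    if not (ct["condition"] == "control").any():
        raise StatsError("Ct table has no control samples")
    return ct


def ddct(ct: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ddCt relative expression per sample, plus a per-condition summary.

    Returns
    -------
    per_sample
        Input rows with ``dct``, ``ddct`` and ``rel_expr`` columns added.
    summary
        Per condition: arithmetic mean, sample SD, n, and geometric mean
        of ``rel_expr`` (the control geometric mean is exactly 1).
    """
    ct = validate_ct_table(ct).copy()
    ct["dct"] = ct["ct_target"] - ct["ct_reference"]
    control_mean_dct = ct.loc[ct["condition"] == "control", "dct"].mean()
    ct["ddct"] = ct["dct"] - control_mean_dct
    ct["rel_expr"] = 2.0 ** (-ct["ddct"])
    summary = (
        ct.groupby("condition")["rel_expr"]
        .agg(
            mean="mean",
            sd=lambda v: v.std(ddof=1) if len(v) > 1 else np.nan,
            n="size",
            geometric_mean=lambda v: float(np.exp(np.log(v).mean())),
        )
        .reset_index()
    )
    return ct, summary
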