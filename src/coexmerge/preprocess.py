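"""Normalization, multi-study merging and differential-expression calling.

Expression enters the pipeline as gene-level log2 matrices (genes x samples),
one per study, each with binary case/control labels.  Studies are made
comparable by per-gene, per-study z-score normalization, then concatenated
into one matrix.  Differentially expressed (DE) genes are called with a
moderated two-sample t-test (empirical-Bayes variance shrinkage) combined
with a fold-change threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"


@dataclass
class ExpressionStudy:
    """One study's log2 expression matrix plus per-sample condition labels.

    Parameters
    ----------
    study_id : str
        Identifier of the study (used to tag merged sample ids).
    expr : pandas.DataFrame
        Genes x samples matrix of log2 expression values.  The index holds
        unique gene ids, the columns unique sample ids.
    condition : pandas.Series
        Per-sample label, ``"case"`` or ``"control"``, indexed by sample id.
    """

    study_id: str
    expr: pd.DataFrame
    condition: pd.Series

    def __post_init__(self) -> None:
        if self.expr.index.has_duplicates:
            raise ValueError("duplicate gene ids in study %r" % self.study_id)
        if self.expr.columns.has_duplicates:
            raise ValueError("duplicate sample ids in study %r" % self.study_id)
        self.condition = self.condition.reindex(self.expr.columns)
        if self.condition.isna().any():
            raise ValueError("missing condition label for some samples")
        labels = set(self.condition.unique())
        if not labels <= {CASE, CONTROL}:
            raise ValueError(f"labels must be 'case'/'control', got {labels}")
        if labels != {CASE, CONTROL}:
            raise ValueError("both conditions must be present in each study")
        if self.expr.isna().any().any():
            raise ValueError("missing expression values are not supported")

    @property
    def gene_ids(self) -> pd.Index:
        return self.expr.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.expr.columns

    def n_samples(self, label: str) -> int:
        return int((self.condition == label).sum())


@dataclass
class MergedExpression:
    """Concatenation of z-score-normalized studies.

    ``expr`` holds the z-scored values used for correlation work: per gene,
    per study the values have mean 0 and sd 1, so study-level batch offsets
    cancel.  ``fc_expr`` holds a parallel matrix that is only *centered* per
    gene per study (batch removed, log2 scale preserved); fold changes are
    computed from it because z-scores destroy fold-change units.
    """

    expr: pd.DataFrame
    fc_expr: pd.DataFrame
    condition: pd.Series
    study: pd.Series

    @property
    def gene_ids(self) -> pd.Index:
        return self.expr.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.expr.columns

    def samples_of(self, label: str) -> pd.Index:
        return self.expr.columns[(self.condition == label).to_numpy()]


def quantile_normalize(values):
    """Force every column to share the distribution of averaged order statistics.

    Each column is mapped onto the vector of row means of the column-wise
    order statistics, preserving within-column rank order.  Ties receive the
    average of the tied quantile means.

    Parameters
    ----------
    values : numpy.ndarray or pandas.DataFrame
        Matrix with observations in rows, arrays/samples in columns.  No
        missing values.

    Returns
    -------
    Same type as the input, quantile normalized.
    """
    df_in = isinstance(values, pd.DataFrame)
    mat = np.asarray(values.to_numpy() if df_in else values, dtype=float)
    if mat.ndim != 2 or mat.size == 0:
        raise ValueError("expected a non-empty 2-D matrix")
    if np.isnan(mat).any():
        raise ValueError("missing values are not supported")
    n = mat.shape[0]
    reference = np.sort(mat, axis=0).mean(axis=1)
    out = np.empty_like(mat)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(mat.shape[1]):
        ranks = stats.rankdata(mat[:, j], method="average")
        # average ranks land between order statistics; interpolate the
        # reference so tied values get the mean of the tied quantile means
        out[:, j] = np.interp(ranks, grid, reference)
    if df_in:
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def zscore_merge(studies: list[ExpressionStudy]) -> MergedExpression:
    """Merge studies into one matrix via per-gene, per-study z-scores.

    For gene i in study k, ``Y = (X - mean_ik) / sd_ik`` with the sample
    (n-1) standard deviation.  The gene universe is the intersection of the
    studies' gene sets; genes with zero variance in any study are dropped
    with a warning.  Sample ids are prefixed with the study id to stay
    unique after concatenation.
    """
    if not studies:
        raise ValueError("need at least one study")
    genes = studies[0].gene_ids
    for s in studies[1:]:
        genes = genes.intersection(s.gene_ids, sort=False)
    if len(genes) == 0:
        raise ValueError("studies share no genes")

    # genes with zero within-study variance cannot be z-scored
    bad: set[str] = set()
    for s in studies:
        sd = s.expr.loc[genes].std(axis=1, ddof=1)
        bad |= set(sd.index[(sd == 0) | sd.isna()])
    if bad:
        warnings.warn(
            f"dropping {len(bad)} gene(s) with zero variance in some study",
            stacklevel=2,
        )
        genes = genes[~genes.isin(bad)]
    if len(genes) == 0:
        raise ValueError("no genes left after zero-variance filtering")

    z_blocks, fc_blocks, cond_parts, study_parts = [], [], [], []
    for s in studies:
        block = s.expr.loc[genes]
        mean = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        z = block.sub(mean, axis=0).div(sd, axis=0)
        fc = block.sub(mean, axis=0)
        new_cols = [f"{s.study_id}:{c}" for c in block.columns]
        z.columns = fc.columns = new_cols
        z_blocks.append(z)
        fc_blocks.append(fc)
        cond_parts.append(pd.Series(s.condition.to_numpy(), index=new_cols))
        study_parts.append(pd.Series(s.study_id, index=new_cols))

    return MergedExpression(
        expr=pd.concat(z_blocks, axis=1),
        fc_expr=pd.concat(fc_blocks, axis=1),
        condition=pd.concat(cond_parts),
        study=pd.concat(study_parts),
    )


def _trigamma_inverse(target: float) -> float:
    """Solve trigamma(x) = target for x > 0."""
    if target <= 0:
        return np.inf
    return float(
        optimize.brentq(lambda x: special.polygamma(1, x) - target, 1e-8, 1e8)
    )


def _squeeze_variances(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching estimate of the variance prior (d0, s0^2).

    Fits a scaled inverse chi-square prior to the per-gene sample variances
    by matching the mean and variance of log(s^2), using the known digamma/
    trigamma moments of log chi-square variables.  Returns the prior degrees
    of freedom d0 (may be inf) and prior scale s0^2.
    """
    s2 = np.maximum(np.asarray(s2, dtype=float), 1e-12)
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) if e.size > 1 else 0.0
    resid = e_var - float(special.polygamma(1, df / 2.0))
    if resid <= 0:
        return np.inf, float(np.exp(e_mean))
    half_d0 = _trigamma_inverse(resid)
    d0 = 2.0 * half_d0
    s0_2 = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s0_2


def detect_de(
    merged: MergedExpression,
    p_thresh: float = 0.05,
    fc_thresh: float = 2.0,
    use_moderated: bool = True,
) -> pd.DataFrame:
    """Call DE genes between cases and controls on the merged matrix.

    The t-statistic is computed on the z-scored values (batch-free scale);
    log2 fold change is the case-minus-control mean difference on the
    study-centered matrix, which keeps log2 units.  With ``use_moderated``
    the pooled within-group variances are shrunk toward a common prior
    estimated by moment matching on the log variances, and the t reference
    distribution gains the prior degrees of freedom; otherwise a plain
    Welch t-test is used.

    Returns a DataFrame indexed by gene with columns ``log2fc``, ``t``,
    ``p``, ``padj`` (Benjamini-Hochberg) and ``is_de`` where
    ``is_de = (p < p_thresh) & (|log2fc| > fc_thresh)``.
    """
    case_cols = merged.samples_of(CASE)
    ctrl_cols = merged.samples_of(CONTROL)
    n1, n2 = len(case_cols), len(ctrl_cols)
    if n1 < 2 or n2 < 2:
        raise ValueError("each condition needs at least 2 samples")

    z = merged.expr
    zc = z[case_cols].to_numpy()
    zn = z[ctrl_cols].to_numpy()
    log2fc = (
        merged.fc_expr[case_cols].mean(axis=1)
        - merged.fc_expr[ctrl_cols].mean(axis=1)
    )

    diff = zc.mean(axis=1) - zn.mean(axis=1)
    if use_moderated:
        df_resid = n1 + n2 - 2
        pooled = (zc.var(axis=1, ddof=1) * (n1 - 1) + zn.var(axis=1, ddof=1) * (n2 - 1)) / df_resid
        d0, s0_2 = _squeeze_variances(pooled, df_resid)
        if np.isinf(d0):
            s2_post = np.full_like(pooled, s0_2)
            df_total = 1e6
        else:
            s2_post = (d0 * s0_2 + df_resid * pooled) / (d0 + df_resid)
            df_total = min(d0 + df_resid, 1e6)
        t = diff / np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    else:
        res = stats.ttest_ind(zc, zn, axis=1, equal_var=False)
        t, p = res.statistic, res.pvalue

    padj = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "log2fc": log2fc.to_numpy(),
            "t": t,
            "p": p,
            "padj": padj,
        },
        index=z.index,
    )
    table["is_de"] = (table["p"] < p_thresh) & (table["log2fc"].abs() > fc_thresh)
    return table


def read_study_tsv(expr_path, labels_path, study_id: str | None = None) -> list[ExpressionStudy]:
    """Read studies from a study-expression TSV and a labels TSV.

    The labels file has columns ``sample``, ``condition``, ``study``; the
    expression file holds one study's genes x samples matrix.  Returns one
    ``ExpressionStudy`` per study id present in both files (or only
    ``study_id`` if given).
    """
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    labels = pd.read_csv(labels_path, sep="\t", dtype=str)
    labels = labels.set_index("sample")
    out = []
    ids = [study_id] if study_id else list(dict.fromkeys(labels["study"]))
    for sid in ids:
        samples = labels.index[labels["study"] == sid]
        cols = [c for c in expr.columns if c in set(samples)]
        if not cols:
            continue
        out.append(
            ExpressionStudy(
                study_id=sid,
                expr=expr[cols],
                condition=labels.loc[cols, "condition"],
            )
        )
    if not out:
        raise ValueError("no study samples matched the expression columns")
    return out


def write_de_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="gene")
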