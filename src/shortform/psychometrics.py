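"""Long-form vs short-form validation statistics.

Everything a reviewer expects when a short form is proposed: Cronbach's
alpha and average inter-item correlation per subscale, subscale
intercorrelation matrices for both forms, the long x short
cross-correlation matrix whose diagonal carries the convergent
correlations, zero-order criterion correlation tables, group means, and
mean-absolute-difference (MAD) summaries that condense the agreement
between two correlation or mean tables into a single number.

Correlations are pairwise-complete by default: under a planned-missing
design listwise deletion would discard nearly every respondent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from shortform.scale_model import ScaleSpec, apply_keying, score_subscales

__all__ = [
    "cronbach_alpha",
    "average_inter_item_correlation",
    "correlation_table",
    "matrix_mad",
    "convergent_diagonal",
    "group_means",
    "split_train_test",
    "ComparisonReport",
    "compare_forms",
]


def cronbach_alpha(item_matrix: pd.DataFrame, pairwise: bool = False) -> float:
    """Internal-consistency reliability of one subscale's keyed items.

        alpha = k/(k-1) * (1 - sum(item variances) / var(total score))

    With ``pairwise=True`` the item covariance matrix is estimated from
    pairwise-complete observations and the total-score variance taken as
    the sum of all its entries; the default uses complete rows only.
    """
    if item_matrix.shape[1] < 2:
        raise ValueError("alpha needs at least 2 items")
    if pairwise:
        cov = item_matrix.cov()
    else:
        complete = item_matrix.dropna()
        if len(complete) < 3:
            raise ValueError(
                f"only {len(complete)} complete rows; use pairwise=True "
                "or provide more data"
            )
        cov = complete.cov()
    k = item_matrix.shape[1]
    total_var = float(cov.to_numpy().sum())
    if total_var <= 0:
        raise ValueError("total score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - np.trace(cov.to_numpy()) / total_var))


def average_inter_item_correlation(item_matrix: pd.DataFrame) -> float:
    """Mean Pearson correlation over distinct item pairs (pairwise-complete)."""
    if item_matrix.shape[1] < 2:
        raise ValueError("need at least 2 items")
    constant = [c for c in item_matrix.columns if item_matrix[c].nunique(dropna=True) <= 1]
    if constant:
        warnings.warn(f"constant items excluded from inter-item correlation: {constant}")
        item_matrix = item_matrix.drop(columns=constant)
        if item_matrix.shape[1] < 2:
            raise ValueError("fewer than 2 non-constant items")
    corr = item_matrix.corr().to_numpy()
    iu = np.triu_indices_from(corr, k=1)
    return float(np.nanmean(corr[iu]))


def correlation_table(
    scores_a: pd.DataFrame,
    scores_b: pd.DataFrame,
    pairwise: bool = True,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Pearson correlations between the columns of two score tables.

    Rows are the columns of ``scores_a``, columns those of ``scores_b``.
    Cells with fewer than ``min_pairs`` jointly observed respondents are
    set to NaN with a warning.
    """
    a, b = scores_a.align(scores_b, join="inner", axis=0)
    if not pairwise:
        complete = pd.concat([a, b], axis=1).dropna().index
        a, b = a.loc[complete], b.loc[complete]
    out = pd.DataFrame(index=a.columns, columns=b.columns, dtype=float)
    for ca in a.columns:
        for cb in b.columns:
            x, y = a[ca], b[cb]
            ok = x.notna() & y.notna()
            if ok.sum() < min_pairs:
                warnings.warn(
                    f"correlation {ca!r} x {cb!r}: only {int(ok.sum())} complete "
                    f"pairs (< {min_pairs}); cell set to NaN"
                )
                out.loc[ca, cb] = np.nan
            else:
                out.loc[ca, cb] = float(np.corrcoef(x[ok], y[ok])[0, 1])
    return out


def matrix_mad(
    A: pd.DataFrame | np.ndarray,
    B: pd.DataFrame | np.ndarray,
    cells: str = "all",
) -> tuple[float, int]:
    """Mean absolute difference between two tables, with the cell count.

    ``cells`` selects which entries are compared:

    - ``"all"``: every cell of A against the same cell of B;
    - ``"offdiagonal"``: the distinct off-diagonal pairs (strict lower
      triangle) of two square tables — the natural choice for symmetric
      correlation matrices, where each pair should count once;
    - ``"lower_vs_upper"``: A's strict lower triangle against B's strict
      upper triangle transposed, for the common compact presentation
      that prints one form below and the other above the diagonal of a
      single square table (pass the same table twice).

    Rounding is left to the caller; full precision is returned.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    if cells == "all":
        diffs = np.abs(A - B).ravel()
    elif cells in ("offdiagonal", "lower_vs_upper"):
        if A.shape[0] != A.shape[1]:
            raise ValueError(f"cells={cells!r} requires square tables")
        il = np.tril_indices(A.shape[0], k=-1)
        other = B[il] if cells == "offdiagonal" else B.T[il]
        diffs = np.abs(A[il] - other)
    else:
        raise ValueError(f"unknown cell selection {cells!r}")
    diffs = diffs[~np.isnan(diffs)]
    return float(diffs.mean()), int(diffs.size)


def convergent_diagonal(
    long_scores: pd.DataFrame, short_scores: pd.DataFrame
) -> pd.Series:
    """Correlation of each subscale's long-form score with its short-form
    score — the diagonal of the long x short cross-correlation matrix."""
    if list(long_scores.columns) != list(short_scores.columns):
        raise ValueError("long and short score tables must share the subscale set")
    table = correlation_table(long_scores, short_scores)
    return pd.Series(np.diag(table), index=long_scores.columns)


def group_means(scores: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-group mean and SD of every subscale score.

    Returns a table indexed by group with a (subscale, mean|sd) column
    hierarchy plus a group size column.
    """
    groups = groups.reindex(scores.index)
    if groups.isna().any():
        missing = scores.index[groups.isna()][:5].tolist()
        raise ValueError(f"unlabeled respondents, e.g. {missing}")
    out = {}
    for g, block in scores.groupby(groups):
        if block.dropna(how="all").empty:
            warnings.warn(f"group {g!r} has no scored respondents")
        row = {("n", ""): len(block)}
        for col in scores.columns:
            row[(col, "mean")] = float(block[col].mean())
            row[(col, "sd")] = float(block[col].std(ddof=1))
        out[g] = row
    return pd.DataFrame(out).T


def split_train_test(n: int, fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint train/test index partition.

    The training set holds ``round(fraction * n)`` indices; the two sets
    are disjoint and exhaustive, and reproducible from ``seed``.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(fraction * n))
    train = np.sort(perm[:n_train])
    test = np.sort(perm[n_train:])
    return train, test


@dataclass
class ComparisonReport:
    """Bundle of long-vs-short validation statistics."""

    long_alpha: pd.Series
    short_alpha: pd.Series
    long_aiic: pd.Series
    short_aiic: pd.Series
    long_intercorr: pd.DataFrame
    short_intercorr: pd.DataFrame
    cross_corr: pd.DataFrame
    convergent: pd.Series
    mad_intercorr: tuple  # (value, n_cells)
    criterion_long: pd.DataFrame | None = None
    criterion_short: pd.DataFrame | None = None
    mad_criterion: tuple | None = None
    group_means_long: pd.DataFrame | None = None
    group_means_short: pd.DataFrame | None = None

    def summary(self) -> dict:
        out = {
            "alpha_long": {k: round(float(v), 2) for k, v in self.long_alpha.items()},
            "alpha_short": {k: round(float(v), 2) for k, v in self.short_alpha.items()},
            "avg_inter_item_r_long": {k: round(float(v), 2) for k, v in self.long_aiic.items()},
            "avg_inter_item_r_short": {k: round(float(v), 2) for k, v in self.short_aiic.items()},
            "convergent_r": {k: round(float(v), 3) for k, v in self.convergent.items()},
            "mad_intercorrelations": round(self.mad_intercorr[0], 2),
            "mad_intercorrelations_cells": self.mad_intercorr[1],
        }
        if self.mad_criterion is not None:
            out["mad_criterion_correlations"] = round(self.mad_criterion[0], 2)
            out["mad_criterion_cells"] = self.mad_criterion[1]
        return out


def compare_forms(
    responses: pd.DataFrame,
    spec: ScaleSpec,
    short_mask: np.ndarray,
    criteria: pd.DataFrame | None = None,
    groups: pd.Series | None = None,
    pairwise_alpha: bool = False,
) -> ComparisonReport:
    """Full validation of a short form against the long form.

    Scores both forms on the same data (keyed means), then computes
    reliability, intercorrelations, the convergent diagonal and MAD
    summaries; criterion correlations and group means when supplied.
    """
    keyed = apply_keying(responses, spec)
    long_scores = score_subscales(responses, spec)
    short_scores = score_subscales(responses, spec, mask=short_mask)

    long_alpha, short_alpha, long_aiic, short_aiic = {}, {}, {}, {}
    for sub in spec.subscales:
        all_ids = spec.items_in_subscale(sub)
        idx = spec.subscale_indices(sub)
        short_ids = [i for i, j in zip(all_ids, idx) if short_mask[j]]
        if len(all_ids) >= 2:
            long_alpha[sub] = cronbach_alpha(keyed[all_ids], pairwise=pairwise_alpha)
            long_aiic[sub] = average_inter_item_correlation(keyed[all_ids])
        else:
            long_alpha[sub] = np.nan
            long_aiic[sub] = np.nan
        if len(short_ids) >= 2:
            short_alpha[sub] = cronbach_alpha(keyed[short_ids], pairwise=pairwise_alpha)
            short_aiic[sub] = average_inter_item_correlation(keyed[short_ids])
        else:
            short_alpha[sub] = np.nan
            short_aiic[sub] = np.nan

    long_ic = correlation_table(long_scores, long_scores)
    short_ic = correlation_table(short_scores, short_scores)
    cross = correlation_table(long_scores, short_scores)
    report = ComparisonReport(
        long_alpha=pd.Series(long_alpha),
        short_alpha=pd.Series(short_alpha),
        long_aiic=pd.Series(long_aiic),
        short_aiic=pd.Series(short_aiic),
        long_intercorr=long_ic,
        short_intercorr=short_ic,
        cross_corr=cross,
        convergent=convergent_diagonal(long_scores, short_scores),
        mad_intercorr=matrix_mad(long_ic, short_ic, cells="offdiagonal"),
    )
    if criteria is not None:
        report.criterion_long = correlation_table(criteria, long_scores)
        report.criterion_short = correlation_table(criteria, short_scores)
        report.mad_criterion = matrix_mad(
            report.criterion_long, report.criterion_short, cells="all"
        )
    if groups is not None:
        report.group_means_long = group_means(long_scores, groups)
        report.group_means_short = group_means(short_scores, groups)
    return report
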