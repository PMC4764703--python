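"""Published comparison tables for the 62-item MEAQ vs the MEAQ-30.

Transcriptions of the printed validation tables for the GA-derived
30-item short form of the Multidimensional Experiential Avoidance
Questionnaire: subscale intercorrelations (one form below, the other
above the diagonal of a single table), six-factor correlation blocks
for both forms, zero-order criterion correlations of both forms with
twelve external measures, and subscale means/SDs across the five US
census regions.  These are the inputs for the ``compare-tables``
workflow, which condenses each long/short pair into a mean-absolute-
difference summary.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "subscale_intercorrelations",
    "factor_correlations",
    "criterion_correlations",
    "region_means",
]


def _read(name: str, **kw) -> pd.DataFrame:
    ref = resources.files("shortform").joinpath("data", name)
    with ref.open() as fh:
        return pd.read_csv(fh, index_col=0, **kw)


def subscale_intercorrelations() -> pd.DataFrame:
    """6x6 table: long-form correlations below the diagonal, short-form
    above; the diagonal is empty."""
    return _read("subscale_intercorr.csv")


def factor_correlations() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric 6x6 factor-correlation matrices (long form, short form)."""
    return _read("factor_corr_62.csv"), _read("factor_corr_30.csv")


def criterion_correlations() -> tuple[pd.DataFrame, pd.DataFrame]:
    """12 criteria x 6 subscales zero-order correlation tables
    (long form, short form)."""
    return _read("criterion_corr_62.csv"), _read("criterion_corr_30.csv")


def region_means() -> pd.DataFrame:
    """Long-format region x subscale means and SDs for both forms."""
    ref = resources.files("shortform").joinpath("data", "region_means.csv")
    with ref.open() as fh:
        return pd.read_csv(fh)


def region_mean_matrices() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pivot the region means into two region x subscale matrices."""
    df = region_means()
    long = df.pivot(index="region", columns="subscale", values="mean_62")
    short = df.pivot(index="region", columns="subscale", values="mean_30")
    return long, short[long.columns]
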