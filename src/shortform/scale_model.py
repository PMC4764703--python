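"""Questionnaire structure, reverse keying and subscale scoring.

A :class:`ScaleSpec` describes a fixed multi-subscale instrument: an
ordered list of items, each belonging to exactly one subscale, with an
optional reverse-key flag, plus the shared integer response range (for a
six-point Likert scale, 1..6).  Response matrices are plain pandas
DataFrames (respondents x items, integer or NaN) so that every other
module can work with ordinary tabular tools.

Scoring follows the convention used when long and short forms are
compared on the same response metric: a subscale score is the *mean* of
its keyed, observed items, so a 5-item short subscale and an 11-item
long subscale both live on the original 1..6 scale.  Sum scoring is
available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ItemSpec",
    "ScaleSpec",
    "key_item",
    "apply_keying",
    "score_subscales",
    "load_response_matrix",
    "save_response_matrix",
    "validate_response_matrix",
]


@dataclass(frozen=True)
class ItemSpec:
    """One questionnaire item.

    Parameters
    ----------
    item_id :
        Unique identifier, used as the column name in response matrices.
    subscale_id :
        The single subscale the item belongs to.
    reverse_keyed :
        If True the item is worded against its subscale's direction and
        is recoded as ``min + max - response`` before any analysis.
    text :
        Optional item wording; never used in computation.
    """

    item_id: str
    subscale_id: str
    reverse_keyed: bool = False
    text: str | None = None


@dataclass
class ScaleSpec:
    """Fixed structure of a multi-subscale instrument."""

    items: list[ItemSpec]
    subscales: list[str] = field(default_factory=list)
    response_min: int = 1
    response_max: int = 6

    def __post_init__(self) -> None:
        if not self.subscales:
            seen: list[str] = []
            for it in self.items:
                if it.subscale_id not in seen:
                    seen.append(it.subscale_id)
            self.subscales = seen
        self.validate()

    # -- derived views -------------------------------------------------
    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def n_subscales(self) -> int:
        return len(self.subscales)

    def items_in_subscale(self, subscale_id: str) -> list[str]:
        return [it.item_id for it in self.items if it.subscale_id == subscale_id]

    def subscale_indices(self, subscale_id: str) -> np.ndarray:
        """Positional indices (into the item order) of one subscale's items."""
        return np.array(
            [i for i, it in enumerate(self.items) if it.subscale_id == subscale_id],
            dtype=int,
        )

    @property
    def reverse_flags(self) -> np.ndarray:
        return np.array([it.reverse_keyed for it in self.items], dtype=bool)

    def validate(self) -> None:
        ids = self.item_ids
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate item ids: {dupes}")
        if self.response_min >= self.response_max:
            raise ValueError(
                f"response_min ({self.response_min}) must be < "
                f"response_max ({self.response_max})"
            )
        referenced = {it.subscale_id for it in self.items}
        missing = referenced - set(self.subscales)
        if missing:
            raise ValueError(f"subscales referenced by items but not declared: {sorted(missing)}")
        empty = [s for s in self.subscales if not self.items_in_subscale(s)]
        if empty:
            raise ValueError(f"subscales with no items: {empty}")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "response_range": [self.response_min, self.response_max],
            "subscales": list(self.subscales),
            "items": [
                {
                    "id": it.item_id,
                    "subscale": it.subscale_id,
                    "reverse": bool(it.reverse_keyed),
                    **({"text": it.text} if it.text else {}),
                }
                for it in self.items
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScaleSpec":
        lo, hi = d["response_range"]
        items = [
            ItemSpec(
                item_id=str(e["id"]),
                subscale_id=str(e["subscale"]),
                reverse_keyed=bool(e.get("reverse", False)),
                text=e.get("text"),
            )
            for e in d["items"]
        ]
        return cls(items=items, subscales=list(d.get("subscales", [])),
                   response_min=int(lo), response_max=int(hi))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScaleSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def key_item(value, spec: ScaleSpec, reverse: bool):
    """Reverse-score a single response; missing values pass through.

    Reverse keying reflects the response around the midpoint of the
    scale: ``min + max - value``.  Applying it twice is the identity.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return value
    if not (spec.response_min <= value <= spec.response_max):
        raise ValueError(
            f"response {value!r} outside range "
            f"[{spec.response_min}, {spec.response_max}]"
        )
    if reverse:
        return spec.response_min + spec.response_max - value
    return value


def validate_response_matrix(responses: pd.DataFrame, spec: ScaleSpec) -> None:
    """Check that columns match the scale's items and values are in range."""
    cols = set(responses.columns)
    want = set(spec.item_ids)
    if cols != want:
        extra, missing = sorted(cols - want), sorted(want - cols)
        raise ValueError(
            f"response matrix columns do not match scale items "
            f"(missing={missing[:5]}, unexpected={extra[:5]})"
        )
    vals = responses.to_numpy(dtype=float)
    bad = (vals < spec.response_min) | (vals > spec.response_max)
    bad &= ~np.isnan(vals)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"out-of-range response {vals[r, c]} for item "
            f"{responses.columns[c]!r}, respondent {responses.index[r]!r}"
        )


def apply_keying(responses: pd.DataFrame, spec: ScaleSpec) -> pd.DataFrame:
    """Return a copy with every reverse-keyed column recoded.

    All downstream analyses (regression, alpha, correlations, GA
    fitness) operate on keyed responses.
    """
    keyed = responses[spec.item_ids].astype(float).copy()
    rev = [it.item_id for it in spec.items if it.reverse_keyed]
    if rev:
        keyed[rev] = spec.response_min + spec.response_max - keyed[rev]
    return keyed


def score_subscales(
    responses: pd.DataFrame,
    spec: ScaleSpec,
    mask: np.ndarray | None = None,
    min_coverage: float = 0.5,
    method: str = "mean",
) -> pd.DataFrame:
    """Compute respondents x subscales scores from keyed item responses.

    Parameters
    ----------
    responses :
        Raw response matrix (reverse keying is applied internally).
    mask :
        Optional 0/1 vector over ``spec.items``; only mask-included
        items contribute.  ``None`` means all items.
    min_coverage :
        A respondent's score is set to NaN when fewer than this fraction
        of the subscale's included items were observed — under planned
        missingness a score from one or two answered items is too noisy
        to keep.
    method :
        ``"mean"`` (default; keeps long and short forms on the same
        response metric) or ``"sum"``.

    Returns
    -------
    DataFrame indexed like ``responses`` with one column per subscale.
    """
    if method not in ("mean", "sum"):
        raise ValueError(f"unknown scoring method {method!r}")
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape != (spec.n_items,):
            raise ValueError(
                f"mask length {mask.shape} does not match item count {spec.n_items}"
            )
    validate_response_matrix(responses, spec)
    keyed = apply_keying(responses, spec)
    out = {}
    for sub in spec.subscales:
        ids = spec.items_in_subscale(sub)
        if mask is not None:
            idx = spec.subscale_indices(sub)
            ids = [iid for iid, j in zip(ids, idx) if mask[j]]
        if not ids:
            warnings.warn(f"subscale {sub!r} has no included items; scores set to NaN")
            out[sub] = pd.Series(np.nan, index=keyed.index)
            continue
        block = keyed[ids]
        observed = block.notna().sum(axis=1)
        score = block.mean(axis=1) if method == "mean" else block.sum(axis=1, min_count=1)
        score[observed < min_coverage * len(ids)] = np.nan
        out[sub] = score
    return pd.DataFrame(out, index=keyed.index)[spec.subscales]


def load_response_matrix(path, spec: ScaleSpec | None = None, sep: str = ",") -> pd.DataFrame:
    """Read a delimited response matrix (first column respondent id,
    header item ids, empty cell = missing)."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    df = df.apply(pd.to_numeric).astype(float)
    if spec is not None:
        validate_response_matrix(df, spec)
        df = df[spec.item_ids]
    return df


def save_response_matrix(responses: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a response matrix with missing cells left empty.

    Integer-valued cells are written without a decimal point so that a
    round trip preserves the file byte-for-byte."""
    out = responses.copy()
    # render 4.0 as "4" while keeping NaN as empty
    out = out.astype("Int64", errors="ignore")
    out.to_csv(path, sep=sep)
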