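"""Consensus short form from an ensemble of GA runs.

A single GA run is stochastic, and when the inputs are multiply imputed
copies of a planned-missing response matrix, each imputed dataset yields
a slightly different best mask.  The consensus procedure counts, for
every item, how many runs retained it, ranks items within each subscale
by that selection frequency, and keeps the top *k* per subscale.

Ranking ties at the cut are resolved deterministically: first by higher
mean absolute corrected item-total correlation with the item's own
subscale across the supplied datasets, then by original item order.
Every applied tie-break is recorded in an audit trail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from shortform.ga_engine import GASolution
from shortform.scale_model import ScaleSpec, apply_keying

__all__ = [
    "ItemSelectionTally",
    "ConsensusShortForm",
    "tally_selections",
    "consensus_top_k",
    "corrected_item_total",
]


@dataclass
class ItemSelectionTally:
    """Per-item selection counts over M runs."""

    counts: pd.Series  # item_id -> number of runs retaining it
    n_runs: int

    def to_frame(self, spec: ScaleSpec | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"item_id": self.counts.index, "count": self.counts.values})
        df["n_runs"] = self.n_runs
        if spec is not None:
            sub = {it.item_id: it.subscale_id for it in spec.items}
            df.insert(1, "subscale", df["item_id"].map(sub))
        return df


@dataclass
class ConsensusShortForm:
    """Top-k-per-subscale short form with its selection evidence."""

    mask: np.ndarray
    item_ids: list
    per_subscale: dict  # subscale -> list of (item_id, count) in rank order, retained only
    k: int
    n_runs: int
    audit: list = field(default_factory=list)  # tie-break / shortfall records

    @property
    def retained_items(self) -> list:
        return [iid for iid, m in zip(self.item_ids, self.mask) if m]

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "n_runs": self.n_runs,
            "item_ids": list(self.item_ids),
            "retained_items": self.retained_items,
            "per_subscale": {
                s: [[iid, int(c)] for iid, c in lst] for s, lst in self.per_subscale.items()
            },
            "audit": list(self.audit),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConsensusShortForm":
        item_ids = list(d["item_ids"])
        retained = set(d["retained_items"])
        mask = np.array([1 if i in retained else 0 for i in item_ids], dtype=np.int8)
        return cls(
            mask=mask,
            item_ids=item_ids,
            per_subscale={s: [(i, int(c)) for i, c in lst]
                          for s, lst in d["per_subscale"].items()},
            k=int(d["k"]),
            n_runs=int(d["n_runs"]),
            audit=list(d.get("audit", [])),
        )


def tally_selections(ensemble: list[GASolution]) -> ItemSelectionTally:
    """Count how many runs retained each item.

    All solutions must share the same item universe (same ids, same
    order); an item retained by 19 of 25 runs gets a count of 19.
    """
    if not ensemble:
        raise ValueError("ensemble must contain at least one solution")
    universe = list(ensemble[0].item_ids)
    for sol in ensemble[1:]:
        if list(sol.item_ids) != universe:
            raise ValueError("solutions in the ensemble have mismatched item universes")
    counts = np.zeros(len(universe), dtype=int)
    for sol in ensemble:
        counts += np.asarray(sol.mask, dtype=int)
    return ItemSelectionTally(
        counts=pd.Series(counts, index=universe), n_runs=len(ensemble)
    )


def corrected_item_total(
    responses: pd.DataFrame, spec: ScaleSpec, item_id: str
) -> float:
    """Pearson r between a keyed item and the keyed mean of the OTHER
    items of its subscale (pairwise-complete)."""
    sub = next(it.subscale_id for it in spec.items if it.item_id == item_id)
    others = [i for i in spec.items_in_subscale(sub) if i != item_id]
    if not others:
        return np.nan
    keyed = apply_keying(responses, spec)
    rest = keyed[others].mean(axis=1)
    return float(keyed[item_id].corr(rest))


def _mean_abs_item_total(
    item_id: str, spec: ScaleSpec, datasets: list[pd.DataFrame]
) -> float:
    vals = [corrected_item_total(d, spec, item_id) for d in datasets]
    vals = [abs(v) for v in vals if np.isfinite(v)]
    return float(np.mean(vals)) if vals else 0.0


def consensus_top_k(
    tally: ItemSelectionTally,
    spec: ScaleSpec,
    k: int = 5,
    tiebreak_data: list[pd.DataFrame] | None = None,
) -> ConsensusShortForm:
    """Keep the k most frequently selected items of each subscale.

    Within a subscale, items are sorted by selection count (descending).
    If the count at the cut boundary is tied, tied items are reordered
    by (1) higher mean absolute corrected item-total correlation across
    ``tiebreak_data``, then (2) original item order; the audit trail
    records the decision.  If fewer than k items were ever selected the
    deficit is filled from never-selected items by the same criterion,
    with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    missing = [i for i in spec.item_ids if i not in tally.counts.index]
    if missing:
        raise ValueError(f"tally lacks counts for items: {missing[:5]}")

    audit: list[dict] = []
    per_subscale: dict[str, list[tuple[str, int]]] = {}
    keep: set[str] = set()

    for sub in spec.subscales:
        ids = spec.items_in_subscale(sub)
        counts = {i: int(tally.counts[i]) for i in ids}
        ordered = sorted(ids, key=lambda i: (-counts[i], ids.index(i)))
        k_eff = min(k, len(ids))
        if k_eff < len(ordered) and counts[ordered[k_eff - 1]] == counts[ordered[k_eff]]:
            cut_count = counts[ordered[k_eff - 1]]
            tied = [i for i in ordered if counts[i] == cut_count]
            if tiebreak_data:
                crit = {i: _mean_abs_item_total(i, spec, tiebreak_data) for i in tied}
                rule = "item_total_then_order"
            else:
                crit = {i: 0.0 for i in tied}
                rule = "original_order"
            tied_sorted = sorted(tied, key=lambda i: (-crit[i], ids.index(i)))
            ordered = (
                [i for i in ordered if counts[i] > cut_count]
                + tied_sorted
                + [i for i in ordered if counts[i] < cut_count]
            )
            audit.append(
                {
                    "subscale": sub,
                    "count_at_cut": cut_count,
                    "tied_items": tied,
                    "rule": rule,
                    "criterion": {i: round(crit[i], 6) for i in tied},
                }
            )
        chosen = ordered[:k_eff]
        n_selected = sum(1 for i in chosen if counts[i] > 0)
        if n_selected < k_eff:
            warnings.warn(
                f"subscale {sub!r}: only {n_selected} items were ever selected; "
                f"filling to k={k_eff} from never-selected items"
            )
            audit.append({"subscale": sub, "shortfall": k_eff - n_selected})
        per_subscale[sub] = [(i, counts[i]) for i in chosen]
        keep.update(chosen)

    mask = np.array([1 if i in keep else 0 for i in spec.item_ids], dtype=np.int8)
    return ConsensusShortForm(
        mask=mask,
        item_ids=list(spec.item_ids),
        per_subscale=per_subscale,
        k=k,
        n_runs=tally.n_runs,
        audit=audit,
    )
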