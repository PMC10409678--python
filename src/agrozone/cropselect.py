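"""Top-crop selection from national crop statistics.

Given a table of items with harvested area, net production value and food
supply, the selector ranks individual crops (never group rows such as
"other vegetables") on each metric, keeps the top *k* per metric and returns
the union — the short list of crops important by area, economic value
and/or food production — together with the share of total harvested area
those crops represent.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd

DEFAULT_METRICS = ("harvested_area", "net_production_value", "food_supply")


@dataclass(frozen=True)
class SelectionParams:
    k: int = 15
    metrics: tuple[str, ...] = DEFAULT_METRICS

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class SelectionResult:
    crops: list[str]  # alphabetically sorted union
    combined_share_pct: float  # share of total non-group harvested area
    selected_by: dict[str, list[str]] = field(default_factory=dict)  # crop -> metrics

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item": self.crops,
                "selected_by": [";".join(self.selected_by[c]) for c in self.crops],
            }
        )


def read_crop_stats(path: str | os.PathLike) -> pd.DataFrame:
    """Read a crop-statistics CSV (item, is_group, the three metrics)."""
    df = pd.read_csv(path)
    df["is_group"] = df["is_group"].astype(bool)
    return df


def select_top_crops(stats: pd.DataFrame, params: SelectionParams = SelectionParams()) -> SelectionResult:
    """Union of the top-``k`` individual crops per metric.

    Group rows are excluded from both the rankings and the share
    denominator (individual crops already cover the same area, so counting
    groups would double it).  Missing metric values drop an item from that
    metric's ranking only; ties rank alphabetically.
    """
    if stats.empty:
        raise ValueError("empty crop statistics table")
    items = stats.loc[~stats["is_group"].astype(bool)].copy()
    if items.empty:
        raise ValueError("all rows are crop groups; nothing to select")
    if items["item"].duplicated().any():
        raise ValueError("item names must be unique")

    selected_by: dict[str, list[str]] = {}
    for metric in params.metrics:
        ranked = (
            items.dropna(subset=[metric])
            .sort_values([metric, "item"], ascending=[False, True], kind="mergesort")
            .head(params.k)
        )
        for item in ranked["item"]:
            selected_by.setdefault(item, []).append(metric)

    crops = sorted(selected_by)
    area = items.set_index("item")["harvested_area"].fillna(0.0)
    total = float(area.sum())
    share = 100.0 * float(area.loc[crops].sum()) / total if total > 0 else 0.0
    return SelectionResult(crops=crops, combined_share_pct=share, selected_by=selected_by)
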