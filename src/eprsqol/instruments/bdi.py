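"""Beck Depression Inventory (21-item) scoring and melancholic subtyping.

Each of the 21 items is rated 0-3; the total ranges 0-63 and a total of 10
or more screens positive for depressive symptoms.  Screen-positive
respondents are subtyped by comparing the mean rating over the
melancholia-aligned items (DSM-IV melancholic features: sadness, past
failure, loss of pleasure, guilt, punishment feelings, irritability, loss of
interest, change of sleeping, change of appetite) against the mean over the
remaining items; the higher mean decides the subtype and ties go to
melancholic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

N_ITEMS = 21

# 1-based positions of the melancholic items on the standard 21-item form:
# 1 sadness, 3 past failure, 4 loss of pleasure, 5 guilt, 6 punishment
# feelings, 11 irritability, 12 loss of interest, 16 change of sleeping,
# 18 change of appetite.  The mapping is data, not code: instrument versions
# differ in numbering, so it is configurable.
DEFAULT_MELANCHOLIC_ITEMS = (1, 3, 4, 5, 6, 11, 12, 16, 18)

DEPRESSION_THRESHOLD = 10


@dataclass(frozen=True)
class BdiItemMap:
    """Partition of the 21 items into melancholic and non-melancholic sets."""

    melancholic: tuple[int, ...] = DEFAULT_MELANCHOLIC_ITEMS
    non_melancholic: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        mel = tuple(sorted(self.melancholic))
        if not mel:
            raise ValueError("melancholic item set must be nonempty")
        if len(set(mel)) != len(mel) or any(i < 1 or i > N_ITEMS for i in mel):
            raise ValueError("melancholic items must be distinct positions in 1..21")
        nonmel = self.non_melancholic or tuple(
            i for i in range(1, N_ITEMS + 1) if i not in set(mel)
        )
        if set(mel) & set(nonmel) or set(mel) | set(nonmel) != set(range(1, N_ITEMS + 1)):
            raise ValueError("item map must partition items 1..21")
        object.__setattr__(self, "melancholic", mel)
        object.__setattr__(self, "non_melancholic", tuple(sorted(nonmel)))


DEFAULT_ITEM_MAP = BdiItemMap()


@dataclass(frozen=True)
class BdiResult:
    total: int
    depressed: bool
    subtype: str  # none | melancholic | non_melancholic
    mel_mean: float
    nonmel_mean: float


def _validate_items(items: np.ndarray) -> np.ndarray:
    arr = np.asarray(items)
    if arr.shape[-1] != N_ITEMS:
        raise ValueError(f"expected {N_ITEMS} BDI items, got {arr.shape[-1]}")
    if not np.isin(arr, [0, 1, 2, 3]).all():
        raise ValueError("BDI item ratings must be integers in {0,1,2,3}")
    return arr.astype(int)


def score_bdi(items: Sequence[int], item_map: BdiItemMap = DEFAULT_ITEM_MAP) -> BdiResult:
    """Score one respondent's 21 item ratings."""
    arr = _validate_items(np.asarray(items))
    total = int(arr.sum())
    mel_idx = np.array(item_map.melancholic) - 1
    nonmel_idx = np.array(item_map.non_melancholic) - 1
    mel_mean = float(arr[mel_idx].mean())
    nonmel_mean = float(arr[nonmel_idx].mean())
    depressed = total >= DEPRESSION_THRESHOLD
    if not depressed:
        subtype = "none"
    elif mel_mean >= nonmel_mean:  # tie -> melancholic
        subtype = "melancholic"
    else:
        subtype = "non_melancholic"
    return BdiResult(total, depressed, subtype, mel_mean, nonmel_mean)


def score_bdi_frame(
    items: pd.DataFrame, item_map: BdiItemMap = DEFAULT_ITEM_MAP
) -> pd.DataFrame:
    """Vectorized scoring of a cohort; columns must be the 21 items in order."""
    arr = _validate_items(items.to_numpy())
    total = arr.sum(axis=1)
    mel = arr[:, np.array(item_map.melancholic) - 1].mean(axis=1)
    nonmel = arr[:, np.array(item_map.non_melancholic) - 1].mean(axis=1)
    depressed = total >= DEPRESSION_THRESHOLD
    subtype = np.where(
        ~depressed, "none", np.where(mel >= nonmel, "melancholic", "non_melancholic")
    )
    return pd.DataFrame(
        {
            "bdi_total": total,
            "depressed": depressed,
            "subtype": pd.Categorical(
                subtype, categories=["none", "non_melancholic", "melancholic"]
            ),
            "mel_mean": mel,
            "nonmel_mean": nonmel,
        },
        index=items.index,
    )
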