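"""Binary item-response data: container, validation, CSV input/output.

The raw input everywhere in this package is an N x J matrix of 0/1 item
scores, one row per subject, one column per item.  Tests of monotone
homogeneity condition each item pair on the remaining items, so at least
three items are required.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ItemResponseMatrix", "load_responses", "save_responses"]


@dataclass(frozen=True)
class ItemResponseMatrix:
    """An N x J matrix of binary item scores.

    Parameters
    ----------
    values
        Integer array of shape (N, J) with entries in {0, 1}.
    item_names
        Optional column labels; defaults to ``item1 ... itemJ``.
    """

    values: np.ndarray
    item_names: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise ValueError("item responses must be a 2-D array")
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("item scores must be 0 or 1 (missing values are rejected)")
        vals = vals.astype(np.int8, copy=False)
        object.__setattr__(self, "values", vals)
        names = self.item_names
        if names is None:
            names = tuple(f"item{j + 1}" for j in range(vals.shape[1]))
        else:
            names = tuple(str(n) for n in names)
            if len(names) != vals.shape[1]:
                raise ValueError("item_names length must equal the number of columns")
        object.__setattr__(self, "item_names", names)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def take_rows(self, rows: np.ndarray) -> "ItemResponseMatrix":
        """Return the sub-matrix with the given subject rows."""
        return ItemResponseMatrix(self.values[np.asarray(rows)], self.item_names)


def load_responses(path) -> ItemResponseMatrix:
    """Read an item-response matrix from CSV (header row, strict 0/1 cells)."""
    frame = pd.read_csv(path)
    if frame.isna().any().any():
        raise ValueError(f"missing values in {path!s}; only complete 0/1 data are accepted")
    return ItemResponseMatrix(frame.to_numpy(), tuple(frame.columns))


def save_responses(X: ItemResponseMatrix, path) -> None:
    """Write an item-response matrix to CSV with a header row of item names."""
    pd.DataFrame(X.values, columns=list(X.item_names)).to_csv(path, index=False)
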