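"""Structure-of-arrays storage for one molecular species.

Agents of a species share a column layout (position plus per-species state
fields) and are stored in parallel numpy arrays in creation order, which the
scheduler relies on for reproducibility.  Removal compacts the arrays,
preserving relative order; rules therefore never hold indices across ticks —
all cross-agent relationships are encoded as expiry/release tick fields.
"""

from __future__ import annotations

from typing import Iterator, Mapping

import numpy as np


class Pool:
    """A compact table of live agents of one species."""

    def __init__(self, columns: Mapping[str, np.dtype | type]):
        self.columns = {name: np.dtype(dt) for name, dt in columns.items()}
        self.data: dict[str, np.ndarray] = {
            name: np.empty(0, dtype=dt) for name, dt in self.columns.items()
        }

    def __len__(self) -> int:
        first = next(iter(self.data.values()))
        return int(first.shape[0])

    @property
    def n(self) -> int:
        return len(self)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[name]

    def __setitem__(self, name: str, values: np.ndarray) -> None:
        if values.shape[0] != len(self):
            raise ValueError(f"column {name!r}: length mismatch")
        self.data[name] = values.astype(self.columns[name], copy=False)

    def add(self, **fields) -> None:
        """Append agents; scalar values broadcast across the batch."""
        lengths = [np.size(v) for v in fields.values() if np.ndim(v) > 0]
        count = lengths[0] if lengths else 1
        for name, dt in self.columns.items():
            if name not in fields:
                raise KeyError(f"missing column {name!r}")
            value = np.broadcast_to(np.asarray(fields[name], dtype=dt), count)
            self.data[name] = np.concatenate([self.data[name], value])

    def remove(self, mask: np.ndarray) -> None:
        """Drop agents where ``mask`` is True, preserving order."""
        keep = ~np.asarray(mask, dtype=bool)
        if keep.all():
            return
        for name in self.data:
            self.data[name] = self.data[name][keep]

    def positions(self) -> np.ndarray:
        """(n, 2) array of x, y (a view-copy; write back via set_positions)."""
        return np.stack([self.data["x"], self.data["y"]], axis=-1)

    def set_positions(self, xy: np.ndarray) -> None:
        self.data["x"] = xy[:, 0].astype(self.columns["x"], copy=False)
        self.data["y"] = xy[:, 1].astype(self.columns["y"], copy=False)

    # -- serialisation -----------------------------------------------------
    def to_records(self) -> Iterator[dict]:
        for i in range(len(self)):
            yield {name: col[i].item() for name, col in self.data.items()}

    def load_records(self, records: list[dict]) -> None:
        for name, dt in self.columns.items():
            self.data[name] = np.array([r[name] for r in records], dtype=dt)
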