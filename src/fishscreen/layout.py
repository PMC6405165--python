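"""Randomized 96-well plate loading schemes.

Wells are loaded in a randomized order so that condition effects are not
confounded with plate position (edge evaporation, illumination gradients).
The layout is a seeded uniform permutation of the requested condition
labels over the plate, with unused wells recorded explicitly as empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import CapacityError

#: Label used for wells that carry no embryo. Explicit so that downstream
#: joins can distinguish "empty by design" from "missing file".
EMPTY = "empty"


def well_name(row: int, col: int) -> str:
    """Row-major plate well name, e.g. (0, 0) -> 'A1', (7, 11) -> 'H12'."""
    return f"{chr(ord('A') + row)}{col + 1}"


@dataclass(frozen=True)
class PlateLayout:
    """Mapping of wells to condition labels for one plate.

    Attributes
    ----------
    rows, cols : int
        Plate geometry (8 x 12 for a standard 96-well plate).
    assignment : dict
        ``well name -> condition label`` with every well present; unused
        wells carry :data:`EMPTY`.
    seed : int
        Seed of the permutation that produced the layout.
    """

    rows: int
    cols: int
    assignment: Mapping[str, str] = field(default_factory=dict)
    seed: int = 0

    @property
    def wells(self) -> list[str]:
        """All well names in row-major order."""
        return [well_name(r, c) for r in range(self.rows) for c in range(self.cols)]

    def condition_of(self, well: str) -> str:
        return self.assignment[well]

    def wells_of(self, condition: str) -> list[str]:
        return [w for w in self.wells if self.assignment[w] == condition]

    @property
    def occupied_wells(self) -> list[str]:
        return [w for w in self.wells if self.assignment[w] != EMPTY]

    def counts(self) -> dict[str, int]:
        """Number of wells per condition (excluding empty wells)."""
        out: dict[str, int] = {}
        for w in self.occupied_wells:
            c = self.assignment[w]
            out[c] = out.get(c, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        records = []
        for r in range(self.rows):
            for c in range(self.cols):
                w = well_name(r, c)
                records.append(
                    {"well": w, "row": chr(ord("A") + r), "col": c + 1,
                     "condition": self.assignment[w]}
                )
        return pd.DataFrame.from_records(records)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, seed: int = 0) -> "PlateLayout":
        rows = frame["row"].map(lambda r: ord(str(r)) - ord("A")).max() + 1
        cols = int(frame["col"].max())
        assignment = dict(zip(frame["well"], frame["condition"]))
        return cls(rows=int(rows), cols=cols, assignment=assignment, seed=seed)

    @classmethod
    def from_csv(cls, path, seed: int = 0) -> "PlateLayout":
        return cls.from_frame(pd.read_csv(path), seed=seed)


def randomize_layout(
    requests: Mapping[str, int],
    rows: int = 8,
    cols: int = 12,
    seed: int = 0,
) -> PlateLayout:
    """Assign conditions to wells by a seeded uniform permutation.

    Parameters
    ----------
    requests : mapping
        ``condition label -> replicate count``. The total must not exceed
        ``rows * cols``; the remainder of the plate is marked empty.
    rows, cols : int
        Plate geometry.
    seed : int
        Seed for the permutation; identical seeds give identical layouts.

    Raises
    ------
    CapacityError
        If the requested replicates exceed the plate capacity.
    """
    capacity = rows * cols
    total = sum(int(n) for n in requests.values())
    if any(int(n) < 0 for n in requests.values()):
        raise CapacityError("replicate counts must be non-negative")
    if total > capacity:
        raise CapacityError(
            f"requested {total} wells on a {rows}x{cols} plate ({capacity} wells)"
        )
    labels = [c for c in sorted(requests) for _ in range(int(requests[c]))]
    labels += [EMPTY] * (capacity - total)
    rng = np.random.default_rng(seed)
    order = rng.permutation(capacity)
    wells = [well_name(r, c) for r in range(rows) for c in range(cols)]
    assignment = {wells[i]: labels[order[i]] for i in range(capacity)}
    return PlateLayout(rows=rows, cols=cols, assignment=assignment, seed=seed)
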