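"""Five-year reproductive age groups (15-19 ... 45-49) and the table indexed by them.

Every age-indexed quantity in the pipeline — death counts, person-years of
exposure, birth counts, calendar outcome tallies, adjustment factors, the
respondent age composition — lives in an :class:`AgeGroupTable`: one float per
five-year group from 15-19 to 45-49, in fixed order.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator

import numpy as np

AGE_GROUP_LABELS: tuple[str, ...] = (
    "15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49",
)
N_AGE_GROUPS = len(AGE_GROUP_LABELS)

#: Completed age in months at the lower/upper bound of the indexed range.
MIN_AGE_MONTHS = 15 * 12          # 180: first month of 15-19
MAX_AGE_MONTHS = 50 * 12 - 1      # 599: last month of 45-49
GROUP_WIDTH_MONTHS = 5 * 12


class AgeGroupTable:
    """A vector of one numeric value per five-year age group.

    Thin wrapper over a length-7 float array; supports indexing by position
    or by label ("20-24"), iteration, elementwise arithmetic with scalars
    and other tables, and conversion to a plain dict for serialisation.
    """

    __slots__ = ("values",)

    def __init__(self, values: Iterable[float] | np.ndarray | float = 0.0):
        if np.isscalar(values):
            arr = np.full(N_AGE_GROUPS, float(values))
        else:
            arr = np.asarray(values, dtype=float).copy()
            if arr.shape != (N_AGE_GROUPS,):
                raise ValueError(
                    f"AgeGroupTable needs exactly {N_AGE_GROUPS} values, got shape {arr.shape}"
                )
        self.values = arr

    @classmethod
    def zeros(cls) -> "AgeGroupTable":
        return cls(np.zeros(N_AGE_GROUPS))

    @classmethod
    def from_dict(cls, d: dict[str, float], default: float = 0.0) -> "AgeGroupTable":
        return cls([float(d.get(lbl, default)) for lbl in AGE_GROUP_LABELS])

    def to_dict(self) -> dict[str, float]:
        return {lbl: float(v) for lbl, v in zip(AGE_GROUP_LABELS, self.values)}

    def _index(self, key: int | str) -> int:
        if isinstance(key, str):
            try:
                return AGE_GROUP_LABELS.index(key)
            except ValueError:
                raise KeyError(f"unknown age group {key!r}") from None
        return int(key)

    def __getitem__(self, key: int | str) -> float:
        return float(self.values[self._index(key)])

    def __setitem__(self, key: int | str, value: float) -> None:
        self.values[self._index(key)] = value

    def __iter__(self) -> Iterator[float]:
        return iter(float(v) for v in self.values)

    def __len__(self) -> int:
        return N_AGE_GROUPS

    def sum(self) -> float:
        return float(self.values.sum())

    def _coerce(self, other) -> np.ndarray:
        if isinstance(other, AgeGroupTable):
            return other.values
        return np.asarray(other, dtype=float)

    def __add__(self, other) -> "AgeGroupTable":
        return AgeGroupTable(self.values + self._coerce(other))

    def __sub__(self, other) -> "AgeGroupTable":
        return AgeGroupTable(self.values - self._coerce(other))

    def __mul__(self, other) -> "AgeGroupTable":
        return AgeGroupTable(self.values * self._coerce(other))

    __radd__ = __add__
    __rmul__ = __mul__

    def __truediv__(self, other) -> "AgeGroupTable":
        return AgeGroupTable(self.values / self._coerce(other))

    def __eq__(self, other) -> bool:
        if not isinstance(other, AgeGroupTable):
            return NotImplemented
        return bool(np.array_equal(self.values, other.values))

    def allclose(self, other: "AgeGroupTable", rtol: float = 1e-12, atol: float = 0.0) -> bool:
        return bool(np.allclose(self.values, other.values, rtol=rtol, atol=atol))

    def __repr__(self) -> str:
        body = ", ".join(f"{lbl}: {v:g}" for lbl, v in zip(AGE_GROUP_LABELS, self.values))
        return f"AgeGroupTable({body})"


def age_group_index_from_months(age_months) -> np.ndarray:
    """Vectorised map from completed age in months to group index 0..6, or -1.

    -1 marks ages outside 15-49 completed years (below 180 or above 599
    months); those person-months and events are excluded everywhere.
    """
    a = np.asarray(age_months, dtype=np.int64)
    idx = (a - MIN_AGE_MONTHS) // GROUP_WIDTH_MONTHS
    out_of_range = (a < MIN_AGE_MONTHS) | (a > MAX_AGE_MONTHS)
    return np.where(out_of_range, -1, idx)
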