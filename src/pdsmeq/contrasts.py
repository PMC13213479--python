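"""Orthogonal Helmert contrast coding for sex, race/ethnicity, and their interaction.

The six intersectional cells (Black/Latinx/White x female/male) are represented by
five contrast-coded predictors:

* ``sex`` — female = 1, male = -1;
* ``race1`` — Black & Latinx vs White: Black = -1/3, Latinx = -1/3, White = 2/3;
* ``race2`` — Black vs Latinx: Black = -1/2, Latinx = 1/2, White = 0;
* ``sex_race1``, ``sex_race2`` — elementwise products of ``sex`` with the race codes.

Codes are held as exact :class:`fractions.Fraction` values internally so the thirds
never accumulate floating-point rounding; they are converted to floats only when a
model matrix is materialised.  The codes are fixed constants of the coding scheme and
are *not* re-centred at observed cell proportions, so the columns are mutually
orthogonal only under balanced cell sizes — :func:`verify_orthogonality` reports, and
never enforces, departures from orthogonality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CodingError",
    "GroupLabel",
    "ContrastDesign",
    "SEXES",
    "RACES",
    "COLUMN_NAMES",
    "normalize_sex",
    "normalize_race",
    "build_contrast_codes",
    "build_design",
    "decode_codes",
    "verify_orthogonality",
    "all_groups",
]


class CodingError(ValueError):
    """Raised when a sex or race/ethnicity label is outside the supported whitelist."""


#: Canonical category labels, in the fixed order used by the Helmert scheme.
SEXES: tuple[str, ...] = ("female", "male")
RACES: tuple[str, ...] = ("Black", "Latinx", "White")
COLUMN_NAMES: tuple[str, ...] = ("sex", "race1", "race2", "sex_race1", "sex_race2")

_SEX_CODE: Mapping[str, Fraction] = {"female": Fraction(1), "male": Fraction(-1)}
_RACE1: Mapping[str, Fraction] = {
    "Black": Fraction(-1, 3),
    "Latinx": Fraction(-1, 3),
    "White": Fraction(2, 3),
}
_RACE2: Mapping[str, Fraction] = {
    "Black": Fraction(-1, 2),
    "Latinx": Fraction(1, 2),
    "White": Fraction(0),
}

# Case-insensitive whitelists (the only admitted spellings).
_SEX_ALIASES = {"female": "female", "f": "female", "male": "male", "m": "male"}
_RACE_ALIASES = {
    "black": "Black",
    "latinx": "Latinx",
    "white": "White",
}


def normalize_sex(value: object) -> str:
    key = str(value).strip().lower()
    try:
        return _SEX_ALIASES[key]
    except KeyError:
        raise CodingError(f"unknown sex category: {value!r} (expected one of {SEXES})") from None


def normalize_race(value: object) -> str:
    key = str(value).strip().lower()
    try:
        return _RACE_ALIASES[key]
    except KeyError:
        raise CodingError(
            f"unknown race/ethnicity category: {value!r} (expected one of {RACES})"
        ) from None


@dataclass(frozen=True)
class GroupLabel:
    """One of the six intersectional cells."""

    sex: str
    race_ethnicity: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", normalize_sex(self.sex))
        object.__setattr__(self, "race_ethnicity", normalize_race(self.race_ethnicity))

    def __str__(self) -> str:  # e.g. "Black female"
        return f"{self.race_ethnicity} {self.sex}"


def all_groups() -> list[GroupLabel]:
    """The six cells in a fixed (race-major, female-first) order."""
    return [GroupLabel(s, r) for r in RACES for s in SEXES]


def build_contrast_codes(group: GroupLabel | tuple[str, str]) -> tuple[Fraction, ...]:
    """Exact contrast codes ``(sex, race1, race2, sex*race1, sex*race2)`` for one cell."""
    if not isinstance(group, GroupLabel):
        group = GroupLabel(*group)
    s = _SEX_CODE[group.sex]
    r1 = _RACE1[group.race_ethnicity]
    r2 = _RACE2[group.race_ethnicity]
    return (s, r1, r2, s * r1, s * r2)


_DECODE: dict[tuple[Fraction, ...], GroupLabel] = {
    build_contrast_codes(g): g for g in all_groups()
}


def decode_codes(codes: Sequence) -> GroupLabel:
    """Invert a 5-vector of contrast codes back to its unique group label."""
    key = tuple(Fraction(c).limit_denominator(6) for c in codes)
    try:
        return _DECODE[key]
    except KeyError:
        raise CodingError(f"code vector {tuple(map(str, key))} matches no supported cell") from None


@dataclass
class ContrastDesign:
    """Row-wise contrast codes for a person table.

    ``exact`` holds one tuple of Fractions per row; ``matrix`` materialises the
    float n x 5 model matrix.
    """

    exact: list[tuple[Fraction, ...]]
    column_names: tuple[str, ...] = COLUMN_NAMES
    _matrix: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.exact)

    @property
    def matrix(self) -> np.ndarray:
        if self._matrix is None:
            self._matrix = np.array(
                [[float(c) for c in row] for row in self.exact], dtype=float
            ).reshape(self.n, len(self.column_names))
        return self._matrix

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=list(self.column_names))


def build_design(table: pd.DataFrame, adapt_to_present: bool = False) -> ContrastDesign:
    """Build the n x 5 contrast design from a table with ``sex`` and ``race_ethnicity``.

    Coding errors are re-raised with the offending row index attached.

    With ``adapt_to_present=True`` (used for subgroup sensitivity analyses, e.g.
    excluding White participants) columns that are constant, or perfectly collinear
    with an earlier column, in the observed rows are dropped: with only Black and
    Latinx present, ``race1`` is constant and ``sex_race1`` collapses onto ``sex``,
    leaving the 3-column design (sex, race2, sex_race2).
    """
    for col in ("sex", "race_ethnicity"):
        if col not in table.columns:
            raise CodingError(f"table lacks required column {col!r}")
    # Only six distinct cells exist, so code each unique pair once.
    cache: dict[tuple, tuple[Fraction, ...]] = {}
    rows: list[tuple[Fraction, ...]] = []
    for i, (s, r) in enumerate(zip(table["sex"], table["race_ethnicity"])):
        key = (s, r)
        if key not in cache:
            try:
                cache[key] = build_contrast_codes(GroupLabel(s, r))
            except CodingError as err:
                raise CodingError(f"row {i}: {err}") from None
        rows.append(cache[key])
    design = ContrastDesign(exact=rows)
    if adapt_to_present and design.n:
        design = _drop_degenerate_columns(design)
    return design


def _drop_degenerate_columns(design: ContrastDesign) -> ContrastDesign:
    """Drop constant or collinear columns (after centering is NOT applied: the codes
    are fixed, so 'constant' means literally one value in the observed rows)."""
    X = design.matrix
    keep: list[int] = []
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.ptp(col) == 0.0:
            continue
        if keep:
            prev = X[:, keep]
            # rank unchanged when adding col => collinear with kept columns
            if np.linalg.matrix_rank(np.column_stack([prev, col])) == len(keep):
                continue
        keep.append(j)
    exact = [tuple(row[j] for j in keep) for row in design.exact]
    names = tuple(design.column_names[j] for j in keep)
    return ContrastDesign(exact=exact, column_names=names)


def verify_orthogonality(design: ContrastDesign, tolerance: float = 1e-12) -> pd.DataFrame:
    """Report pairwise column mean cross-products and flag pairs exceeding ``tolerance``.

    Exact orthogonality holds only under balanced cell sizes; at unbalanced
    (e.g. realistic cohort) proportions small nonzero products are expected and the
    flags are informational.
    """
    if design.n == 0:
        raise ValueError("orthogonality check requires a nonempty design")
    X = design.matrix
    names = design.column_names
    records = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            dot = float(X[:, a] @ X[:, b]) / design.n
            records.append(
                {
                    "col_a": names[a],
                    "col_b": names[b],
                    "mean_cross_product": dot,
                    "orthogonal": abs(dot) <= tolerance,
                }
            )
    return pd.DataFrame.from_records(records)
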