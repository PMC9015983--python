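"""Sum-to-zero contrast design matrices for the factorial RT models.

Factors are Distance (5 levels), Light Location and Tactile Location (3
levels each), all treated as categorical.  A k-level factor contributes
k - 1 sum-to-zero columns (level i indicator minus last-level indicator);
interaction blocks are elementwise products of their margins' columns, so
a full three-way expansion of the 3 x 3 x 5 design has
1 + 4 + 2 + 2 + 8 + 8 + 4 + 16 = 45 columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["FACTOR_COLUMNS", "DesignMatrices", "sum_to_zero", "build_design"]

#: Term token -> data column.
FACTOR_COLUMNS = {
    "distance": "distance",
    "light": "light_location",
    "tactile": "tactile_location",
}
_ALIASES = {
    "distance": "distance",
    "light": "light",
    "lightlocation": "light",
    "light_location": "light",
    "tactile": "tactile",
    "tactilelocation": "tactile",
    "tactile_location": "tactile",
    "intercept": "intercept",
    "1": "intercept",
}


class SpecificationError(ValueError):
    """Raised for malformed model terms or rank-deficient designs."""


def canonical_term(term: str) -> str:
    parts = [p.strip().lower() for p in term.split(":")]
    try:
        parts = [_ALIASES[p] for p in parts]
    except KeyError as exc:
        raise SpecificationError(f"unknown factor {exc.args[0]!r} in term {term!r}") from None
    return ":".join(parts)


def sum_to_zero(values: Sequence, levels: Sequence) -> np.ndarray:
    """(n, k-1) sum-to-zero contrast columns for a categorical vector."""
    levels = list(levels)
    codes = pd.Categorical(values, categories=levels).codes
    if (codes < 0).any():
        bad = sorted(set(np.asarray(values)[codes < 0]))
        raise SpecificationError(f"values {bad} not among declared levels {levels}")
    k = len(levels)
    out = np.zeros((len(codes), k - 1))
    for j in range(k - 1):
        out[:, j] = (codes == j).astype(float) - (codes == k - 1).astype(float)
    return out


@dataclass
class DesignMatrices:
    """Fixed (X) and random (Z) design matrices with column bookkeeping."""

    X: np.ndarray
    term_slices: dict[str, slice]
    coef_names: list[str]
    Z: np.ndarray  # (n, q); q = 0 when no random terms
    z_names: list[str]
    subject: np.ndarray  # integer subject codes per row
    subjects: list
    levels: dict[str, list] = field(default_factory=dict)

    @property
    def n_coef(self) -> int:
        return self.X.shape[1]

    @property
    def n_random(self) -> int:
        return self.Z.shape[1]


def _factor_block(
    data: pd.DataFrame, factor: str, levels: dict[str, list]
) -> tuple[np.ndarray, list[str]]:
    col = FACTOR_COLUMNS[factor]
    if col not in data.columns:
        raise SpecificationError(f"term {factor!r} needs column {col!r}, absent from data")
    cols = sum_to_zero(data[col].to_numpy(), levels[factor])
    names = [f"{factor}[{lev}]" for lev in levels[factor][:-1]]
    return cols, names


def build_design(
    data: pd.DataFrame,
    fixed_terms: Sequence[str],
    random_terms: Sequence[str] = (),
    levels: Mapping[str, Sequence] | None = None,
) -> DesignMatrices:
    """Build X and Z for a cell-mean table.

    ``fixed_terms`` are factor tokens ("distance", "light", "tactile") or
    interactions ("distance:light"); an intercept column is always included
    first under the term name "intercept".  ``random_terms`` are
    by-participant terms from {"intercept", "light", "tactile"}.  Factor
    levels default to the sorted values observed in the data and can be
    pinned explicitly for prediction on new data.
    """
    fixed_terms = [canonical_term(t) for t in fixed_terms]
    if len(set(fixed_terms)) != len(fixed_terms):
        raise SpecificationError(f"duplicate fixed terms in {fixed_terms}")
    lv = {
        f: list(levels[f]) if levels and f in levels else sorted(data[FACTOR_COLUMNS[f]].unique())
        for f in FACTOR_COLUMNS
        if FACTOR_COLUMNS[f] in data.columns
    }

    blocks = [np.ones((len(data), 1))]
    names = ["intercept"]
    slices = {"intercept": slice(0, 1)}
    pos = 1
    for term in fixed_terms:
        if term == "intercept":
            continue
        factors = term.split(":")
        cols, cnames = _factor_block(data, factors[0], lv)
        for f in factors[1:]:
            c2, n2 = _factor_block(data, f, lv)
            cols = np.concatenate(
                [cols[:, [i]] * c2 for i in range(cols.shape[1])], axis=1
            )
            cnames = [
                f"{a}:{b}"
                for a, b in product(cnames, n2)
            ]
        blocks.append(cols)
        names.extend(cnames)
        slices[term] = slice(pos, pos + cols.shape[1])
        pos += cols.shape[1]
    X = np.concatenate(blocks, axis=1)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SpecificationError("rank-deficient fixed-effect design")

    subjects = sorted(data["participant"].unique()) if "participant" in data.columns else []
    subj = (
        pd.Categorical(data["participant"], categories=subjects).codes.astype(int)
        if subjects
        else np.zeros(len(data), dtype=int)
    )
    z_blocks: list[np.ndarray] = []
    z_names: list[str] = []
    for term in (canonical_term(t) for t in random_terms):
        if term == "intercept":
            z_blocks.append(np.ones((len(data), 1)))
            z_names.append("u|intercept")
        else:
            cols, cnames = _factor_block(data, term, lv)
            z_blocks.append(cols)
            z_names.extend(f"u|{n}" for n in cnames)
    Z = np.concatenate(z_blocks, axis=1) if z_blocks else np.zeros((len(data), 0))
    return DesignMatrices(X, slices, names, Z, z_names, subj, subjects, lv)
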