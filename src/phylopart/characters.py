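"""Discrete morphological character matrices.

A :class:`CharacterMatrix` is a taxa-by-characters table of discrete
states with per-character ordering flags (unordered Fitch-style vs
ordered linear-cost) and a two-way partition of characters into ``hard``
(biomineralized, readily fossilizable anatomy: bones, teeth, shells) and
``soft`` (myology, integument, internal organs) classes.

Cell values follow the union ("any member") semantics standard in
parsimony software: a cell is either a single state, a polymorphic set
of states, or missing.  Missing is represented by ``None`` and is
distinct from every state; in scoring it behaves as the full state set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .errors import ValidationError

#: Sentinel for a missing observation (``?`` or ``-`` in NEXUS files).
MISSING = None

UNORDERED = "unordered"
ORDERED = "ordered"

HARD = "hard"
SOFT = "soft"

Cell = "frozenset[int] | None"


def cell(value) -> "frozenset[int] | None":
    """Normalize a cell value: int, iterable of ints, or None/MISSING."""
    if value is MISSING:
        return MISSING
    if isinstance(value, int):
        return frozenset((value,))
    states = frozenset(int(v) for v in value)
    if not states:
        raise ValidationError("empty state set is not a valid cell")
    return states


@dataclass(frozen=True)
class CharacterColumn:
    """One character: a per-taxon tuple of cells (state sets or MISSING)."""

    cells: tuple

    def __post_init__(self):
        object.__setattr__(self, "cells", tuple(cell(c) for c in self.cells))
        for c in self.cells:
            if c is not MISSING and any(s < 0 for s in c):
                raise ValidationError("negative state symbols are not allowed")

    @property
    def n_taxa(self) -> int:
        return len(self.cells)

    @property
    def observed_states(self) -> tuple:
        """Sorted union of states over all non-missing cells."""
        seen = set()
        for c in self.cells:
            if c is not MISSING:
                seen |= c
        return tuple(sorted(seen))

    @property
    def n_observed(self) -> int:
        """Number of non-missing cells."""
        return sum(1 for c in self.cells if c is not MISSING)

    def is_constant(self) -> bool:
        """True if some single state is compatible with every cell."""
        live = [c for c in self.cells if c is not MISSING]
        if not live:
            return True
        common = frozenset.intersection(*live)
        return bool(common)


@dataclass(frozen=True)
class CharacterMatrix:
    """Taxa x characters with ordering flags and hard/soft partition labels.

    Parameters
    ----------
    taxa
        Ordered unique taxon labels (>= 2).
    columns
        One :class:`CharacterColumn` per character; every column has
        exactly one cell per taxon.
    ordering
        Per-character flag, ``"unordered"`` or ``"ordered"``.
    partition
        Per-character label, ``"hard"`` or ``"soft"``.
    dataset_id, clade
        Free-text identifiers used by collection runs.
    """

    taxa: tuple
    columns: tuple
    ordering: tuple
    partition: tuple
    dataset_id: str = ""
    clade: str = ""

    def __post_init__(self):
        object.__setattr__(self, "taxa", tuple(str(t) for t in self.taxa))
        object.__setattr__(self, "columns", tuple(self.columns))
        object.__setattr__(self, "ordering", tuple(self.ordering))
        object.__setattr__(self, "partition", tuple(self.partition))
        if len(self.taxa) < 2:
            raise ValidationError("a character matrix needs at least 2 taxa")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError("duplicate taxon labels")
        n = len(self.columns)
        if len(self.ordering) != n or len(self.partition) != n:
            raise ValidationError(
                "ordering and partition labels must cover every column"
            )
        for o in self.ordering:
            if o not in (UNORDERED, ORDERED):
                raise ValidationError(f"unknown ordering flag {o!r}")
        for p in self.partition:
            if p not in (HARD, SOFT):
                raise ValidationError(f"unknown partition label {p!r}")
        for j, col in enumerate(self.columns):
            if not isinstance(col, CharacterColumn):
                raise ValidationError(f"column {j} is not a CharacterColumn")
            if col.n_taxa != len(self.taxa):
                raise ValidationError(
                    f"column {j} has {col.n_taxa} cells for "
                    f"{len(self.taxa)} taxa"
                )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.columns)

    @property
    def max_state(self) -> int:
        """Largest state symbol observed anywhere (0 if all missing)."""
        best = 0
        for col in self.columns:
            if col.observed_states:
                best = max(best, col.observed_states[-1])
        return best

    def indices(self, label: str) -> tuple:
        """Character indices carrying the given partition label."""
        return tuple(j for j, p in enumerate(self.partition) if p == label)

    @property
    def hard_indices(self) -> tuple:
        return self.indices(HARD)

    @property
    def soft_indices(self) -> tuple:
        return self.indices(SOFT)

    def subset(self, indices: Iterable[int]) -> "CharacterMatrix":
        """A new matrix containing only the given characters (same taxa)."""
        idx = tuple(indices)
        return replace(
            self,
            columns=tuple(self.columns[j] for j in idx),
            ordering=tuple(self.ordering[j] for j in idx),
            partition=tuple(self.partition[j] for j in idx),
        )

    def take_taxa(self, labels: Iterable[str]) -> "CharacterMatrix":
        """Restrict to the given taxa, preserving the matrix's taxon order."""
        keep = set(labels)
        missing = keep - set(self.taxa)
        if missing:
            raise ValidationError(f"taxa not in matrix: {sorted(missing)}")
        rows = [i for i, t in enumerate(self.taxa) if t in keep]
        return replace(
            self,
            taxa=tuple(self.taxa[i] for i in rows),
            columns=tuple(
                CharacterColumn(tuple(col.cells[i] for i in rows))
                for col in self.columns
            ),
        )

    def with_partition(self, labels: Sequence[str]) -> "CharacterMatrix":
        return replace(self, partition=tuple(labels))


def matrix_from_strings(
    taxa: Sequence[str],
    rows: Sequence[Sequence],
    ordering: Sequence[str] | None = None,
    partition: Sequence[str] | None = None,
    **kw,
) -> CharacterMatrix:
    """Build a matrix from per-taxon rows of cell values.

    ``rows[i][j]`` is the cell for taxon ``i``, character ``j``; values may
    be ints, iterables of ints, or ``None`` for missing.  Convenience for
    tests and examples.
    """
    n_char = len(rows[0]) if rows else 0
    cols = tuple(
        CharacterColumn(tuple(row[j] for row in rows)) for j in range(n_char)
    )
    if ordering is None:
        ordering = (UNORDERED,) * n_char
    if partition is None:
        half = n_char // 2
        partition = (HARD,) * half + (SOFT,) * (n_char - half)
    return CharacterMatrix(tuple(taxa), cols, tuple(ordering), tuple(partition), **kw)
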