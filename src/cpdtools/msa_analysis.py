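"""Position mapping and per-column conservation measures on ortholog MSAs.

An :class:`OrthologAlignment` is a set of aligned ortholog protein sequences
with one row designated as the human reference. Variant positions are 1-based
indices into the *ungapped* human sequence; :func:`map_position_to_column`
converts them to 0-based alignment columns. Column conservation is summarised
by amino-acid frequency profiles and their Shannon entropy in bits, which
ranges from 0 (fully conserved site) to log2(20) ~ 4.322 (all twenty amino
acids equally frequent).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

from .errors import ValidationError, UndefinedStatisticError

#: The 20 canonical amino acids, one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AMINO_ACID_SET = frozenset(AMINO_ACIDS)

#: Characters treated as alignment gaps.
GAP_CHARS = frozenset("-.")

#: Maximum attainable column entropy in bits: log2(20).
MAX_ENTROPY = math.log2(20)


@dataclass(frozen=True)
class OrthologAlignment:
    """Aligned ortholog sequences with a designated human row.

    Parameters
    ----------
    rows
        Ordered ``(species_id, aligned_seq)`` pairs. Sequences may contain
        gap characters (``-`` or ``.``) and are upper-cased on construction.
    human_index
        Index into ``rows`` of the human reference sequence.
    """

    rows: tuple[tuple[str, str], ...]
    human_index: int

    def __post_init__(self) -> None:
        rows = tuple((sid, seq.upper()) for sid, seq in self.rows)
        object.__setattr__(self, "rows", rows)
        if not rows:
            raise ValidationError("alignment must contain at least one row")
        lengths = {len(seq) for _, seq in rows}
        if len(lengths) != 1:
            raise ValidationError(
                f"aligned sequences have unequal lengths: {sorted(lengths)}"
            )
        if lengths == {0}:
            raise ValidationError("aligned sequences must be non-empty")
        if not 0 <= self.human_index < len(rows):
            raise ValidationError(
                f"human_index {self.human_index} out of range for "
                f"{len(rows)} rows"
            )
        ids = [sid for sid, _ in rows]
        if len(set(ids)) != len(ids):
            raise ValidationError("species identifiers must be unique")

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def human_id(self) -> str:
        return self.rows[self.human_index][0]

    @property
    def human_row(self) -> str:
        return self.rows[self.human_index][1]

    @property
    def human_ungapped_length(self) -> int:
        return sum(1 for c in self.human_row if c not in GAP_CHARS)

    def column(self, index: int) -> str:
        """Residues (and gaps) of one column, in row order."""
        if not 0 <= index < self.length:
            raise IndexError(
                f"column {index} out of range for alignment of length "
                f"{self.length}"
            )
        return "".join(seq[index] for _, seq in self.rows)


@dataclass(frozen=True)
class ColumnProfile:
    """Amino-acid occurrence counts of one alignment column.

    Gaps and non-canonical letters are excluded from both ``counts`` and
    ``n_nongap``; frequencies therefore sum to 1 over canonical residues.
    """

    column_index: int
    counts: dict[str, int]
    n_nongap: int = field(init=False)

    def __post_init__(self) -> None:
        bad = set(self.counts) - AMINO_ACID_SET
        if bad:
            raise ValidationError(f"non-canonical letters in profile: {bad}")
        if any(c < 0 for c in self.counts.values()):
            raise ValidationError("negative count in profile")
        object.__setattr__(self, "counts", dict(self.counts))
        object.__setattr__(self, "n_nongap", sum(self.counts.values()))

    @property
    def frequencies(self) -> dict[str, float]:
        if self.n_nongap == 0:
            return {}
        return {aa: c / self.n_nongap for aa, c in self.counts.items()}


def map_position_to_column(aln: OrthologAlignment, pos: int) -> int:
    """Map a 1-based human-sequence position to its 0-based alignment column.

    The returned column holds the ``pos``-th non-gap character of the human
    row. Raises :class:`IndexError` if ``pos`` exceeds the ungapped human
    length.
    """
    if pos < 1:
        raise IndexError(f"position must be >= 1, got {pos}")
    seen = 0
    for col, char in enumerate(aln.human_row):
        if char not in GAP_CHARS:
            seen += 1
            if seen == pos:
                return col
    raise IndexError(
        f"position {pos} exceeds ungapped human length {seen} "
        f"(human row {aln.human_id!r})"
    )


def column_profile(aln: OrthologAlignment, column: int) -> ColumnProfile:
    """Count canonical residues in one column over all rows, human included.

    Gaps and ambiguous letters (X, B, Z, U, ...) do not contribute.
    """
    residues = aln.column(column)  # raises IndexError when out of range
    counts = Counter(c for c in residues if c in AMINO_ACID_SET)
    return ColumnProfile(column_index=column, counts=dict(counts))


def shannon_entropy(profile: ColumnProfile) -> float:
    """Shannon entropy of a column profile in bits: -sum p_i * log2 p_i.

    Bounded by [0, log2(20)]. Undefined (raises
    :class:`UndefinedStatisticError`) when the column has no canonical
    residues.
    """
    if profile.n_nongap == 0:
        raise UndefinedStatisticError(
            f"entropy undefined for all-gap column {profile.column_index}"
        )
    return -sum(p * math.log2(p) for p in profile.frequencies.values() if p > 0)


def residues_at_column(aln: OrthologAlignment, column: int) -> dict[str, str]:
    """Per-species residue (or gap character) at one column."""
    residues = aln.column(column)
    return {sid: residues[i] for i, (sid, _) in enumerate(aln.rows)}
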