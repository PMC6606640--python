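"""Classify pathogenic missense variants as compensated (CPD) or not.

A variant is a compensated pathogenic deviation (CPD) when the mutant
residue — pathogenic in humans — is found as the native residue of at least
one non-human ortholog at the same alignment column. One supporting species
suffices; the criterion is existential and threshold-free.

Severity contingency tables (CPD/noCPD x mild/severe) feed the association
statistics in :mod:`cpdtools.impact_stats`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, UndefinedStatisticError
from .io_formats import MissenseVariant
from .msa_analysis import (
    GAP_CHARS,
    OrthologAlignment,
    map_position_to_column,
    residues_at_column,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CompensationCall:
    """CPD/noCPD status of one variant plus the supporting evidence.

    ``supporting_species`` lists the non-human rows whose native residue at
    the mapped column equals the mutant residue; it is non-empty iff
    ``is_cpd``. ``human_residue_check`` is ``"mismatch"`` when the human MSA
    row disagrees with the variant table's wild-type residue; such calls are
    still emitted but flagged, and excluded from statistics by default.
    """

    variant: MissenseVariant
    is_cpd: bool
    supporting_species: tuple[str, ...]
    column: int
    human_residue_check: str  # "match" | "mismatch"

    def __post_init__(self) -> None:
        assert self.is_cpd == bool(self.supporting_species)
        assert self.human_residue_check in ("match", "mismatch")


def classify_variant(
    variant: MissenseVariant, aln: OrthologAlignment
) -> CompensationCall:
    """Call CPD status for one variant against its gene's ortholog MSA.

    Matching is exact, case-insensitive, single-letter equality; gaps and
    ambiguous letters never match. Raises :class:`IndexError` when the
    position exceeds the ungapped human sequence.
    """
    column = map_position_to_column(aln, variant.pos)
    residues = residues_at_column(aln, column)
    human_residue = residues[aln.human_id]
    check = "match" if human_residue == variant.wt else "mismatch"
    if check == "mismatch":
        logger.warning(
            "%s %s: human MSA residue %r at column %d != table wt %r",
            variant.gene,
            variant.key,
            human_residue,
            column,
            variant.wt,
        )
    supporting = tuple(
        sid
        for sid, res in residues.items()
        if sid != aln.human_id and res == variant.mut
    )
    if aln.n_rows == 1:
        logger.warning(
            "%s: alignment has no non-human rows; %s called noCPD by default",
            variant.gene,
            variant.key,
        )
    return CompensationCall(
        variant=variant,
        is_cpd=bool(supporting),
        supporting_species=supporting,
        column=column,
        human_residue_check=check,
    )


def classify_dataset(
    variants: pd.DataFrame,
    alignments: Mapping[str, OrthologAlignment],
) -> list[CompensationCall]:
    """Call CPD status for every row of a variant table, order-preserving.

    Raises :class:`ConfigurationError` naming the first gene that lacks an
    alignment. Logs summary counts (CPD / noCPD / flagged wt mismatches).
    """
    missing = sorted(set(variants["gene"]) - set(alignments)) if len(variants) else []
    if missing:
        raise ConfigurationError(f"no alignment provided for gene {missing[0]!r}")
    calls: list[CompensationCall] = []
    for row in variants.itertuples(index=False):
        variant = MissenseVariant(
            row.gene, row.wt, row.pos, row.mut,
            getattr(row, "severity", "unknown"),
            getattr(row, "pathogenicity", "unknown"),
        )
        calls.append(classify_variant(variant, alignments[row.gene]))
    n_cpd = sum(c.is_cpd for c in calls)
    n_flagged = sum(c.human_residue_check == "mismatch" for c in calls)
    logger.info(
        "classified %d variants: %d CPD, %d noCPD, %d flagged wt mismatches",
        len(calls),
        n_cpd,
        len(calls) - n_cpd,
        n_flagged,
    )
    return calls


def calls_to_frame(calls: Sequence[CompensationCall]) -> pd.DataFrame:
    """Tabulate calls for output; columns are reported 1-based."""
    return pd.DataFrame(
        {
            "gene": [c.variant.gene for c in calls],
            "wt": [c.variant.wt for c in calls],
            "pos": [c.variant.pos for c in calls],
            "mut": [c.variant.mut for c in calls],
            "severity": [c.variant.severity for c in calls],
            "is_cpd": [c.is_cpd for c in calls],
            "supporting_species": [",".join(c.supporting_species) for c in calls],
            "column_1based": [c.column + 1 for c in calls],
            "wt_check": [c.human_residue_check for c in calls],
        }
    )


@dataclass(frozen=True)
class SeverityContingency:
    """2x2 counts: rows (CPD, noCPD) x columns (mild, severe)."""

    table: np.ndarray

    def __post_init__(self) -> None:
        table = np.asarray(self.table, dtype=int)
        assert table.shape == (2, 2) and (table >= 0).all()
        object.__setattr__(self, "table", table)

    def row(self, group: str) -> tuple[int, int]:
        """(mild, severe) counts for group 'CPD' or 'noCPD'."""
        index = {"CPD": 0, "noCPD": 1}[group]
        return tuple(int(v) for v in self.table[index])


def severity_contingency(
    calls: Iterable[CompensationCall],
    *,
    include_wt_mismatches: bool = False,
) -> SeverityContingency:
    """Cross-tabulate CPD status against binary severity.

    Calls with unknown severity are excluded (logged); calls flagged with a
    wild-type mismatch are excluded unless ``include_wt_mismatches``.
    """
    table = np.zeros((2, 2), dtype=int)
    n_unknown = n_flagged = 0
    for call in calls:
        if call.human_residue_check == "mismatch" and not include_wt_mismatches:
            n_flagged += 1
            continue
        if call.variant.severity not in ("mild", "severe"):
            n_unknown += 1
            continue
        i = 0 if call.is_cpd else 1
        j = 0 if call.variant.severity == "mild" else 1
        table[i, j] += 1
    if n_unknown:
        logger.warning(
            "%d calls with unknown severity excluded from contingency", n_unknown
        )
    if n_flagged:
        logger.info("%d wt-mismatch calls excluded from contingency", n_flagged)
    if table.sum() == 0:
        logger.warning("severity contingency is empty")
    return SeverityContingency(table=table)


def severe_fraction(counts: SeverityContingency, group: str) -> int:
    """Percent of a group's calls that are severe, half-up rounded.

    Raises :class:`UndefinedStatisticError` for an empty group.
    """
    mild, severe = counts.row(group)
    total = mild + severe
    if total == 0:
        raise UndefinedStatisticError(f"group {group!r} has no retained calls")
    return int(math.floor(100 * severe / total + 0.5))
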