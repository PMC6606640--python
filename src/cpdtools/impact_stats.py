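"""Molecular-impact properties and the statistical comparisons built on them.

Each variant call carries up to four impact measures: FoldX-style stability
change (ddg, kcal/mol, destabilising positive) and relative solvent
accessibility (rsa, percent) joined from precomputed tables, plus the
BLOSUM62 element and the Shannon entropy of the variant's MSA column,
computed internally.

Two tests are provided. ``fisher_exact_2x2`` is the two-sided exact test on
a 2x2 table: the p-value sums hypergeometric point probabilities, over all
tables with the observed margins, that do not exceed the observed table's
probability (with a 1e-7 relative slack on the comparison, so exact ties are
always included despite floating-point rounding). ``moods_median_test``
dichotomises two samples at their pooled grand median — ties with the median
count as "<= median" — and tests the resulting 2x2, by default with the
exact test so that small samples are handled honestly; a Pearson chi-square
backend (no continuity correction) is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, chi2

from .cpd_classifier import CompensationCall
from .errors import InsufficientDataError, ValidationError
from .io_formats import blosum62
from .msa_analysis import (
    OrthologAlignment,
    column_profile,
    map_position_to_column,
    shannon_entropy,
)

logger = logging.getLogger(__name__)

IMPACT_PROPERTIES = ("ddg", "rsa", "blosum", "entropy")

#: Relative slack when comparing hypergeometric point probabilities.
_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class TestResult:
    """Outcome of one statistical comparison."""

    method: str  # "fisher_exact" | "moods_median"
    statistic: float | None
    p_value: float
    group_sizes: tuple[int, int]
    medians: tuple[float, float] | None = None
    note: str = ""

    def __post_init__(self) -> None:
        assert 0.0 <= self.p_value <= 1.0


def fisher_exact_2x2(table: Sequence[Sequence[float]]) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 contingency table.

    The statistic is the sample odds ratio (inf when the denominator
    vanishes). Degenerate margins (an empty row or column) return p = 1 with
    a warning; negative counts raise :class:`ValidationError`.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValidationError("contingency counts must be non-negative")
    if not np.allclose(t, np.round(t)):
        raise ValidationError("contingency counts must be integers")
    a, b, c, d = (int(v) for v in np.round(t).ravel())
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    n = row1 + row2
    odds = (a * d / (b * c)) if b * c > 0 else float("inf")
    if 0 in (row1, row2, col1, col2):
        logger.warning("degenerate 2x2 margins %s; returning p = 1", [t.tolist()])
        return TestResult("fisher_exact", odds, 1.0, (row1, row2))
    support = np.arange(max(0, col1 - row2), min(row1, col1) + 1)
    pmf = hypergeom.pmf(support, n, row1, col1)
    p_obs = float(pmf[a - support[0]])
    p = float(pmf[pmf <= p_obs * (1 + _TIE_RTOL)].sum())
    return TestResult("fisher_exact", odds, min(max(p, 0.0), 1.0), (row1, row2))


def moods_median_test(
    x: Sequence[float],
    y: Sequence[float],
    *,
    backend: str = "exact",
) -> TestResult:
    """Mood's median test between two samples.

    Counts per group how many observations exceed the pooled grand median
    (values equal to the median count as "<= median") and tests the 2x2
    table with :func:`fisher_exact_2x2` (``backend="exact"``, default) or a
    Pearson chi-square without continuity correction (``backend="chi2"``).
    Reports both group medians. When every pooled value is identical no
    dichotomy exists and p = 1 is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise InsufficientDataError("both samples must be non-empty")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValidationError("samples must not contain NaN")
    medians = (float(np.median(x)), float(np.median(y)))
    pooled = np.concatenate([x, y])
    grand = float(np.median(pooled))
    above = (int((x > grand).sum()), int((y > grand).sum()))
    table = np.array(
        [[above[0], x.size - above[0]], [above[1], y.size - above[1]]]
    )
    note = f"grand median {grand:g}; ties counted as <= median"
    if (pooled == pooled[0]).all():
        logger.warning("all pooled values identical; Mood's test undefined, p = 1")
        return TestResult(
            "moods_median", None, 1.0, (x.size, y.size), medians,
            note + "; degenerate (constant data)",
        )
    if backend == "exact":
        inner = fisher_exact_2x2(table)
        return TestResult(
            "moods_median", inner.statistic, inner.p_value,
            (x.size, y.size), medians, note + "; exact backend",
        )
    if backend == "chi2":
        expected = table.sum(axis=1, keepdims=True) * table.sum(axis=0) / table.sum()
        if (expected == 0).any():
            logger.warning("degenerate dichotomy; returning p = 1")
            return TestResult(
                "moods_median", None, 1.0, (x.size, y.size), medians,
                note + "; degenerate margins",
            )
        stat = float(((table - expected) ** 2 / expected).sum())
        p = float(chi2.sf(stat, df=1))
        return TestResult(
            "moods_median", stat, min(max(p, 0.0), 1.0),
            (x.size, y.size), medians, note + "; chi2 backend",
        )
    raise ValueError(f"unknown backend {backend!r}")


def build_impact_table(
    calls: Sequence[CompensationCall],
    props: pd.DataFrame | None,
    alignments: Mapping[str, OrthologAlignment],
) -> pd.DataFrame:
    """Attach the four molecular-impact values to each call.

    BLOSUM62 and column entropy are computed internally from the call and
    its gene's alignment; ddg and rsa are joined from ``props`` (keyed by
    gene, wt, pos, mut) and left missing — excluded pairwise from downstream
    tests — where no row matches.
    """
    records = []
    for call in calls:
        v = call.variant
        aln = alignments[v.gene]
        entropy = shannon_entropy(
            column_profile(aln, map_position_to_column(aln, v.pos))
        )
        records.append(
            {
                "gene": v.gene,
                "wt": v.wt,
                "pos": v.pos,
                "mut": v.mut,
                "severity": v.severity,
                "is_cpd": call.is_cpd,
                "wt_check": call.human_residue_check,
                "blosum": blosum62(v.wt, v.mut),
                "entropy": entropy,
            }
        )
    out = pd.DataFrame(
        records,
        columns=[
            "gene", "wt", "pos", "mut", "severity", "is_cpd", "wt_check",
            "blosum", "entropy",
        ],
    )
    if props is not None and len(out):
        joined = out.merge(
            props[["gene", "wt", "pos", "mut", "ddg", "rsa"]],
            on=["gene", "wt", "pos", "mut"],
            how="left",
            validate="many_to_one",
        )
        out["ddg"] = pd.to_numeric(joined["ddg"], errors="coerce")
        out["rsa"] = pd.to_numeric(joined["rsa"], errors="coerce")
        for col in ("ddg", "rsa"):
            n_missing = int(out[col].isna().sum())
            if n_missing:
                logger.info("%d calls without %s after property join", n_missing, col)
    else:
        out["ddg"] = np.nan
        out["rsa"] = np.nan
    return out


def _two_group_test(
    records: pd.DataFrame,
    mask_a: pd.Series,
    mask_b: pd.Series,
    prop: str,
    labels: tuple[str, str],
    backend: str,
) -> TestResult:
    if prop not in IMPACT_PROPERTIES:
        raise ValueError(f"unknown property {prop!r}")
    values = pd.to_numeric(records[prop], errors="coerce")
    a = values[mask_a].dropna().to_numpy()
    b = values[mask_b].dropna().to_numpy()
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError(
            f"need >= 2 {prop} values per group, got "
            f"{labels[0]}: {a.size}, {labels[1]}: {b.size}"
        )
    result = moods_median_test(a, b, backend=backend)
    logger.info(
        "%s %s vs %s: n=%s medians=%s p=%.3g",
        prop, labels[0], labels[1], result.group_sizes, result.medians,
        result.p_value,
    )
    return result


def compare_cpd_vs_nocpd(
    records: pd.DataFrame, prop: str, *, backend: str = "exact",
    include_wt_mismatches: bool = False,
) -> TestResult:
    """Mood's median test of one impact property, CPD vs noCPD.

    Group order in the result is (CPD, noCPD). Missing values are removed
    per property; a group reduced below 2 observations raises
    :class:`InsufficientDataError`.
    """
    kept = records if include_wt_mismatches else records[records["wt_check"] == "match"]
    return _two_group_test(
        kept, kept["is_cpd"], ~kept["is_cpd"], prop, ("CPD", "noCPD"), backend
    )


def compare_mild_vs_severe(
    records: pd.DataFrame, prop: str, *, backend: str = "exact",
    include_wt_mismatches: bool = False,
) -> TestResult:
    """Mood's median test of one impact property among CPDs, mild vs severe."""
    kept = records[records["is_cpd"]]
    if not include_wt_mismatches:
        kept = kept[kept["wt_check"] == "match"]
    return _two_group_test(
        kept,
        kept["severity"] == "mild",
        kept["severity"] == "severe",
        prop,
        ("mild", "severe"),
        backend,
    )


def overlap_fraction(a: Sequence[float], b: Sequence[float]) -> float:
    """Percentage of sample ``b`` lying strictly below the median of ``a``.

    Quantifies distribution overlap: for continuous data, a == b gives ~50%.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise InsufficientDataError("both samples must be non-empty")
    return float(100.0 * (b < np.median(a)).mean())
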