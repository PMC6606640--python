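"""Readers and writers for the external formats the pipeline touches.

Formats: aligned FASTA (ortholog MSAs, via biopython), tab-separated variant
and per-variant property tables, per-individual genotype tables (long TSV or
a minimal VCF dialect read through pysam). Also houses the embedded BLOSUM62
substitution matrix.

All TSVs are UTF-8, tab-delimited, carry a header line, and may contain
``#`` comment lines. Positions are 1-based indices into the human protein
sequence as provided; no renumbering to legacy/mature-chain coordinates is
attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import AlignIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Align import MultipleSeqAlignment

from .errors import FormatError, ValidationError
from .msa_analysis import AMINO_ACID_SET, OrthologAlignment

logger = logging.getLogger(__name__)

SEVERITIES = ("mild", "severe", "unknown")
PATHOGENICITIES = ("pathogenic", "neutral", "unknown")
SUPERPOPULATIONS = ("AFR", "AMR", "EAS", "EUR", "SAS", "other")

# BLOSUM62 (Henikoff & Henikoff), canonical 20x20 block in half-bit units.
_BLOSUM62_ORDER = "ARNDCQEGHILKMFPSTWYV"
_BLOSUM62_ROWS = """
  4  -1  -2  -2   0  -1  -1   0  -2  -1  -1  -1  -1  -2  -1   1   0  -3  -2   0
 -1   5   0  -2  -3   1   0  -2   0  -3  -2   2  -1  -3  -2  -1  -1  -3  -2  -3
 -2   0   6   1  -3   0   0   0   1  -3  -3   0  -2  -3  -2   1   0  -4  -2  -3
 -2  -2   1   6  -3   0   2  -1  -1  -3  -4  -1  -3  -3  -1   0  -1  -4  -3  -3
  0  -3  -3  -3   9  -3  -4  -3  -3  -1  -1  -3  -1  -2  -3  -1  -1  -2  -2  -1
 -1   1   0   0  -3   5   2  -2   0  -3  -2   1   0  -3  -1   0  -1  -2  -1  -2
 -1   0   0   2  -4   2   5  -2   0  -3  -3   1  -2  -3  -1   0  -1  -3  -2  -2
  0  -2   0  -1  -3  -2  -2   6  -2  -4  -4  -2  -3  -3  -2   0  -2  -2  -3  -3
 -2   0   1  -1  -3   0   0  -2   8  -3  -3  -1  -2  -1  -2  -1  -2  -2   2  -3
 -1  -3  -3  -3  -1  -3  -3  -4  -3   4   2  -3   1   0  -3  -2  -1  -3  -1   3
 -1  -2  -3  -4  -1  -2  -3  -4  -3   2   4  -2   2   0  -3  -2  -1  -2  -1   1
 -1   2   0  -1  -3   1   1  -2  -1  -3  -2   5  -1  -3  -1   0  -1  -3  -2  -2
 -1  -1  -2  -3  -1   0  -2  -3  -2   1   2  -1   5   0  -2  -1  -1  -1  -1   1
 -2  -3  -3  -3  -2  -3  -3  -3  -1   0   0  -3   0   6  -4  -2  -2   1   3  -1
 -1  -2  -2  -1  -3  -1  -1  -2  -2  -3  -3  -1  -2  -4   7  -1  -1  -4  -3  -2
  1  -1   1   0  -1   0   0   0  -1  -2  -2   0  -1  -2  -1   4   1  -3  -2  -2
  0  -1   0  -1  -1  -1  -1  -2  -2  -1  -1  -1  -1  -2  -1   1   5  -2  -2   0
 -3  -3  -4  -4  -2  -2  -3  -2  -2  -3  -2  -3  -1   1  -4  -3  -2  11   2  -3
 -2  -2  -2  -3  -2  -1  -2  -3   2  -1  -1  -2  -1   3  -3  -2  -2   2   7  -1
  0  -3  -3  -3  -1  -2  -2  -3  -3   3   1  -2   1  -1  -2  -2   0  -3  -1   4
"""

BLOSUM62: dict[tuple[str, str], int] = {
    (a, b): int(v)
    for a, row in zip(_BLOSUM62_ORDER, _BLOSUM62_ROWS.strip().splitlines())
    for b, v in zip(_BLOSUM62_ORDER, row.split())
}


def blosum62(wt: str, mut: str) -> int:
    """Published BLOSUM62 score for an amino-acid pair (symmetric).

    Raises :class:`KeyError` for non-canonical letters.
    """
    wt, mut = wt.upper(), mut.upper()
    if wt not in AMINO_ACID_SET:
        raise KeyError(f"non-canonical amino acid {wt!r}")
    if mut not in AMINO_ACID_SET:
        raise KeyError(f"non-canonical amino acid {mut!r}")
    return BLOSUM62[(wt, mut)]


@dataclass(frozen=True)
class MissenseVariant:
    """One amino-acid substitution in a human protein."""

    gene: str
    wt: str
    pos: int
    mut: str
    severity: str = "unknown"
    pathogenicity: str = "unknown"

    def __post_init__(self) -> None:
        object.__setattr__(self, "wt", self.wt.upper())
        object.__setattr__(self, "mut", self.mut.upper())
        if self.wt not in AMINO_ACID_SET or self.mut not in AMINO_ACID_SET:
            raise ValidationError(
                f"non-canonical residue in {self.gene} {self.wt}{self.pos}"
                f"{self.mut}"
            )
        if self.wt == self.mut:
            raise ValidationError(
                f"synonymous record {self.gene} {self.wt}{self.pos}{self.mut}"
            )
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        if self.severity not in SEVERITIES:
            raise ValidationError(f"bad severity {self.severity!r}")
        if self.pathogenicity not in PATHOGENICITIES:
            raise ValidationError(f"bad pathogenicity {self.pathogenicity!r}")

    @property
    def key(self) -> str:
        """Compact ``wt+pos+mut`` key, e.g. ``L69V``."""
        return f"{self.wt}{self.pos}{self.mut}"


def normalize_severity(label: object) -> str:
    """Map a free-text severity label to mild/severe/unknown.

    Case-insensitive and whitespace-stripped; any label other than
    mild/severe (e.g. "moderate") maps to unknown with a warning, keeping
    mild-vs-severe analyses strictly binary.
    """
    if label is None or (isinstance(label, float) and pd.isna(label)):
        return "unknown"
    text = str(label).strip().lower()
    if text in ("", "na", "nan", "none", "unknown", "?"):
        return "unknown"
    if text in ("mild", "severe"):
        return text
    logger.warning("unrecognised severity label %r mapped to 'unknown'", label)
    return "unknown"


def normalize_pathogenicity(label: object) -> str:
    if label is None or (isinstance(label, float) and pd.isna(label)):
        return "unknown"
    text = str(label).strip().lower()
    if text in ("pathogenic", "neutral"):
        return text
    if text in ("", "na", "nan", "none", "unknown", "?"):
        return "unknown"
    logger.warning(
        "unrecognised pathogenicity label %r mapped to 'unknown'", label
    )
    return "unknown"


# ---------------------------------------------------------------------------
# MSA FASTA

def read_msa_fasta(path: str | Path, human_id: str) -> OrthologAlignment:
    """Read an aligned FASTA file, flagging ``human_id`` as the human row.

    Input order is preserved. Unequal record lengths raise
    :class:`FormatError`; a missing/ambiguous ``human_id`` raises
    :class:`KeyError`.
    """
    try:
        msa = AlignIO.read(str(path), "fasta")
    except ValueError as exc:  # biopython signals ragged records this way
        raise FormatError(f"{path}: not a well-formed aligned FASTA: {exc}") from exc
    rows = tuple((rec.id, str(rec.seq)) for rec in msa)
    matches = [i for i, (sid, _) in enumerate(rows) if sid == human_id]
    if len(matches) != 1:
        raise KeyError(
            f"{path}: human id {human_id!r} matched {len(matches)} records"
        )
    return OrthologAlignment(rows=rows, human_index=matches[0])


def write_msa_fasta(aln: OrthologAlignment, path: str | Path) -> None:
    """Write an alignment back to FASTA (one line per sequence)."""
    msa = MultipleSeqAlignment(
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in aln.rows
    )
    with open(path, "w") as handle:
        for rec in msa:
            handle.write(f">{rec.id}\n{rec.seq}\n")


# ---------------------------------------------------------------------------
# Variant and property tables

VARIANT_COLUMNS = ("gene", "wt", "pos", "mut", "severity", "pathogenicity")


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Read a missense variant TSV into a validated DataFrame.

    Required columns: gene, wt, pos, mut. Optional: severity, pathogenicity,
    curated, ddg, rsa (numeric columns are passed through). Severity and
    pathogenicity labels are normalised; residue letters are upper-cased and
    validated (wt == mut or non-canonical letters raise
    :class:`ValidationError`).
    """
    df = _read_tsv(path)
    missing = [c for c in ("gene", "wt", "pos", "mut") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    out = pd.DataFrame(
        {
            "gene": df["gene"].str.strip(),
            "wt": df["wt"].str.strip().str.upper(),
            "pos": pd.to_numeric(df["pos"], errors="raise").astype(int),
            "mut": df["mut"].str.strip().str.upper(),
        }
    )
    out["severity"] = (
        df["severity"].map(normalize_severity)
        if "severity" in df.columns
        else "unknown"
    )
    out["pathogenicity"] = (
        df["pathogenicity"].map(normalize_pathogenicity)
        if "pathogenicity" in df.columns
        else "unknown"
    )
    if "curated" in df.columns:
        out["curated"] = (
            df["curated"].str.strip().str.lower().isin(("1", "true", "yes", "y"))
        )
    for col in ("ddg", "rsa"):
        if col in df.columns:
            out[col] = pd.to_numeric(df[col], errors="coerce")
    # row-level invariants, reported with the offending variant spelled out
    for row in out.itertuples(index=False):
        MissenseVariant(
            row.gene, row.wt, row.pos, row.mut, row.severity, row.pathogenicity
        )
    return out


def write_variant_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_property_table(path: str | Path) -> pd.DataFrame:
    """Read a per-variant molecular-property TSV (ddg, rsa).

    Keyed by (gene, wt, pos, mut); duplicate keys raise
    :class:`ValidationError`. ddg is a stability change in kcal/mol
    (destabilising positive); rsa a relative solvent accessibility in percent.
    """
    df = _read_tsv(path)
    missing = [c for c in ("gene", "wt", "pos", "mut") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    out = pd.DataFrame(
        {
            "gene": df["gene"].str.strip(),
            "wt": df["wt"].str.strip().str.upper(),
            "pos": pd.to_numeric(df["pos"], errors="raise").astype(int),
            "mut": df["mut"].str.strip().str.upper(),
        }
    )
    for col in ("ddg", "rsa"):
        out[col] = (
            pd.to_numeric(df[col], errors="coerce") if col in df.columns else pd.NA
        )
    dup = out.duplicated(subset=["gene", "wt", "pos", "mut"])
    if dup.any():
        keys = out.loc[dup, ["gene", "wt", "pos", "mut"]].iloc[0].tolist()
        raise ValidationError(f"{path}: duplicate property key {keys}")
    bad_rsa = out["rsa"].dropna()
    if ((bad_rsa < 0) | (bad_rsa > 100)).any():
        raise ValidationError(f"{path}: rsa outside [0, 100]")
    return out


# ---------------------------------------------------------------------------
# Genotype tables

GENOTYPE_COLUMNS = (
    "individual_id",
    "superpopulation",
    "gene",
    "variant_key",
    "pathogenicity",
)


def _finalize_genotypes(df: pd.DataFrame, source: str) -> pd.DataFrame:
    df = df.copy()
    df["superpopulation"] = df["superpopulation"].where(
        df["superpopulation"].isin(SUPERPOPULATIONS), "other"
    )
    df["pathogenicity"] = df["pathogenicity"].map(normalize_pathogenicity)
    before = len(df)
    df = df.drop_duplicates(
        subset=["individual_id", "gene", "variant_key"], ignore_index=True
    )
    if len(df) < before:
        logger.warning(
            "%s: collapsed %d duplicate (individual, gene, variant) rows",
            source,
            before - len(df),
        )
    return df[list(GENOTYPE_COLUMNS)]


def read_genotypes(
    path: str | Path,
    dialect: str = "long_tsv",
    *,
    gene_tag: str = "GENE",
    consequence_tag: str = "CSQ",
    populations: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read per-individual missense genotypes as a long-format table.

    ``dialect="long_tsv"`` expects columns individual_id, gene, variant_key
    and optionally superpopulation, pathogenicity. ``dialect="vcf"`` reads a
    minimal VCF 4.x with per-sample GT fields; the INFO tags named by
    ``gene_tag`` and ``consequence_tag`` supply the gene symbol and the
    variant consequence (only ``missense``-annotated records are ingested);
    ``populations`` optionally maps sample ids to superpopulation labels.

    One output row per (individual, gene, variant) with any non-reference
    genotype; duplicates are collapsed with a warning.
    """
    if dialect == "long_tsv":
        df = _read_tsv(path)
        missing = [
            c for c in ("individual_id", "gene", "variant_key") if c not in df.columns
        ]
        if missing:
            raise FormatError(f"{path}: missing required columns {missing}")
        if "superpopulation" not in df.columns:
            df["superpopulation"] = "other"
        if "pathogenicity" not in df.columns:
            df["pathogenicity"] = "unknown"
        return _finalize_genotypes(df, str(path))
    if dialect == "vcf":
        return _read_genotypes_vcf(
            path, gene_tag=gene_tag, consequence_tag=consequence_tag,
            populations=populations,
        )
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_genotypes_vcf(
    path: str | Path,
    *,
    gene_tag: str,
    consequence_tag: str,
    populations: Mapping[str, str] | None,
) -> pd.DataFrame:
    import pysam

    populations = populations or {}
    rows: list[dict[str, object]] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = dict(rec.info)
            if gene_tag not in info:
                raise FormatError(
                    f"{path}: record at {rec.chrom}:{rec.pos} lacks INFO tag "
                    f"{gene_tag!r}"
                )
            csq = info.get(consequence_tag, "")
            if isinstance(csq, tuple):
                csq = ",".join(str(c) for c in csq)
            if "missense" not in str(csq).lower():
                continue
            gene = info[gene_tag]
            if isinstance(gene, tuple):
                gene = gene[0]
            variant_key = str(info.get("AAKEY", rec.id or f"{rec.chrom}:{rec.pos}"))
            pathogenicity = str(info.get("PATHO", "unknown"))
            for sample, call in rec.samples.items():
                alleles = call.get("GT") or ()
                if any(a not in (None, 0) for a in alleles):
                    rows.append(
                        {
                            "individual_id": sample,
                            "superpopulation": populations.get(sample, "other"),
                            "gene": str(gene),
                            "variant_key": variant_key,
                            "pathogenicity": pathogenicity,
                        }
                    )
    df = pd.DataFrame(rows, columns=list(GENOTYPE_COLUMNS))
    return _finalize_genotypes(df, str(path))


def write_genotypes(df: pd.DataFrame, path: str | Path) -> None:
    df[list(GENOTYPE_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_gene_panel(path: str | Path) -> list[str]:
    """Read a gene panel file: one symbol per line, '#' comments allowed."""
    genes: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return genes
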