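"""Per-individual mutational burden over a hemostasis gene panel.

The genetic background of a focal coagulation-factor variant is the set of
other missense variants its carrier holds across the hemostasis panel.
This module reproduces the population-level accounting: per-individual
variant and mutated-protein counts, per-gene prevalence, pathogenic/neutral
composition, cis/trans labelling, and per-focal-variant background ranges
across carriers.

Zygosity is ignored throughout: any non-reference genotype counts once per
(individual, variant), which for an all-male cohort makes X-linked genes
effectively hemizygous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError
from .io_formats import SUPERPOPULATIONS

logger = logging.getLogger(__name__)

#: Default 19-gene hemostasis panel (synthetic stand-in roster: the named
#: high/low-prevalence genes plus canonical coagulation-cascade members).
DEFAULT_PANEL_GENES = (
    "F8", "F9", "VWF", "F12", "KNG1", "GP1BB", "F2", "F5", "F7", "F10",
    "F11", "F13A1", "FGA", "FGB", "FGG", "SERPINC1", "PROC", "PROS1",
    "GP1BA",
)


@dataclass(frozen=True)
class GenePanel:
    """Ordered gene roster with a subset of focal (disease) genes."""

    genes: tuple[str, ...] = DEFAULT_PANEL_GENES
    focal_genes: tuple[str, ...] = ("F8", "F9")

    def __post_init__(self) -> None:
        genes = tuple(g.upper() for g in self.genes)
        focal = tuple(g.upper() for g in self.focal_genes)
        if len(set(genes)) != len(genes):
            raise ValidationError("panel gene symbols must be unique")
        if not set(focal) <= set(genes):
            raise ValidationError("focal genes must be a subset of the panel")
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "focal_genes", focal)


BURDEN_COLUMNS = (
    "individual_id",
    "superpopulation",
    "n_variants_total",
    "n_variants_excl_focal",
    "n_mutated_proteins",
    "n_pathogenic",
    "n_neutral",
    "n_unknown",
)


def _panel_genotypes(genotypes: pd.DataFrame, panel: GenePanel) -> pd.DataFrame:
    df = genotypes.copy()
    df["gene"] = df["gene"].str.upper()
    outside = ~df["gene"].isin(panel.genes)
    if outside.any():
        logger.warning(
            "dropping %d genotype rows for genes outside the panel: %s",
            int(outside.sum()),
            sorted(df.loc[outside, "gene"].unique()),
        )
        df = df[~outside]
    return df


def individual_burdens(
    genotypes: pd.DataFrame, panel: GenePanel = GenePanel()
) -> pd.DataFrame:
    """Per-individual variant counts and pathogenic/neutral composition.

    One row per individual present in the genotype table (no zero-filling
    for absent individuals). ``n_variants_excl_focal`` omits variants in the
    panel's focal genes; ``n_mutated_proteins`` counts genes with >= 1
    variant.
    """
    df = _panel_genotypes(genotypes, panel)
    if df.empty:
        return pd.DataFrame(columns=list(BURDEN_COLUMNS))
    grouped = df.groupby("individual_id", sort=True)
    out = pd.DataFrame(
        {
            "individual_id": grouped.size().index,
            "superpopulation": grouped["superpopulation"].first().to_numpy(),
            "n_variants_total": grouped.size().to_numpy(),
            "n_variants_excl_focal": grouped["gene"]
            .apply(lambda g: int((~g.isin(panel.focal_genes)).sum()))
            .to_numpy(),
            "n_mutated_proteins": grouped["gene"].nunique().to_numpy(),
            "n_pathogenic": grouped["pathogenicity"]
            .apply(lambda p: int((p == "pathogenic").sum()))
            .to_numpy(),
            "n_neutral": grouped["pathogenicity"]
            .apply(lambda p: int((p == "neutral").sum()))
            .to_numpy(),
            "n_unknown": grouped["pathogenicity"]
            .apply(lambda p: int((~p.isin(["pathogenic", "neutral"])).sum()))
            .to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def gene_mutation_prevalence(
    genotypes: pd.DataFrame, panel: GenePanel = GenePanel()
) -> pd.Series:
    """Number of individuals with >= 1 variant in each panel gene (zero-filled)."""
    df = _panel_genotypes(genotypes, panel)
    counts = df.groupby("gene")["individual_id"].nunique()
    return counts.reindex(panel.genes, fill_value=0).rename("n_individuals")


def cis_trans_label(background_variant_gene: str, focal_gene: str) -> str:
    """"cis" when the background variant lies in the focal gene itself,
    "trans" otherwise (case-insensitive symbol comparison)."""
    return (
        "cis"
        if background_variant_gene.upper() == focal_gene.upper()
        else "trans"
    )


RANGE_COLUMNS = (
    "gene",
    "variant_key",
    "n_carriers",
    "multi_carrier",
    "min_background",
    "max_background",
    "min_background_pathogenic",
    "max_background_pathogenic",
)


def variant_background_ranges(
    genotypes: pd.DataFrame,
    panel: GenePanel = GenePanel(),
    focal_genes: tuple[str, ...] | None = None,
    *,
    pathogenic_only: bool = False,
) -> pd.DataFrame:
    """Background-size range across carriers of each focal-gene variant.

    For each variant of a focal gene carried by >= 1 individual, a carrier's
    background is the number of panel variants that carrier holds besides
    the focal variant itself (other same-gene, i.e. cis, variants included).
    Both the all-variant and the pathogenic-only background counts are
    reported; ``pathogenic_only=True`` restricts the output to focal
    variants themselves annotated pathogenic. Variants with >= 2 carriers
    are flagged ``multi_carrier``.
    """
    focal = tuple(
        g.upper() for g in (focal_genes if focal_genes else panel.focal_genes)
    )
    df = _panel_genotypes(genotypes, panel)
    rows = []
    per_ind_total = df.groupby("individual_id").size()
    per_ind_patho = (
        df[df["pathogenicity"] == "pathogenic"].groupby("individual_id").size()
    )
    focal_df = df[df["gene"].isin(focal)]
    if pathogenic_only:
        focal_df = focal_df[focal_df["pathogenicity"] == "pathogenic"]
    for (gene, key), carriers in focal_df.groupby(["gene", "variant_key"]):
        ids = carriers["individual_id"]
        is_patho = (carriers["pathogenicity"] == "pathogenic").to_numpy()
        bg_all = (per_ind_total.reindex(ids).fillna(0).to_numpy() - 1).astype(int)
        bg_patho = (
            per_ind_patho.reindex(ids).fillna(0).to_numpy() - is_patho
        ).astype(int)
        rows.append(
            {
                "gene": gene,
                "variant_key": key,
                "n_carriers": len(ids),
                "multi_carrier": len(ids) >= 2,
                "min_background": int(bg_all.min()),
                "max_background": int(bg_all.max()),
                "min_background_pathogenic": int(bg_patho.min()),
                "max_background_pathogenic": int(bg_patho.max()),
            }
        )
    out = pd.DataFrame(rows, columns=list(RANGE_COLUMNS))
    return out.sort_values(["gene", "variant_key"], ignore_index=True)


@dataclass(frozen=True)
class CompositionSummary:
    """Observed (n_neutral, n_pathogenic) combinations and their prevalence."""

    table: pd.DataFrame
    pathogenic_carrier_fraction: float


def pathogenic_composition_summary(
    burdens: pd.DataFrame, *, strict: bool = False
) -> CompositionSummary:
    """Tabulate neutral/pathogenic variant-count combinations per individual.

    By default, unknown-pathogenicity variants count as neutral (absence of
    a pathogenicity annotation is read as "not annotated pathogenic");
    ``strict=True`` keeps them out of both counts. One row per observed
    (n_neutral, n_pathogenic) pair with its multiplicity and superpopulation
    shares (summing to 1 per row); also reports the fraction of individuals
    carrying >= 1 pathogenic variant.
    """
    if burdens.empty:
        empty = pd.DataFrame(
            columns=["n_neutral", "n_pathogenic", "n_individuals"]
            + [f"frac_{p}" for p in SUPERPOPULATIONS]
        )
        return CompositionSummary(table=empty, pathogenic_carrier_fraction=float("nan"))
    df = burdens.copy()
    df["n_neutral_eff"] = df["n_neutral"] + (0 if strict else df["n_unknown"])
    rows = []
    for (n_neu, n_pat), group in df.groupby(["n_neutral_eff", "n_pathogenic"]):
        row = {
            "n_neutral": int(n_neu),
            "n_pathogenic": int(n_pat),
            "n_individuals": len(group),
        }
        shares = group["superpopulation"].value_counts(normalize=True)
        for pop in SUPERPOPULATIONS:
            row[f"frac_{pop}"] = float(shares.get(pop, 0.0))
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(
        ["n_neutral", "n_pathogenic"], ignore_index=True
    )
    fraction = float((df["n_pathogenic"] >= 1).mean())
    return CompositionSummary(table=table, pathogenic_carrier_fraction=fraction)
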