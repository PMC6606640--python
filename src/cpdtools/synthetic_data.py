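"""Synthetic inputs with recorded ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes:

* per-gene ortholog MSAs whose columns follow a target conservation
  (entropy) profile, with compensations planted at known variants — the
  mutant residue is written into at least one non-human row for true CPDs
  and guaranteed absent from non-human rows for true noCPDs;
* curated-style variant tables with severity drawn from a logistic model of
  the stability change, plus FoldX/NACCESS-style property tables with
  group-specific ddg (Gaussian) and rsa (uniform) distributions, the CPD
  group being configured milder than the noCPD group;
* a male population cohort over a 19-gene hemostasis panel with per-gene
  allele-frequency spectra (two near-ubiquitously mutated genes, two rare
  ones), five superpopulations, and per-variant pathogenicity flags.

Defaults mirror the FVIII study scale: 971 pathogenic variants of which
~122 compensated, and a cohort of 1233 individuals. Entropy targeting uses
a two-state mixture per site (one dominant residue with tunable frequency,
the rest uniform) and is therefore approximate by design.

Everything is driven by an integer seed through independent deterministic
substreams, so identical configurations yield byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .background_analysis import DEFAULT_PANEL_GENES, GenePanel
from .errors import ConfigurationError
from .io_formats import (
    write_genotypes,
    write_msa_fasta,
    write_variant_table,
)
from .msa_analysis import AMINO_ACIDS, MAX_ENTROPY, OrthologAlignment

logger = logging.getLogger(__name__)

_AA = np.array(list(AMINO_ACIDS))

# default per-gene allele-frequency spectra for the cohort generator;
# VWF/F12 nearly always mutated, KNG1/GP1BB rare, the rest intermediate
_DEFAULT_SPECTRUM: dict[str, tuple[float, ...]] = {
    "VWF": (0.80, 0.60, 0.40, 0.25, 0.10),
    "F12": (0.75, 0.55, 0.30),
    "KNG1": (0.004,),
    "GP1BB": (0.006,),
    "F8": (0.08, 0.03, 0.01),
    "F9": (0.05, 0.02),
}
_FALLBACK_SPECTRUM = (0.25, 0.08, 0.03)


def _default_spectrum() -> dict[str, tuple[float, ...]]:
    return {
        gene: _DEFAULT_SPECTRUM.get(gene, _FALLBACK_SPECTRUM)
        for gene in DEFAULT_PANEL_GENES
    }


@dataclass
class SimulationConfig:
    """All tunable knobs of the generator, with study-scale defaults."""

    seed: int = 0
    # --- MSA / variant structure ---
    genes: tuple[str, ...] = ("F8",)
    n_species: int = 25
    seq_length: int = 2351
    site_conservation_profile: tuple[float, ...] | None = None
    entropy_range: tuple[float, float] = (0.3, 3.0)
    insert_column_rate: float = 0.03
    ortholog_gap_rate: float = 0.01
    n_variants: int = 971
    cpd_fraction: float = 122 / 971
    max_support_species: int = 3
    # --- molecular properties / severity ---
    ddg_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"cpd": (0.8, 1.0), "nocpd": (1.8, 1.2)}
    )
    rsa_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"cpd": (15.0, 95.0), "nocpd": (0.0, 75.0)}
    )
    severity_slope: float = 0.9
    severity_intercept: float = -1.5
    # --- cohort ---
    cohort_size: int = 1233
    superpopulation_weights: dict[str, float] = field(
        default_factory=lambda: {
            "AFR": 0.27, "AMR": 0.14, "EAS": 0.20, "EUR": 0.19, "SAS": 0.20,
        }
    )
    gene_freq_spectrum: dict[str, tuple[float, ...]] = field(
        default_factory=_default_spectrum
    )
    pop_freq_multipliers: dict[str, float] | None = None
    pathogenic_prob: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.cpd_fraction <= 1.0:
            raise ConfigurationError("cpd_fraction must lie in [0, 1]")
        if self.cohort_size < 0:
            raise ConfigurationError("cohort_size must be >= 0")
        if self.n_species < 2:
            raise ConfigurationError("need >= 2 species (human + 1 ortholog)")
        if self.n_variants > self.seq_length:
            raise ConfigurationError(
                "n_variants exceeds seq_length (one variant per site)"
            )
        weights = sum(self.superpopulation_weights.values())
        if abs(weights - 1.0) > 1e-9:
            raise ConfigurationError("superpopulation weights must sum to 1")


@dataclass
class GroundTruth:
    """Planted parameters and labels, consistent with the emitted files."""

    variants: pd.DataFrame = field(default_factory=pd.DataFrame)
    cohort_variants: pd.DataFrame = field(default_factory=pd.DataFrame)
    target_entropy: dict[str, np.ndarray] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "variants": self.variants.to_dict(orient="records"),
            "cohort_variants": self.cohort_variants.to_dict(orient="records"),
            "target_entropy": {
                g: [round(float(v), 6) for v in arr]
                for g, arr in self.target_entropy.items()
            },
        }
        return json.dumps(payload, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _dominant_frequency(target_entropy: np.ndarray) -> np.ndarray:
    """Invert the two-state-mixture entropy for the dominant-residue
    frequency q: one residue at q, the other 19 sharing 1 - q equally."""
    qs = np.linspace(1.0 / 20.0, 1.0, 4096)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -qs * np.log2(qs) - (1 - qs) * np.log2((1 - qs) / 19.0)
    h[-1] = 0.0  # q = 1 exactly
    # h decreases in q on [1/20, 1]; np.interp needs ascending x
    return np.interp(target_entropy, h[::-1], qs[::-1])


def _other_residue(rng: np.random.Generator, avoid: np.ndarray) -> np.ndarray:
    """Uniform residues guaranteed different from ``avoid`` (index array)."""
    r = rng.integers(0, 19, size=avoid.shape)
    return np.where(r >= avoid, r + 1, r)


def gen_msa(
    config: SimulationConfig,
) -> tuple[dict[str, OrthologAlignment], GroundTruth]:
    """Generate per-gene ortholog alignments with planted compensations.

    Returns the alignments plus a :class:`GroundTruth` whose ``variants``
    frame carries gene, wt, pos (1-based, human ungapped), mut, ``true_cpd``
    and the number of supporting species planted. Positions are unique per
    gene, so each variant owns its column.
    """
    rng = _rng(config, 1)
    length = config.seq_length
    if config.site_conservation_profile is not None:
        profile = np.asarray(config.site_conservation_profile, dtype=float)
        if profile.shape != (length,):
            raise ConfigurationError(
                "site_conservation_profile length must equal seq_length"
            )
    else:
        profile = rng.uniform(*config.entropy_range, size=length)
    if (profile < 0).any() or (profile > MAX_ENTROPY + 1e-9).any():
        raise ConfigurationError(
            f"target entropies must lie in [0, {MAX_ENTROPY:.3f}]"
        )
    q = _dominant_frequency(profile)

    alignments: dict[str, OrthologAlignment] = {}
    truth_rows = []
    target_entropy: dict[str, np.ndarray] = {}
    n_orth = config.n_species - 1
    n_cpd = int(round(config.cpd_fraction * config.n_variants))
    for gene in config.genes:
        human = rng.integers(0, 20, size=length)
        # ortholog residues: dominant (human) residue with prob q, else
        # uniform over the remaining 19
        keep = rng.random((n_orth, length)) < q
        other = _other_residue(rng, np.broadcast_to(human, (n_orth, length)))
        matrix = np.where(keep, human, other)
        gapped = rng.random((n_orth, length)) < config.ortholog_gap_rate

        # variants: unique positions, mutant residue != wild-type
        positions = np.sort(rng.choice(length, size=config.n_variants, replace=False))
        muts = _other_residue(rng, human[positions])
        is_cpd = np.zeros(config.n_variants, dtype=bool)
        is_cpd[rng.permutation(config.n_variants)[:n_cpd]] = True

        n_support = np.zeros(config.n_variants, dtype=int)
        for i, (site, mut) in enumerate(zip(positions, muts)):
            if is_cpd[i]:
                k = int(rng.integers(1, config.max_support_species + 1))
                support = rng.choice(n_orth, size=min(k, n_orth), replace=False)
                matrix[support, site] = mut
                gapped[support, site] = False
                n_support[i] = len(support)
            else:
                clash = matrix[:, site] == mut
                matrix[clash, site] = human[site]  # scrub: wt != mut
        rows_res = _AA[matrix]
        rows_res[gapped] = "-"

        # insertion columns: human gap, orthologs half gap / half residue
        n_ins = int(round(config.insert_column_rate * length))
        ins_at = np.sort(rng.choice(length + 1, size=n_ins, replace=True))
        human_res = _AA[human]
        col_chunks_h, col_chunks_o = [], []
        prev = 0
        for j, cut in enumerate(list(ins_at) + [length + 1]):
            cut = min(cut, length)
            col_chunks_h.append(human_res[prev:cut])
            col_chunks_o.append(rows_res[:, prev:cut])
            if j < n_ins:
                col_chunks_h.append(np.array(["-"]))
                ins_res = _AA[rng.integers(0, 20, size=n_orth)]
                ins_res[rng.random(n_orth) < 0.5] = "-"
                col_chunks_o.append(ins_res[:, None])
            prev = cut
        human_row = "".join(np.concatenate(col_chunks_h))
        orth_rows = np.concatenate(col_chunks_o, axis=1)

        rows = [("HUMAN", human_row)]
        rows += [
            (f"SPECIES_{i + 1:02d}", "".join(orth_rows[i]))
            for i in range(n_orth)
        ]
        alignments[gene] = OrthologAlignment(rows=tuple(rows), human_index=0)
        target_entropy[gene] = profile.copy()
        for i in range(config.n_variants):
            truth_rows.append(
                {
                    "gene": gene,
                    "wt": str(_AA[human[positions[i]]]),
                    "pos": int(positions[i]) + 1,
                    "mut": str(_AA[muts[i]]),
                    "true_cpd": bool(is_cpd[i]),
                    "n_support": int(n_support[i]),
                }
            )
    truth = GroundTruth(
        variants=pd.DataFrame(truth_rows), target_entropy=target_entropy
    )
    logger.info(
        "generated %d alignments, %d variants (%d planted CPDs per gene)",
        len(alignments), len(truth.variants), n_cpd,
    )
    return alignments, truth


def gen_variant_and_property_tables(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw severity and molecular properties for the planted variants.

    ddg comes from the group-specific Gaussians in ``config.ddg_params``;
    severity from the logistic model P(severe) = expit(slope * ddg +
    intercept); rsa from the group-specific uniform ranges. The draws are
    recorded back into ``truth.variants``.
    """
    if truth.variants.empty:
        raise ConfigurationError("run gen_msa first: truth has no variants")
    rng = _rng(config, 2)
    df = truth.variants.copy()
    group = np.where(df["true_cpd"], "cpd", "nocpd")
    means = np.array([config.ddg_params[g][0] for g in group])
    sds = np.array([config.ddg_params[g][1] for g in group])
    ddg = rng.normal(means, sds)
    p_severe = 1.0 / (
        1.0 + np.exp(-(config.severity_slope * ddg + config.severity_intercept))
    )
    severity = np.where(rng.random(len(df)) < p_severe, "severe", "mild")
    lo = np.array([config.rsa_params[g][0] for g in group])
    hi = np.array([config.rsa_params[g][1] for g in group])
    rsa = rng.uniform(lo, hi)

    df["ddg"] = np.round(ddg, 4)
    df["rsa"] = np.round(rsa, 2)
    df["severity"] = severity
    df["p_severe"] = np.round(p_severe, 6)
    truth.variants = df

    variants = df[["gene", "wt", "pos", "mut", "severity"]].copy()
    variants["pathogenicity"] = "pathogenic"
    props = df[["gene", "wt", "pos", "mut", "ddg", "rsa"]].copy()
    return variants, props


def gen_cohort(
    config: SimulationConfig,
    panel: GenePanel = GenePanel(),
    truth: GroundTruth | None = None,
) -> pd.DataFrame:
    """Sample a cohort's missense genotypes over the gene panel.

    Each panel gene carries the variants of its configured frequency
    spectrum; presence per (individual, variant) is an independent Bernoulli
    draw of the variant's frequency (times an optional per-superpopulation
    multiplier). Variant pathogenicity is a Bernoulli(``pathogenic_prob``)
    flag drawn once per variant. The realised per-variant roster (key,
    frequency, pathogenic flag) is recorded into ``truth.cohort_variants``
    when a truth object is supplied.
    """
    rng = _rng(config, 3)
    roster_rows = []
    for gene in panel.genes:
        freqs = config.gene_freq_spectrum.get(gene, _FALLBACK_SPECTRUM)
        positions = rng.choice(2000, size=len(freqs), replace=False) + 1
        for freq, pos in zip(freqs, positions):
            wt_i = int(rng.integers(0, 20))
            mut_i = int(_other_residue(rng, np.array(wt_i)))
            roster_rows.append(
                {
                    "gene": gene,
                    "variant_key": f"{_AA[wt_i]}{pos}{_AA[mut_i]}",
                    "freq": float(freq),
                    "pathogenic": bool(rng.random() < config.pathogenic_prob),
                }
            )
    roster = pd.DataFrame(roster_rows)
    if truth is not None:
        truth.cohort_variants = roster.copy()

    pops = list(config.superpopulation_weights)
    weights = np.array([config.superpopulation_weights[p] for p in pops])
    pop_of = rng.choice(pops, size=config.cohort_size, p=weights)
    multipliers = config.pop_freq_multipliers or {}
    mult = np.array([multipliers.get(p, 1.0) for p in pop_of])

    freq = roster["freq"].to_numpy()
    present = rng.random((config.cohort_size, len(roster))) < np.clip(
        np.outer(mult, freq), 0.0, 1.0
    )
    ind_idx, var_idx = np.nonzero(present)
    genotypes = pd.DataFrame(
        {
            "individual_id": [f"IND{i + 1:04d}" for i in ind_idx],
            "superpopulation": pop_of[ind_idx],
            "gene": roster["gene"].to_numpy()[var_idx],
            "variant_key": roster["variant_key"].to_numpy()[var_idx],
            "pathogenicity": np.where(
                roster["pathogenic"].to_numpy()[var_idx], "pathogenic", "neutral"
            ),
        }
    )
    logger.info(
        "cohort of %d individuals, %d genotype rows over %d roster variants",
        config.cohort_size, len(genotypes), len(roster),
    )
    return genotypes


@dataclass
class SimulationResult:
    alignments: dict[str, OrthologAlignment]
    variants: pd.DataFrame
    props: pd.DataFrame
    genotypes: pd.DataFrame
    panel: GenePanel
    truth: GroundTruth


def simulate_all(
    config: SimulationConfig,
    panel: GenePanel = GenePanel(),
    out_dir: str | Path | None = None,
) -> SimulationResult:
    """Run every generator stage; optionally write all files to a directory.

    Emits per-gene ``msa_<gene>.fasta``, ``variants.tsv``, ``props.tsv``,
    ``genotypes.tsv``, ``panel.txt`` and ``truth.json``.
    """
    alignments, truth = gen_msa(config)
    variants, props = gen_variant_and_property_tables(config, truth)
    genotypes = gen_cohort(config, panel, truth)
    result = SimulationResult(alignments, variants, props, genotypes, panel, truth)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for gene, aln in alignments.items():
            write_msa_fasta(aln, out / f"msa_{gene}.fasta")
        write_variant_table(variants, out / "variants.tsv")
        props.to_csv(out / "props.tsv", sep="\t", index=False)
        write_genotypes(genotypes, out / "genotypes.tsv")
        (out / "panel.txt").write_text("\n".join(panel.genes) + "\n")
        (out / "truth.json").write_text(truth.to_json())
    return result


def config_from_mapping(mapping: dict) -> SimulationConfig:
    """Build a config from a flat key-value mapping (e.g. parsed YAML)."""
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigurationError(f"unknown simulation keys: {sorted(unknown)}")
    coerced = dict(mapping)
    for key in ("genes", "site_conservation_profile"):
        if key in coerced and coerced[key] is not None:
            coerced[key] = tuple(coerced[key])
    if "entropy_range" in coerced:
        coerced["entropy_range"] = tuple(coerced["entropy_range"])
    if "gene_freq_spectrum" in coerced:
        coerced["gene_freq_spectrum"] = {
            g: tuple(v) for g, v in coerced["gene_freq_spectrum"].items()
        }
    return SimulationConfig(**coerced)
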