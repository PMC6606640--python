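import pandas as pd
import pytest
from hypothesis import settings

from cpdtools.msa_analysis import OrthologAlignment

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def fviii_toy_alignment() -> OrthologAlignment:
    """Toy FVIII-family MSA built around the classic L69V hemophilia-A
    compensation: the human row carries L at ungapped position 69 while
    chimpanzee, mouse and rat carry V at the same column; pig keeps L.
    One insertion column (human gap) sits before the site, so alignment
    column != position.
    """
    stem = "A" * 30
    tail = "A" * 38
    human = stem + "-" + tail + "L" + "A"  # 70 residues, pos 69 = L, column 69
    compensated = stem + "G" + tail + "V" + "A"
    uncompensated = stem + "G" + tail + "L" + "A"
    rows = (
        ("HUMAN", human),
        ("CHIMP", compensated),
        ("MOUSE", compensated),
        ("RAT", compensated),
        ("PIG", uncompensated),
    )
    return OrthologAlignment(rows=rows, human_index=0)


@pytest.fixture
def small_alignment() -> OrthologAlignment:
    """Hand-checkable 4-row, 6-column alignment with gaps and an ambiguous
    letter."""
    rows = (
        ("HUMAN", "ACD-EF"),
        ("SP1", "AVD-EF"),
        ("SP2", "A-DXEF"),
        ("SP3", "-CD-EF"),
    )
    return OrthologAlignment(rows=rows, human_index=0)


@pytest.fixture
def toy_genotypes() -> pd.DataFrame:
    """Three-individual cohort over a few panel genes; I1 carries the focal
    F8 variant L69V with 4 accompanying variants."""
    rows = [
        ("I1", "EUR", "F8", "L69V", "pathogenic"),
        ("I1", "EUR", "VWF", "A10T", "neutral"),
        ("I1", "EUR", "VWF", "P20S", "pathogenic"),
        ("I1", "EUR", "F12", "G30R", "neutral"),
        ("I1", "EUR", "F5", "K40E", "unknown"),
        ("I2", "AFR", "VWF", "A10T", "neutral"),
        ("I2", "AFR", "F12", "G30R", "neutral"),
        ("I3", "EAS", "VWF", "A10T", "neutral"),
        ("I3", "EAS", "F9", "R55Q", "pathogenic"),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "individual_id", "superpopulation", "gene", "variant_key",
            "pathogenicity",
        ],
    )
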