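import numpy as np
import pytest

from copurify import (
    GeneratorConfig,
    ProteinEntry,
    PsmRecord,
    generate_experiment,
    run_pipeline,
)

TRYPTIC_FLANKS = ("K", "R", "-")
RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


def random_psm(rng: np.random.Generator, i: int) -> PsmRecord:
    """A PSM with fields scattered around the retention boundaries."""
    length = int(rng.integers(4, 15))
    peptide = "".join(rng.choice(list(RESIDUES), size=length - 1))
    peptide += str(rng.choice(["K", "R", "G"]))
    return PsmRecord(
        spectrum_id=f"s{i:04d}",
        peptide=peptide,
        prev_aa=str(rng.choice(["K", "R", "-", "G", "A"])),
        next_aa=str(rng.choice(["-", "P", "G", "A"])),
        charge=int(rng.integers(1, 6)),
        xcorr=float(rng.uniform(0.5, 4.5)),
        deltcn=float(rng.uniform(0.0, 0.3)),
        sp_rank=int(rng.integers(1, 30)),
        protein_accessions=("P1",),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def toy_db() -> list[ProteinEntry]:
    return [
        ProteinEntry("P1", "", "MKAAAAGGRCCDDK"),
        ProteinEntry("P2", "", "GGKAARCCWWYK"),
        ProteinEntry("shuffled_P1", "", "KADMACGDAKGARC", is_decoy=True),
    ]


@pytest.fixture(scope="session")
def default_experiment():
    """One default-configuration synthetic experiment, shared read-only."""
    return generate_experiment(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_pipeline_result(default_experiment):
    exp = default_experiment
    return run_pipeline(exp.database, exp.psm_tables, exp.manifest, bait=exp.truth.bait)
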