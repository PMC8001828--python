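"""Shared fixtures: the five-line study design and compact table builders."""

import pandas as pd
import pytest
from hypothesis import settings

from segbioid.core import DetectionTable, ExperimentDesign, TABLE_COLUMNS, study_design

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

# canonical line labels of the built-in design
PARENTAL = "HEK293"
NLS = "NLS-BioID2"
FULL = "Ku70-BioID2"
VWA = "Ku70-vWA-BioID2"
DVWA = "Ku70-dvWA-BioID2"
ALL_LINES = (PARENTAL, NLS, FULL, VWA, DVWA)


@pytest.fixture(scope="session")
def design() -> ExperimentDesign:
    return study_design()


def make_table(hits: dict, spectral: int = 5, peptides: int = 2) -> DetectionTable:
    """Build a DetectionTable from {gene: {line: [replicates]}} shorthand.

    Each listed replicate becomes one detected row with the given spectral and
    unique-peptide counts; a (gene, line) pair may alternatively map to
    {replicate: spectral_count} for per-replicate counts.
    """
    rows = []
    for gene, lines in hits.items():
        for line, reps in lines.items():
            if isinstance(reps, dict):
                items = reps.items()
            else:
                items = ((r, spectral) for r in reps)
            for rep, count in items:
                rows.append((f"ACC_{gene}", gene, line, rep, peptides, count))
    return DetectionTable(pd.DataFrame(rows, columns=TABLE_COLUMNS))


@pytest.fixture
def table_builder():
    return make_table
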