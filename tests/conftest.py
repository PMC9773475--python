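import datetime as dt

import numpy as np
import pytest

import pallimed as pm


@pytest.fixture(scope="session")
def lexicon():
    return pm.load_default_lexicon()


@pytest.fixture
def worked_example_dtm():
    """The 3-patient x 4-drug worked binary matrix.

    Original layout (albumin, vancomycin, fentanyl, furosemide):
    D1 (1,1,1,1), D2 (1,0,0,1), D3 (1,1,0,0); stored here with
    lexicographic columns.
    """
    terms = ["albumin", "fentanyl", "furosemide", "vancomycin"]
    values = np.array(
        [
            [1, 1, 1, 1],  # D1
            [1, 0, 1, 0],  # D2: albumin, furosemide
            [1, 0, 0, 1],  # D3: albumin, vancomycin
        ]
    )
    return pm.DocumentTermMatrix(["d1", "d2", "d3"], terms, values, mode="binary")


@pytest.fixture
def worked_example_docs():
    """Notes that reconstruct the worked example matrix."""
    return [
        pm.NoteDocument("d1", "albumin vancomycin fentanyl furosemide"),
        pm.NoteDocument("d2", "albumin given; furosemide continued"),
        pm.NoteDocument("d3", "albumin and vancomycin"),
    ]


#: (term, freq_early, freq_late) rows of the reference trigger table
REFERENCE_FREQS = [
    ("cefepime", 35, 19),
    ("fluconazole", 25, 8),
    ("vancomycin", 22, 5),
    ("ceftazidime", 21, 4),
    ("furosemide", 23, 8),
    ("morphine", 29, 19),
    ("albumin", 23, 11),
    ("amiodarone", 23, 12),
    ("fentanyl", 19, 8),
    ("meropenem", 16, 4),
    ("metronidazole", 16, 4),
]

#: expected PTI column, descending
REFERENCE_PTI = [560, 425, 374, 357, 345, 290, 276, 253, 209, 192, 192]


def make_records(intervals, start=dt.date(2017, 1, 1), covariates=None):
    """Patient records with the given referral-to-death intervals."""
    records = []
    for i, days in enumerate(intervals):
        covs = covariates[i] if covariates else {}
        records.append(
            pm.PatientRecord(
                f"p{i:03d}", start, start + dt.timedelta(days=int(days)), covs
            )
        )
    return records


def random_binary_dtm(rng, max_patients=30, max_terms=15):
    """Random binary matrix with no all-zero columns."""
    n = int(rng.integers(2, max_patients + 1))
    m = int(rng.integers(1, max_terms + 1))
    values = (rng.random((n, m)) < rng.uniform(0.15, 0.7)).astype(np.int64)
    keep = values.sum(axis=0) > 0
    values = values[:, keep]
    terms = [f"drug{j:02d}" for j in range(values.shape[1])]
    return pm.DocumentTermMatrix([f"p{i}" for i in range(n)], terms, values)
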