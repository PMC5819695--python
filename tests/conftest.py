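import numpy as np
import pandas as pd
import pytest

from mirtriad.types import (
    AssayDefinition,
    AssayRole,
    CtMatrix,
    SampleManifest,
    default_assay_roles,
)

HOUSEKEEPERS = ("RNU44", "RNU48", "U6")
NEG_CONTROL = "ath-miR-159a"


def make_ct_matrix(values: dict[str, list], samples: list[str],
                   housekeepers=HOUSEKEEPERS, neg_control=NEG_CONTROL) -> CtMatrix:
    """Build a CtMatrix from {assay_id: row} with roles assigned by name."""
    ids = list(values)
    frame = pd.DataFrame(
        [values[a] for a in ids], index=ids, columns=samples, dtype=float
    )
    return CtMatrix(default_assay_roles(ids, housekeepers, neg_control), frame)


def make_manifest(rows: dict[str, dict]) -> SampleManifest:
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "sample_id"
    if "is_pool" not in frame.columns:
        frame["is_pool"] = False
    return SampleManifest(frame)


@pytest.fixture
def small_ct():
    """3 targets + 3 housekeepers + negative control, 2 samples."""
    return make_ct_matrix(
        {
            "hsa-miR-1": [25.0, 26.0],
            "hsa-miR-2": [30.0, 29.0],
            "hsa-miR-3": [np.nan, 31.0],
            "RNU44": [20.0, 21.0],
            "RNU48": [22.0, 21.0],
            "U6": [24.0, 21.0],
            "ath-miR-159a": [np.nan, np.nan],
        },
        ["s1", "s2"],
    )


@pytest.fixture
def cohort_manifest():
    """10 LM / 10 PER / 3 M0 patient manifest with pT4 + classifier attributes
    matching the printed cohort counts (PER 7/10 pT4, LM 0/10; classifier
    LM 10/10, PER 2/10, M0 0/3)."""
    rows = {}
    for i in range(1, 11):
        rows[f"LM-{i:02d}"] = {"group": "LM", "pT4_positive": 0, "classifier_positive": 1}
    for i in range(1, 11):
        rows[f"PER-{i:02d}"] = {
            "group": "PER",
            "pT4_positive": 1 if i <= 7 else 0,
            "classifier_positive": 1 if i <= 2 else 0,
        }
    for i in range(1, 4):
        rows[f"M0-{i:02d}"] = {"group": "M0", "pT4_positive": 0, "classifier_positive": 0}
    return make_manifest(rows)
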