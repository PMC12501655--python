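import numpy as np
import pandas as pd
import pytest

from innomod import (
    CANONICAL_TRAITS,
    OsteometricTable,
    default_reference_config,
    default_validation_config,
    generate_table,
)

# round positive fill values so tables are valid by construction
_FILL = {
    "PUM": 70.0, "SPU": 30.0, "DCOX": 200.0, "IIMT": 40.0,
    "ISMM": 100.0, "SCOX": 150.0, "SS": 65.0, "SA": 70.0,
}


def build_table(n=None, sex=None, **columns) -> OsteometricTable:
    """Construct a valid table, filling unspecified traits with varying
    positive values (small per-row jitter keeps variances nonzero)."""
    if n is None:
        n = len(next(iter(columns.values()))) if columns else 3
    data = {}
    for i, t in enumerate(CANONICAL_TRAITS):
        if t in columns:
            data[t] = list(columns[t])
        else:
            data[t] = [_FILL[t] + 0.5 * j + 0.1 * i for j in range(n)]
    if sex is not None:
        data["sex"] = list(sex)
    return OsteometricTable(pd.DataFrame(data))


@pytest.fixture(scope="session")
def reference_table() -> OsteometricTable:
    """Default synthetic reference set: 944 F + 941 M, fully observed."""
    return generate_table(default_reference_config(seed=0))


@pytest.fixture(scope="session")
def validation_table() -> OsteometricTable:
    """Default synthetic validation set: 360 F + 367 M with the default
    per-trait missing-cell counts."""
    return generate_table(default_validation_config(seed=1))
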