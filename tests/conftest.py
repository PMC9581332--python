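import numpy as np
import pandas as pd
import pytest

from clonetrace.datamodel import CountMatrix, MetadataTable, ValueKind


@pytest.fixture
def toy_cm() -> CountMatrix:
    """3 barcodes x 2 samples with column sums (15, 9)."""
    df = pd.DataFrame(
        [[10, 0], [5, 2], [0, 7]],
        index=pd.Index(["BC001", "BC002", "BC003"], name="barcode"),
        columns=["s1", "s2"],
        dtype=float,
    )
    return CountMatrix(df, ValueKind.RAW_READS)


@pytest.fixture
def dup_cm() -> CountMatrix:
    """The duplicate-merge worked example: dupA=(10,0,5), dupB=(6,2,0)."""
    df = pd.DataFrame(
        {"s1_dupA": [10.0, 0.0, 5.0], "s1_dupB": [6.0, 2.0, 0.0]},
        index=pd.Index(["BC001", "BC002", "BC003"], name="barcode"),
    )
    return CountMatrix(df, ValueKind.RAW_READS)


@pytest.fixture
def dup_md() -> MetadataTable:
    df = pd.DataFrame(
        {"individual": ["s1", "s1"], "duplicate": ["dupA", "dupB"]},
        index=pd.Index(["s1_dupA", "s1_dupB"], name="sample"),
    )
    return MetadataTable(df)


@pytest.fixture
def merged_two_types() -> tuple[CountMatrix, MetadataTable]:
    """Merged matrix over two individuals x two cell types."""
    rng = np.random.default_rng(11)
    raw = rng.integers(0, 50, size=(8, 4)).astype(float)
    raw[raw < 10] = 0.0
    df = pd.DataFrame(
        raw,
        index=pd.Index([f"BC{i:03d}" for i in range(8)], name="barcode"),
        columns=["m1_cDC1", "m1_cDC2", "m2_cDC1", "m2_cDC2"],
    )
    cm = CountMatrix(df, ValueKind.RAW_READS)
    md = MetadataTable.from_sample_names(list(df.columns), ["individual", "cell_type"])
    return cm, md
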