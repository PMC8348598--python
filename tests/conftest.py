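import numpy as np
import pandas as pd
import pytest

from sweatlipidomics.peaktable import InjectionRecord, PeakTable
from sweatlipidomics.synthetic import GeneratorParams, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One full default synthetic study run, shared across tests."""
    return generate_dataset(GeneratorParams(seed=7))


@pytest.fixture(scope="session")
def noiseless_params():
    """All stochastic components switched off."""
    return GeneratorParams(
        seed=5, base_log_sd=0.0, individual_log_sd=0.0, day_log_sd=0.0,
        sample_log_sd=0.0, side_log2_shift=0.0, dilution_log_sd=0.0,
        drift_mode="none", analytical_log_sd=0.0, qc_log_sd=0.0,
        blank_level=0.0, blank_log_sd=0.0, cal_log_sd=0.0,
    )


def make_toy_table(areas: dict, manifest_rows: list[tuple]) -> PeakTable:
    """Small hand-built table: manifest_rows = (id, type, order, ind, day, side, lvl)."""
    records = [InjectionRecord(r[0], r[1], r[2], *(r[3:] if len(r) > 3 else ()))
               for r in manifest_rows]
    ids = [r.injection_id for r in records]
    df = pd.DataFrame(areas, index=ids, dtype=float)
    return PeakTable.from_records(records, df)


@pytest.fixture
def toy_blank_table():
    """10 study samples + 1 blank, three analytes exercising the blank rules.

    - FA 16:0: blank zero, untouched.
    - FA 18:0: blank 5 exceeds the area in 1 of the study samples.
    - FA 20:0: blank above 6 of 10 study samples -> discarded.
    """
    rows = [("B1", "blank", 1)]
    rows += [(f"S{i + 1}", "study", i + 2, "ABCDEFGHIJ"[i], 1, "L") for i in range(10)]
    areas = {
        "FA 16:0": [0.0] + [10.0] * 10,                       # clean
        "FA 18:0": [5.0, 10.0, 10.0, 10.0, 4.0] + [10.0] * 6,  # one deficit cell
        "FA 20:0": [8.0] + [2.0] * 6 + [50.0] * 4,             # 6 deficits -> drop
    }
    return make_toy_table(areas, rows)
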