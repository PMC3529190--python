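from pathlib import Path

import pandas as pd
import pytest

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def printed_rates() -> pd.DataFrame:
    """The published age-specific rate grid, transcribed independently."""
    return pd.read_csv(DATA / "rates_printed.csv")


@pytest.fixture(scope="session")
def printed_rr() -> pd.DataFrame:
    """The published relative-risk grid (2 dp), transcribed independently."""
    return pd.read_csv(DATA / "rr_printed.csv")
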