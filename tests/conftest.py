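from pathlib import Path

import numpy as np
import pytest

REPO_ROOT = Path(__file__).resolve().parents[1]

#: the eight-point, two-variable walkthrough window (time order t1..t8)
TABLE1_POINTS = np.array([
    (0.6, 1.5), (2.0, 1.5), (0.3, 1.0), (3.5, 4.8),
    (0.95, 2.0), (3.1, 4.0), (2.4, 1.8), (2.7, 2.1),
])
TABLE1_DELTAS = np.array([0.5, 1.0])


@pytest.fixture
def table1_points():
    return TABLE1_POINTS.copy()


@pytest.fixture
def table1_deltas():
    return TABLE1_DELTAS.copy()


@pytest.fixture
def worked_example_csv():
    return REPO_ROOT / "examples" / "worked_example.csv"


@pytest.fixture
def gistemp_text():
    """Minimal GISTEMP-style monthly table: 3 complete years."""
    return (
        "Land-Ocean Temperature Index (synthetic fixture)\n"
        "Year,Jan,Feb,Mar,Apr,May,Jun,Jul,Aug,Sep,Oct,Nov,Dec,J-D\n"
        "2000,23,40,46,50,31,33,31,32,34,27,28,25,33\n"
        "2001,41,38,49,44,49,46,52,55,46,43,61,49,48\n"
        "2002,70,70,83,51,53,46,56,47,56,49,51,34,56\n"
    )
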