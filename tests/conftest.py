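import numpy as np
import pandas as pd
import pytest

from msrehab.battery import TestDef


def tidy_scores(rows):
    """Build a tidy score table from (subject, arm, timepoint, test, value,
    higher_is_better) tuples."""
    return pd.DataFrame(
        rows,
        columns=["subject_id", "arm", "timepoint", "test_id", "value",
                 "higher_is_better"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_test():
    """A single higher-is-better test with unit-free round parameters."""
    return TestDef("TST", "working_memory", True, 10.0, 2.0, 9.0, 2.0, 0.5)


@pytest.fixture
def two_arm_scores():
    """Four waitlist controls and two intervention subjects on one test.

    Control changes are {-1, 1, 2, -2} (mean 0, sd sqrt(10/3)); the two
    intervention subjects change by +4 and 0.
    """
    rows = []
    for i, delta in enumerate([-1.0, 1.0, 2.0, -2.0]):
        rows.append((f"w{i}", "waitlist", "T0", "TST", 10.0, True))
        rows.append((f"w{i}", "waitlist", "T1", "TST", 10.0 + delta, True))
    rows.append(("p0", "intervention", "T0", "TST", 10.0, True))
    rows.append(("p0", "intervention", "T1", "TST", 14.0, True))
    rows.append(("p1", "intervention", "T0", "TST", 10.0, True))
    rows.append(("p1", "intervention", "T1", "TST", 10.0, True))
    return tidy_scores(rows)
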