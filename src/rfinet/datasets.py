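"""Built-in example data: the published Nelore divergent-RFI phenotype table.

Twenty Nelore steers selected from the tails of the BLUP distribution for
residual feed intake: ten feed-efficient (low RFI) and ten feed-inefficient
(high RFI) animals, with BLUP (kg/day), RFI (kg/day), intramuscular fat
(IMF, %) and ribeye area (REA, cm^2).  Two IMF cells are missing in the
published table and are stored as NaN here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from rfinet.phenotypes import FEED_EFFICIENT, FEED_INEFFICIENT

_NA = np.nan

# animal_id, group, blup, rfi, imf, rea
_NELORE_ROWS = [
    ("FE01", FEED_EFFICIENT, -0.0914, -1.0493, 2.44, 58.75),
    ("FE02", FEED_EFFICIENT, -0.0699, -0.5469, 3.03, 69.75),
    ("FE03", FEED_EFFICIENT, -0.0360, -0.5714, 2.65, 63.00),
    ("FE04", FEED_EFFICIENT, -0.0990, -1.2284, 3.07, 59.00),
    ("FE05", FEED_EFFICIENT, -0.0862, -0.7682, 3.05, 57.25),
    ("FE06", FEED_EFFICIENT, -0.0414, -0.6588, 3.37, 57.00),
    ("FE07", FEED_EFFICIENT, -0.0341, -0.3803, 2.71, 61.25),
    ("FE08", FEED_EFFICIENT, -0.0417, -0.1459, 2.38, 58.00),
    ("FE09", FEED_EFFICIENT, -0.0679, -1.1983, _NA, 69.00),
    ("FE10", FEED_EFFICIENT, -0.0306, -0.2845, 4.58, 67.75),
    ("FI01", FEED_INEFFICIENT, 0.0856, 0.3270, 3.86, 52.75),
    ("FI02", FEED_INEFFICIENT, 0.0939, 0.6588, _NA, 55.75),
    ("FI03", FEED_INEFFICIENT, 0.0876, 0.4115, 3.40, 56.00),
    ("FI04", FEED_INEFFICIENT, 0.0480, 0.2443, 2.34, 59.50),
    ("FI05", FEED_INEFFICIENT, 0.0721, -0.1548, 3.69, 59.50),
    ("FI06", FEED_INEFFICIENT, 0.1247, 1.8084, 4.20, 66.75),
    ("FI07", FEED_INEFFICIENT, 0.0875, 0.4206, 2.86, 57.25),
    ("FI08", FEED_INEFFICIENT, 0.0688, -0.2976, 2.83, 63.50),
    ("FI09", FEED_INEFFICIENT, 0.0861, 1.2807, 3.26, 45.75),
    ("FI10", FEED_INEFFICIENT, 0.0924, 0.5969, 2.59, 53.75),
]


def nelore_phenotypes() -> pd.DataFrame:
    """The published 20-animal divergent-RFI Nelore phenotype table."""
    return pd.DataFrame(
        _NELORE_ROWS, columns=["animal_id", "group", "blup", "rfi", "imf", "rea"]
    )
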