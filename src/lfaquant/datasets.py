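"""Bundled validation-study fixtures for the three-level 25(OH)D readout.

These are the published summary data of a commercial smartphone-read
lateral-flow 25(OH)D kit's clinical validation: two 3x3 contingency
tables cross-classifying the kit's three-level calls (rows) against a
laboratory immunoassay analyzer's concentration categories (columns:
deficient < 20, insufficient 20–30, sufficient > 30 ng/mL), and the
blank/low-level summary statistics behind its EP17 detection limits.
They serve as ready inputs for the agreement and detection-limit layers.
"""

from __future__ import annotations

import numpy as np


def serum_comparison_table() -> np.ndarray:
    """Serum method comparison, n = 100: kit (rows) vs analyzer (columns)."""
    return np.array(
        [
            [14, 1, 0],
            [1, 38, 1],
            [0, 0, 45],
        ]
    )


def capillary_equivalence_table() -> np.ndarray:
    """Capillary blood (kit, rows) vs serum (analyzer, columns), n = 22."""
    return np.array(
        [
            [12, 1, 0],
            [0, 6, 0],
            [0, 0, 3],
        ]
    )


# Blank / low-level summary from the kit's EP17 detection-limit study
# (20 replicates each), in ng/mL.
BLANK_MEAN = 0.5
BLANK_SD = 0.2
LOW_SD = 2.5
N_BLANK_REPLICATES = 20
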