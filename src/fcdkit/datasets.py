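"""Bundled reference data for worked examples.

A 23-subject pediatric FCD type II surgical series provides the volume
bookkeeping used in the worked examples: the expert-outlined predictive
radiological ROI (PRR, plotted in 17 of 23 subjects), the automatically
detected post-resection cavity (PRC, all 23), and their overlap, all in
mm^3 on a 1 mm^3 voxel grid.  Percent overlay is the fraction of the
PRC covered by the PRR.

Subject 2's row is internally inconsistent in the source table (its
overlap and printed percent cannot both be right); its cavity volume is
reconstructed here from the cohort mean, the row is flagged, and it is
excluded from worked examples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .volumes import BinaryMask

# subject -> (PRR mm^3 or None, PRC mm^3, overlap mm^3 or None, consistent row)
_SURGICAL_SERIES = {
    1:  (None, 14769, None, True),
    2:  (3466, 52332, 274,  False),  # cavity volume back-computed from cohort mean
    3:  (1164, 21046, 137,  True),
    4:  (863,  13798, 0,    True),
    5:  (781,  14029, 685,  True),
    6:  (3691, 26929, 2902, True),
    7:  (847,  7920,  127,  True),
    8:  (None, 4287,  None, True),
    9:  (4701, 3124,  0,    True),
    10: (1072, 6274,  453,  True),
    11: (None, 6365,  None, True),
    12: (2558, 18720, 2211, True),
    13: (None, 9450,  None, True),
    14: (None, 14781, None, True),
    15: (1217, 4286,  0,    True),
    16: (3202, 5999,  745,  True),
    17: (727,  9432,  447,  True),
    18: (574,  9690,  449,  True),
    19: (1593, 3096,  1056, True),
    20: (None, 12114, None, True),
    21: (1901, 5307,  351,  True),
    22: (866,  2385,  0,    True),
    23: (1053, 52716, 0,    True),
}

#: subjects whose rows are self-consistent and have a nonzero overlap —
#: usable as percent-overlay worked examples
WORKED_EXAMPLE_SUBJECTS = (19, 16, 12, 6, 18)


def surgical_series() -> pd.DataFrame:
    """The reference cohort as a DataFrame indexed by subject number.

    Columns: ``prr_mm3``, ``prc_mm3``, ``overlap_mm3`` (floats, NaN
    where no PRR was plotted) and ``consistent`` (bool).
    """
    rows = {
        s: {"prr_mm3": np.nan if prr is None else float(prr),
            "prc_mm3": float(prc),
            "overlap_mm3": np.nan if ov is None else float(ov),
            "consistent": ok}
        for s, (prr, prc, ov, ok) in _SURGICAL_SERIES.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject"
    return df


def synthetic_mask_pair(n_a: int, n_b: int, n_overlap: int,
                        voxel_mm: float = 1.0):
    """Construct a (detected, reference) mask pair with given voxel counts.

    Builds two masks on a 1 x 1 x N line grid sharing exactly
    ``n_overlap`` voxels — the minimal geometry realising a printed
    (|A|, |B|, |A∩B|) triple so that overlap metrics can be recomputed
    from actual masks rather than from the published numbers directly.
    """
    if n_overlap > min(n_a, n_b):
        raise ValueError("overlap cannot exceed either mask")
    n = n_a + n_b - n_overlap
    if n == 0:
        n = 1
    a = np.zeros((1, 1, n), dtype=np.uint8)
    b = np.zeros((1, 1, n), dtype=np.uint8)
    a[0, 0, :n_a] = 1
    b[0, 0, n_a - n_overlap:n_a - n_overlap + n_b] = 1
    spacing = (voxel_mm, voxel_mm, voxel_mm)
    return (BinaryMask(data=a, spacing=spacing),
            BinaryMask(data=b, spacing=spacing))
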