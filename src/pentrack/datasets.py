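"""Small bundled reference tables for worked examples and validation.

The stay-time table below is a published 24-hour comparison for a
four-pig finishing pen: seconds each pig spent in the defecating,
resting and eating areas, once from continuous manual video observation
and once from the automated tracking pipeline.  It is the canonical
input for :func:`pentrack.zones.error_analysis`.
"""

from __future__ import annotations

from typing import Tuple

import pandas as pd

__all__ = ["example_stay_times"]

_ZONES = ["defecating", "resting", "eating"]

_MANUAL = {
    1: [9039, 67530, 9791],
    2: [32, 73850, 12478],
    3: [14407, 55649, 16304],
    4: [4150, 75939, 6271],
}

_TRACKED = {
    1: [9138, 67213, 10009],
    2: [32, 74190, 12138],
    3: [14665, 55136, 16559],
    4: [4033, 75787, 6540],
}


def example_stay_times() -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Return ``(manual, tracked)`` stay-time tables in seconds.

    Rows are pig identities 1-4, columns the three pen zones; both
    tables cover the same 24-hour observation window.
    """
    manual = pd.DataFrame.from_dict(_MANUAL, orient="index", columns=_ZONES).rename_axis("id")
    tracked = pd.DataFrame.from_dict(_TRACKED, orient="index", columns=_ZONES).rename_axis("id")
    return manual, tracked
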