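"""Hans immunohistochemistry surrogate classifier.

Decision tree over CD10, BCL6 and MUM1 tumor-cell staining percentages, each
dichotomized at a positivity cut-off (default 30%, with exactly the cut-off
counting as positive):

    CD10+                     → GCB
    CD10−, BCL6−              → non-GCB
    CD10−, BCL6+, MUM1+       → non-GCB
    CD10−, BCL6+, MUM1−       → GCB
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import IhcTable


@dataclass(frozen=True)
class HansConfig:
    positivity_cutoff: float = 30.0  # percent tumor cells staining

    def __post_init__(self) -> None:
        if not 0 < self.positivity_cutoff < 100:
            raise ValueError("positivity_cutoff must lie in (0, 100)")


def hans_call(
    cd10_pct: float,
    bcl6_pct: float,
    mum1_pct: float,
    config: HansConfig = HansConfig(),
) -> str:
    """Classify one sample as GCB or non-GCB from its three marker stains.

    All three percentages must be present and in [0, 100]; a missing marker
    makes the call non-evaluable and raises.
    """
    values = (cd10_pct, bcl6_pct, mum1_pct)
    for name, v in zip(("CD10", "BCL6", "MUM1"), values):
        if v is None or not np.isfinite(v):
            raise ValueError(f"{name} staining missing; Hans call not evaluable")
        if not 0 <= v <= 100:
            raise ValueError(f"{name} staining {v} outside [0, 100]")
    cut = config.positivity_cutoff
    cd10, bcl6, mum1 = (v >= cut for v in values)
    if cd10:
        return "GCB"
    if not bcl6:
        return "non-GCB"
    return "non-GCB" if mum1 else "GCB"


def hans_calls(table: IhcTable, config: HansConfig = HansConfig()) -> pd.Series:
    """Vectorized Hans call per sample of an IHC table."""
    out = {
        s: hans_call(r["cd10_pct"], r["bcl6_pct"], r["mum1_pct"], config)
        for s, r in table.data.iterrows()
    }
    return pd.Series(out, name="hans_call").rename_axis("sample_id")
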