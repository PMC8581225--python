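"""Vigilance stage labels, ordering, and numeric arousal codes.

Wakefulness vigilance is described on an ordinal scale running from alert
desynchronization down to drowsiness:

``0``   alert, desynchronized low-voltage EEG, no alpha, no slow eye movements
``A1``  occipitally dominant alpha (relaxed wakefulness)
``A2``  alpha spreading anteriorly
``A3``  anteriorized alpha
``B1``  alpha dropout with slow eye movements (SEM)
``B23`` theta-dominant drowsiness

``ARTIFACT`` marks 1-s segments excluded from every denominator.
"""

from __future__ import annotations

import numpy as np

# Ordered from most alert to drowsiest.  Stage C (sleep onset) is out of
# scope: monitored resting-state recordings do not reach it.
STAGE_ORDER: tuple[str, ...] = ("0", "A1", "A2", "A3", "B1", "B23")

ARTIFACT = "ARTIFACT"

ALL_LABELS: tuple[str, ...] = STAGE_ORDER + (ARTIFACT,)

#: Numeric arousal code per stage: higher = more aroused.  The mean vigilance
#: level is the artifact-free average of these codes; the 6..1 map reproduces
#: published mean-vigilance values from their own stage-occurrence
#: percentages, which is how the coding was fixed.
STAGE_CODE: dict[str, int] = {"0": 6, "A1": 5, "A2": 4, "A3": 3, "B1": 2, "B23": 1}

#: index of each stage in STAGE_ORDER
STAGE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STAGE_ORDER)}


def as_label_array(labels) -> np.ndarray:
    """Coerce a sequence of stage labels to a validated numpy string array."""
    arr = np.asarray(labels, dtype="U8")
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("stage sequence must be a non-empty 1-D sequence")
    bad = set(arr.tolist()) - set(ALL_LABELS)
    if bad:
        raise ValueError(f"unknown stage labels: {sorted(bad)}")
    return arr
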