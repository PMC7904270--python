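"""Reference benchmark results on the EYEDIAP database.

These are the published per-preset and per-participant gaze-tracking
errors of this method on the EYEDIAP RGB video clips, kept here for
context and for arithmetic self-consistency checks: the combined error C
must equal sqrt(H^2 + V^2) within printed precision, averages must equal
the column means, and detection rates must equal DF/TF. Reproducing the
absolute numbers requires the EYEDIAP dataset itself and is out of scope.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "mapping_function_errors",
    "session_errors",
    "rss_deviation",
    "average_row_deviation",
    "detection_rate_deviation",
]

# Mean H/V/C (degrees) over 52 RGB clips for the six mapping presets,
# at refinement delta = 1 and delta = 2.
_MAPPING_ROWS = [
    # preset, delta, H, V, C
    (1, 1, 6.4, 4.0, 7.5), (1, 2, 6.3, 3.9, 7.4),
    (2, 1, 6.4, 3.9, 7.5), (2, 2, 6.2, 3.8, 7.3),
    (3, 1, 6.0, 4.1, 7.3), (3, 2, 5.8, 4.1, 7.1),
    (4, 1, 5.8, 4.0, 7.0), (4, 2, 5.7, 4.0, 7.0),
    (5, 1, 6.2, 4.6, 7.7), (5, 2, 6.1, 4.6, 7.6),
    (6, 1, 6.1, 4.5, 7.6), (6, 2, 5.9, 4.4, 7.4),
]

# Per-participant errors on the DSM and CSM clips: total/detected frames
# and H/V/C for the left (w=1), right (w=0) and fused (w=0.5) POR.
# Columns: participant, TF, DF, rate(%),
#          H_L, H_R, H_F, V_L, V_R, V_F, C_L, C_R, C_F
_SESSION_ROWS = {
    "DSM": [
        (1, 4465, 3893, 87.2, 7.9, 8.0, 7.7, 4.5, 4.5, 4.5, 9.1, 9.2, 8.9),
        (2, 4464, 4335, 97.1, 7.6, 6.5, 6.8, 3.7, 3.8, 3.7, 8.4, 7.6, 7.7),
        (3, 4433, 4322, 97.5, 5.9, 6.9, 5.9, 5.7, 5.5, 5.3, 8.2, 8.8, 7.9),
        (4, 4464, 4402, 98.6, 7.7, 7.2, 5.7, 5.0, 4.8, 4.5, 9.2, 8.7, 7.3),
        (5, 4465, 4465, 100.0, 5.9, 5.2, 4.5, 4.5, 4.1, 4.0, 7.4, 6.7, 6.0),
        (6, 4464, 4464, 100.0, 5.3, 5.5, 5.1, 4.6, 4.6, 4.5, 7.0, 7.2, 6.8),
        (8, 4465, 4020, 90.0, 9.2, 10.1, 8.7, 4.8, 4.5, 4.4, 10.4, 11.0, 9.8),
        (9, 4464, 4362, 97.7, 10.1, 6.8, 7.5, 3.7, 3.7, 3.6, 10.8, 7.8, 8.3),
        (10, 4464, 4450, 99.7, 9.1, 9.5, 9.2, 4.5, 4.8, 4.6, 10.2, 10.7, 10.3),
        (11, 4465, 4465, 100.0, 4.7, 3.7, 3.5, 4.5, 6.4, 3.5, 6.5, 7.4, 4.9),
        (14, 4465, 4464, 100.0, 4.7, 4.3, 3.6, 3.7, 3.6, 3.3, 6.0, 5.5, 4.9),
        (15, 4465, 4465, 100.0, 3.8, 3.4, 3.2, 4.1, 4.2, 4.2, 5.6, 5.4, 5.3),
        (16, 4465, 4286, 96.0, 6.1, 6.6, 4.9, 4.0, 4.1, 3.9, 7.3, 7.8, 6.2),
    ],
    "CSM": [
        (1, 4457, 3370, 75.6, 9.7, 11.2, 10.3, 4.0, 4.1, 4.0, 10.5, 12.0, 11.0),
        (2, 4457, 4360, 97.8, 7.9, 7.6, 7.6, 3.2, 3.2, 3.1, 8.5, 8.2, 8.2),
        (3, 4458, 3962, 88.9, 6.0, 7.0, 5.9, 4.1, 3.8, 4.0, 7.3, 8.0, 7.1),
        (4, 4494, 4333, 96.4, 8.1, 7.0, 6.7, 3.7, 3.8, 3.7, 8.9, 8.0, 7.7),
        (5, 4458, 4394, 98.6, 5.3, 6.1, 5.1, 3.8, 3.6, 3.7, 6.5, 7.1, 6.3),
        (6, 4458, 4458, 100.0, 7.7, 8.4, 7.6, 4.4, 4.5, 4.1, 8.8, 9.6, 8.6),
        (8, 4458, 3510, 78.7, 10.6, 9.3, 9.6, 4.1, 4.5, 4.3, 11.4, 10.3, 10.5),
        (9, 4457, 4199, 94.2, 7.4, 7.2, 7.2, 4.0, 3.8, 3.8, 8.4, 8.1, 8.1),
        (10, 4492, 4492, 100.0, 6.5, 7.3, 6.6, 5.0, 4.9, 4.9, 8.2, 8.8, 8.3),
        (11, 4458, 4360, 97.8, 6.0, 6.5, 6.2, 3.6, 3.6, 3.6, 7.0, 7.4, 7.1),
        (14, 4458, 4439, 99.6, 4.1, 3.3, 3.4, 3.1, 4.1, 3.4, 5.2, 5.2, 4.9),
        (15, 4458, 4458, 100.0, 3.6, 3.5, 2.9, 3.2, 3.2, 3.1, 4.8, 4.8, 4.2),
        (16, 4458, 4293, 96.3, 5.5, 9.7, 5.5, 4.2, 5.8, 3.8, 6.9, 11.3, 6.6),
    ],
}

# Printed average rows (means over the 13 participants).
_SESSION_AVG = {
    "DSM": (4462, 4338, 97.2, 6.8, 6.5, 5.9, 4.4, 4.5, 4.2, 8.1, 7.9, 7.2),
    "CSM": (4463, 4202, 94.2, 6.8, 7.2, 6.5, 3.9, 4.1, 3.8, 7.9, 8.4, 7.6),
}


def mapping_function_errors() -> pd.DataFrame:
    """Mean H/V/C per mapping preset and refinement delta (degrees)."""
    return pd.DataFrame(_MAPPING_ROWS, columns=["preset", "delta", "H", "V", "C"])


def session_errors(clip_type: str) -> pd.DataFrame:
    """Per-participant errors on the DSM or CSM clips, with the Avg row."""
    cols = [
        "participant", "TF", "DF", "rate",
        "H_L", "H_R", "H_F", "V_L", "V_R", "V_F", "C_L", "C_R", "C_F",
    ]
    df = pd.DataFrame(_SESSION_ROWS[clip_type], columns=cols)
    df.attrs["avg"] = dict(zip(cols[1:], _SESSION_AVG[clip_type]))
    return df


def rss_deviation() -> float:
    """Max |C - sqrt(H^2 + V^2)| over every printed H/V/C triple (degrees).

    Checks all mapping-preset rows plus the L/R/fused triples of every
    participant row; small deviations reflect printed one-decimal rounding.
    """
    devs = []
    for _, _, H, V, C in _MAPPING_ROWS:
        devs.append(abs(C - float(np.hypot(H, V))))
    for rows in _SESSION_ROWS.values():
        for r in rows:
            for off in range(3):  # L, R, fused columns
                H, V, C = r[4 + off], r[7 + off], r[10 + off]
                devs.append(abs(C - float(np.hypot(H, V))))
    return float(max(devs))


def average_row_deviation() -> float:
    """Max |printed average - recomputed column mean| over both clip tables."""
    devs = []
    for clip, rows in _SESSION_ROWS.items():
        arr = np.array([r[1:] for r in rows], dtype=float)
        recomputed = arr.mean(axis=0)
        printed = np.array(_SESSION_AVG[clip], dtype=float)
        # TF/DF averages are printed as integers; compare on the same scale
        devs.append(float(np.max(np.abs(np.round(recomputed[:2]) - printed[:2]))))
        devs.append(float(np.max(np.abs(recomputed[2:] - printed[2:]))))
    return float(max(devs))


def detection_rate_deviation() -> float:
    """Max |printed rate - 100 * DF / TF| over all participant rows (% points)."""
    devs = []
    for rows in _SESSION_ROWS.values():
        for r in rows:
            devs.append(abs(r[3] - 100.0 * r[2] / r[1]))
    return float(max(devs))
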