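"""Event tables for the cued equiprobable Go/NoGo task.

An event table is a :class:`pandas.DataFrame` with one row per
experimental event and columns

``onset``           target (second stimulus) onset, seconds
``duration``        stimulus duration, seconds (0.1 for task trials)
``trial_type``      one of ``go, nogo, ignore_pa, ignore_pp, null_event``
``cue_onset``       cue (first stimulus) onset, seconds; NaN for null events
``response_time``   response latency in milliseconds; NaN when no response

Timing contract (all task trials): the cue is shown for 100 ms and the
cue-target interval is 1000 ms, so ``onset - cue_onset == 1.1 s``; the
inter-trial interval takes values in {2.8, 2.9, 3.0, 3.1, 3.2} s and null
events last {3.0, 3.5, 4.0, 4.5, 5.0} s. For a null event ``onset`` is the
start of the fixation period and ``duration`` its length.

Files are tab-separated with the header
``onset duration trial_type cue_onset response_time`` (BIDS-events core
columns plus the task-specific ones).
"""

from __future__ import annotations

from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

TASK_TRIAL_TYPES = ("go", "nogo", "ignore_pa", "ignore_pp")
NULL_EVENT = "null_event"
TRIAL_TYPES = TASK_TRIAL_TYPES + (NULL_EVENT,)

EVENT_COLUMNS = ["onset", "duration", "trial_type", "cue_onset", "response_time"]

CUE_DURATION_S = 0.1
CUE_TARGET_INTERVAL_S = 1.0
#: cue onset to target onset (cue duration + cue-target interval)
CUE_TARGET_SOA_S = CUE_DURATION_S + CUE_TARGET_INTERVAL_S
STIM_DURATION_S = 0.1
ITI_CHOICES_S = (2.8, 2.9, 3.0, 3.1, 3.2)
NULL_DURATIONS_S = (3.0, 3.5, 4.0, 4.5, 5.0)

__all__ = [
    "TASK_TRIAL_TYPES",
    "NULL_EVENT",
    "TRIAL_TYPES",
    "EVENT_COLUMNS",
    "CUE_TARGET_SOA_S",
    "STIM_DURATION_S",
    "ITI_CHOICES_S",
    "NULL_DURATIONS_S",
    "validate_events",
    "read_events",
    "write_events",
    "events_to_tsv_bytes",
]


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Check the event-table contract; return the (unmodified) table.

    Raises ``ValueError`` on missing columns, unknown trial types,
    non-increasing onsets, or broken cue/target timing.
    """
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table lacks columns {missing}")
    unknown = set(events["trial_type"].unique()) - set(TRIAL_TYPES)
    if unknown:
        raise ValueError(f"unknown trial types {sorted(unknown)}")
    onsets = events["onset"].to_numpy(dtype=float)
    if np.any(~np.isfinite(onsets)):
        raise ValueError("non-finite onsets")
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("onsets must be strictly increasing")
    task = events[events["trial_type"] != NULL_EVENT]
    if len(task):
        soa = task["onset"].to_numpy(float) - task["cue_onset"].to_numpy(float)
        if not np.allclose(soa, CUE_TARGET_SOA_S, atol=1e-9):
            raise ValueError(
                f"task trials must have onset - cue_onset = {CUE_TARGET_SOA_S} s"
            )
        if not np.allclose(task["duration"].to_numpy(float), STIM_DURATION_S):
            raise ValueError(f"task stimulus duration must be {STIM_DURATION_S} s")
    nulls = events[events["trial_type"] == NULL_EVENT]
    if len(nulls):
        durs = nulls["duration"].to_numpy(float)
        ok = np.isclose(durs[:, None], np.asarray(NULL_DURATIONS_S)[None, :]).any(axis=1)
        if not ok.all():
            raise ValueError(f"null-event durations must be in {NULL_DURATIONS_S}")
    return events


def events_to_tsv_bytes(events: pd.DataFrame) -> bytes:
    """Serialize exactly as :func:`write_events` would (determinism checks)."""
    buf = StringIO()
    events[EVENT_COLUMNS].to_csv(buf, sep="\t", index=False, na_rep="n/a", float_format="%.6g")
    return buf.getvalue().encode()


def write_events(events: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_bytes(events_to_tsv_bytes(events))
    return path


def read_events(path: str | Path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t", na_values=["n/a"])
    return validate_events(events)
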