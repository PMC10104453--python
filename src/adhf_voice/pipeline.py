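"""End-to-end glue: recordings → per-day feature table.

Feature columns are named ``<task>:<measure>`` (e.g. ``vowel:f0_mean``,
``rainbow:phrase_total_dur``, ``mpt:mpt``) so the same measure from
different tasks stays distinct in the cohort table.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .segmental import extract_task_features
from .signal_io import (
    SessionManifest,
    Task,
    Waveform,
    load_recording,
    preprocess,
)


def task_feature_row(w: Waveform, task: Task) -> dict[str, float]:
    """Features of one preprocessed recording, task-prefixed."""
    measures = extract_task_features(w, task)
    return {f"{task.value}:{k}": v for k, v in measures.items()}


def build_feature_table(
    recordings: Iterable[tuple[str, int, str, Task, Waveform]],
    preprocessed: bool = False,
) -> pd.DataFrame:
    """One row per (participant, day, sensor) from task recordings.

    `recordings` yields (participant, day, sensor, task, waveform).  Repeats
    of the same task on the same day are averaged per measure, ignoring
    missing repeats.
    """
    rows = []
    for participant, day, sensor, task, wave in recordings:
        w = wave if preprocessed else preprocess(wave)
        row = {"participant": participant, "day": day, "sensor": sensor}
        row.update(task_feature_row(w, task))
        rows.append(row)
    if not rows:
        raise ValueError("no recordings supplied")
    df = pd.DataFrame(rows)
    return (
        df.groupby(["participant", "day", "sensor"], sort=True)
        .mean(numeric_only=True)
        .reset_index()
    )


def run_manifest(manifest: list[SessionManifest], root: str | Path = ".") -> pd.DataFrame:
    """Load every manifest entry from disk and build the feature table."""
    root = Path(root)

    def stream():
        for e in manifest:
            path = Path(e.path)
            if not path.is_absolute():
                path = root / path
            yield (
                e.participant_id,
                e.day_index,
                e.sensor.value,
                e.task,
                load_recording(path, e.sensor),
            )

    return build_feature_table(stream())
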