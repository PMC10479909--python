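"""Trial-log CSV format, fits tables and run manifests.

Trial logs are RFC-4180 CSV, UTF-8, '.' decimal, one row per trial with
the canonical header::

    subject_id,experiment,block_index,phase,trial_index,stage1_option,
    stage1_is_choice,stage2_action,displayed_target,coherent,reward

Trial indices are 0-based within phase.  Reading validates enumerated
fields and the coherence invariant and reports the first offending row.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .simulate import TRIAL_COLUMNS, TrialRecord, records_to_frame
from .fitting import DataError

_ENUMS = {
    "phase": {"train", "test"},
    "stage1_option": {"free", "forced"},
    "stage2_action": {"a1", "a2"},
    "displayed_target": {"a1", "a2"},
}


def write_trial_log(log, path) -> None:
    df = log if isinstance(log, pd.DataFrame) else records_to_frame(list(log))
    df.to_csv(path, index=False)


def read_trial_log(path) -> list[TrialRecord]:
    """Read and validate a trial-log CSV; errors carry the 0-based data
    row index."""
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        for col, allowed in _ENUMS.items():
            val = getattr(row, col)
            if val not in allowed:
                raise DataError(
                    f"{path}: row {i}: bad {col}={val!r} "
                    f"(expected one of {sorted(allowed)})")
        if int(row.reward) not in (0, 1):
            raise DataError(f"{path}: row {i}: reward must be 0 or 1")
        if bool(row.coherent) != (row.stage2_action == row.displayed_target):
            raise DataError(
                f"{path}: row {i}: coherent flag inconsistent with "
                f"stage2_action/displayed_target")
        try:
            records.append(TrialRecord(
                subject_id=str(row.subject_id),
                experiment=str(row.experiment),
                block_index=int(row.block_index),
                phase=str(row.phase),
                trial_index=int(row.trial_index),
                stage1_option=str(row.stage1_option),
                stage1_is_choice=bool(row.stage1_is_choice),
                stage2_action=str(row.stage2_action),
                displayed_target=str(row.displayed_target),
                coherent=bool(row.coherent),
                reward=int(row.reward)))
        except ValueError as err:
            raise DataError(f"{path}: row {i}: {err}") from err
    return records


def read_trial_frame(path) -> pd.DataFrame:
    """Validated log as a DataFrame (same checks as read_trial_log)."""
    return records_to_frame(read_trial_log(path))


@dataclass
class RunManifest:
    """Provenance record written next to every command's outputs."""

    command: str
    seed: int
    config: str = ""
    version: str = ""
    started: str = ""
    finished: str = ""
    outputs: list[str] = field(default_factory=list)

    @staticmethod
    def now() -> str:
        return datetime.now(timezone.utc).isoformat()

    def write(self, out_dir) -> Path:
        from . import __version__
        self.version = self.version or __version__
        self.finished = self.finished or self.now()
        path = Path(out_dir) / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)
        return path
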