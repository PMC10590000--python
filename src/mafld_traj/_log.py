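"""Machine-readable JSON-lines run log.

Deliberately timestamp-free so repeated runs with the same config and seed
produce byte-identical logs.
"""
from __future__ import annotations

import json
import pathlib


class RunLog:
    def __init__(self, path=None):
        self.path = pathlib.Path(path) if path is not None else None
        self.records: list[dict] = []
        if self.path is not None:
            self.path.parent.mkdir(parents=True, exist_ok=True)
            self.path.write_text("")

    def log(self, stage: str, event: str, **params) -> dict:
        record = {"stage": stage, "event": event, **params}
        self.records.append(record)
        if self.path is not None:
            with open(self.path, "a") as fh:
                fh.write(json.dumps(record, sort_keys=True, default=str) + "\n")
        return record

    @staticmethod
    def read(path) -> list[dict]:
        with open(path) as fh:
            return [json.loads(line) for line in fh if line.strip()]
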