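"""Ground-truth records shipped alongside every synthetic fixture."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


@dataclass
class GroundTruth:
    """True parameters of a generated fixture.

    ``kind`` names the generator ('lfp', 'ic', 'image', 'plate');
    ``data`` holds the generator-specific truth (burst times, AP times,
    cell centers, branch graphs, analyte concentrations, ...).
    """

    kind: str
    data: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.data[key]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"kind": self.kind, "data": _jsonable(self.data)}, indent=1)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(kind=payload["kind"], data=payload["data"])
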