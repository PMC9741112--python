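"""Global run configuration shared by the CLI commands.

A single JSON file can fix the pipeline parameters
(``{"t_f": 0.1, "t_d": 0.5, "filter_rule": "text_consistent",
"dialect": "plane_distance", "t_f_strict_factor": 0.5,
"iou_threshold": 0.5, "seed": 0}``); individual CLI flags override it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

log = logging.getLogger("depthprop")


@dataclass
class RunConfig:
    t_f: float = 0.1
    t_d: float = 0.5
    filter_rule: str = "text_consistent"
    dialect: str = "piecewise"
    t_f_strict_factor: float = 0.5
    iou_threshold: float = 0.5
    seed: int = 0

    @classmethod
    def load(cls, path: str | Path | None) -> "RunConfig":
        if path is None:
            return cls()
        d = json.loads(Path(path).read_text())
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def override(self, **kwargs) -> "RunConfig":
        d = asdict(self)
        d.update({k: v for k, v in kwargs.items() if v is not None})
        return RunConfig(**d)

    def log_params(self, command: str) -> None:
        log.info("%s parameters: %s", command, asdict(self))
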