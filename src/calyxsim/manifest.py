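"""Run manifests: config snapshot + seeds + outputs, enough to reproduce a run."""

from __future__ import annotations

import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

from .config import SimConfig


@dataclass
class RunManifest:
    """Provenance record written next to every experiment's outputs."""

    config: SimConfig
    seeds: dict[str, int]
    software_version: str = ""
    stage_runtimes_s: dict[str, float] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.software_version:
            from . import __version__

            self.software_version = __version__

    def add_output(self, path: str | Path) -> None:
        self.outputs.append(str(path))

    def time_stage(self, name: str):
        """Context manager recording a stage's wall-clock runtime."""
        manifest = self

        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                manifest.stage_runtimes_s[name] = round(
                    time.perf_counter() - self.t0, 3
                )
                return False

        return _Timer()

    def to_dict(self) -> dict:
        return {
            "config": self.config.model_dump(mode="json"),
            "seeds": self.seeds,
            "software_version": self.software_version,
            "python": platform.python_version(),
            "stage_runtimes_s": self.stage_runtimes_s,
            "outputs": self.outputs,
            "extra": self.extra,
        }

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if str(path) not in self.outputs:
            self.add_output(path)
        path.write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        m = cls(
            config=SimConfig.model_validate(d["config"]),
            seeds={k: int(v) for k, v in d["seeds"].items()},
            software_version=d.get("software_version", ""),
            stage_runtimes_s=d.get("stage_runtimes_s", {}),
            outputs=d.get("outputs", []),
            extra=d.get("extra", {}),
        )
        return m
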