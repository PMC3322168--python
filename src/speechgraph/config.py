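"""Run configuration: one JSON-serializable object per pipeline run.

Every CLI invocation resolves its options into a :class:`RunConfig`,
writes it (with the package version and a content hash) next to its
outputs, and logs the seed — so any result on disk can be traced back to
the exact settings that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional


@dataclass
class RunConfig:
    open_marker: str = "["
    close_marker: str = "]"
    separator: str = "/"
    lexeme_map_path: Optional[str] = None
    deviation_convention: str = "either"  # either | source | target
    normalize: bool = True
    cv_scheme: str = "loo"  # loo | stratified
    cv_folds: int = 5
    seed: int = 0
    features: dict[str, list[str]] = field(default_factory=dict)
    outdir: str = "."

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode("utf-8")).hexdigest()[:12]

    def write_resolved(self, outdir: str | Path, version: str) -> Path:
        """Record the resolved config, version and hash in the output dir."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        payload = dataclasses.asdict(self)
        payload["speechgraph_version"] = version
        payload["config_hash"] = self.config_hash()
        path = outdir / "run_config.json"
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                        encoding="utf-8")
        return path
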