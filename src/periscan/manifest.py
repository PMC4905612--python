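"""Run manifests: everything needed to re-run a command bit-identically."""

from __future__ import annotations

import hashlib
import json
import sys
from datetime import datetime, timezone
from pathlib import Path

from . import __version__

__all__ = ["RunManifest"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """Collects command, parameters, seeds, input digests and outputs."""

    def __init__(self, command: str, params: dict, seed: int | None = None) -> None:
        self.data: dict = {
            "tool": "periscan",
            "version": __version__,
            "command": command,
            "argv": sys.argv,
            "params": params,
            "seed": seed,
            "started": datetime.now(timezone.utc).isoformat(),
            "inputs": {},
            "outputs": [],
        }

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        self.data["inputs"][str(p)] = _sha256(p)

    def add_output(self, path: str | Path) -> None:
        self.data["outputs"].append(str(path))

    def write(self, directory: str | Path) -> Path:
        self.data["finished"] = datetime.now(timezone.utc).isoformat()
        out = Path(directory) / "run_manifest.json"
        out.write_text(json.dumps(self.data, indent=1, default=str))
        return out
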