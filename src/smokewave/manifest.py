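"""Reproducible run manifests: config hash, input/output checksums, stages."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

__all__ = ["sha256_file", "sha256_text", "RunManifest"]


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


class RunManifest:
    """Accumulates what a run consumed and produced, then writes JSON."""

    def __init__(self, version: str, seed: int | None, config_hash: str | None):
        self.data: dict = {
            "tool": "smokewave",
            "version": version,
            "seed": seed,
            "config_sha256": config_hash,
            "inputs": {},
            "stages": [],
            "outputs": {},
        }

    def add_input(self, path) -> None:
        p = Path(path)
        self.data["inputs"][p.name] = sha256_file(p)

    def add_stage(self, name: str, outputs: list) -> None:
        self.data["stages"].append(name)
        for path in outputs:
            p = Path(path)
            self.data["outputs"][f"{name}/{p.name}"] = sha256_file(p)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)
            fh.write("\n")
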