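"""Run manifests: provenance records written alongside every output set."""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path


@dataclass
class RunManifest:
    """What produced an output directory: command, config, seed, software
    version, timestamp and input checksums.  Re-running with the same
    manifest reproduces deterministic outputs bit for bit and stochastic
    outputs identically given the seed."""

    command: str
    config_path: str | None
    seed: int | None
    output_dir: str
    version: str
    timestamp: str = ""
    input_checksums: dict[str, str] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
        return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(command: str, output_dir: str | Path,
                   config_path: str | Path | None = None,
                   seed: int | None = None,
                   extra_inputs: list[Path] | None = None) -> RunManifest:
    from . import __version__

    checksums = {}
    inputs = list(extra_inputs or [])
    if config_path is not None:
        inputs.insert(0, Path(config_path))
    for p in inputs:
        p = Path(p)
        if p.exists():
            checksums[p.name] = _sha256(p)
    return RunManifest(
        command=command,
        config_path=str(config_path) if config_path else None,
        seed=seed,
        output_dir=str(output_dir),
        version=__version__,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        input_checksums=checksums,
    )
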