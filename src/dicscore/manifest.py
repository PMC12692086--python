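"""Run manifests: a JSON record of what a CLI command did.

Each output directory gets exactly one ``manifest.json`` describing the
command, its configuration hash, the seed, inputs and outputs, and the
package version.  The manifest carries a timestamp and is therefore the
one file not expected to be byte-identical between reruns; all data
outputs of deterministic commands are.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

from . import __version__

MANIFEST_NAME = "manifest.json"


def _hash_obj(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_manifest(
    out_dir: Path,
    command: str,
    seed: Optional[int],
    inputs: Sequence[str],
    outputs: Sequence[str],
    config: Optional[dict] = None,
) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config_hash": _hash_obj(config) if config is not None else None,
        "seed": seed,
        "inputs": list(map(str, inputs)),
        "outputs": list(map(str, outputs)),
        "package_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    path = out_dir / MANIFEST_NAME
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
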