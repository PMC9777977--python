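"""Report helpers: table rounding and run manifests.

All report rounding is half-away-from-zero (the convention behind printed
two-decimal tables) and happens only at serialization time; analysis code
keeps full precision throughout.
"""

from __future__ import annotations

import hashlib
import json
import time
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any, Iterable, Mapping


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half-away-from-zero (0.005 -> 0.01, -0.005 -> -0.01)."""
    if value is None:
        return value
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    params: Mapping[str, Any],
    inputs: Iterable[str | Path] = (),
    seed: int | None = None,
) -> Path:
    """Write a run manifest (command, parameter hash, input digests, seed)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = {k: v for k, v in sorted(params.items())}
    manifest = {
        "command": command,
        "params": params,
        "config_hash": hashlib.sha256(
            json.dumps(params, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "inputs": {str(p): file_digest(p) for p in inputs},
        "version": __version__,
        "seed": seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
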