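"""Small shared helpers: named seed substreams and run manifests."""

from __future__ import annotations

import hashlib
import json
import zlib
from datetime import datetime, timezone
from pathlib import Path


def substream(seed: int, name: str) -> int:
    """Derive a reproducible per-stage seed (< 2^31) from a master seed."""
    import numpy as np

    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] >> 1)


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, subcommand: str, params: dict, inputs: dict) -> None:
    """Record the exact invocation so a run can be reproduced bit-for-bit."""
    from . import __version__

    manifest = {
        "subcommand": subcommand,
        "parameters": params,
        "input_checksums": {
            name: file_checksum(p) for name, p in inputs.items() if p and Path(p).exists()
        },
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
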