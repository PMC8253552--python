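"""Atomic file writing and run provenance records."""

from __future__ import annotations

import json
import os
import tempfile
from datetime import datetime, timezone
from pathlib import Path

__all__ = ["atomic_write", "write_provenance"]


def atomic_write(path, write_fn) -> None:
    """Call ``write_fn(temp_path)`` then rename onto ``path``.

    Output files never exist half-written: crashes leave the target
    untouched.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(
        dir=path.parent, prefix=f".{path.name}.", suffix=".tmp"
    )
    os.close(fd)
    try:
        write_fn(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_provenance(path, subcommand: str, params: dict) -> None:
    """Machine-readable record of a run: version, subcommand, parameters
    and timestamp."""
    from . import __version__

    record = {
        "tool": "rotspeaks",
        "version": __version__,
        "subcommand": subcommand,
        "parameters": {k: _jsonable(v) for k, v in params.items()},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    atomic_write(
        path,
        lambda tmp: Path(tmp).write_text(json.dumps(record, indent=2) + "\n"),
    )


def _jsonable(value):
    if isinstance(value, (str, int, float, bool)) or value is None:
        return value
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    if isinstance(value, dict):
        return {str(k): _jsonable(v) for k, v in value.items()}
    return str(value)
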