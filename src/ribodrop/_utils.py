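"""Small shared helpers: seed fan-out, validation."""

from __future__ import annotations

import hashlib

from ribodrop.errors import ConfigError

MAX_SEED = 2**31


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed from one global seed.

    Uses SHA-256 of ``"<seed>:<stage>"`` so re-running a single stage gets the
    same stream regardless of which other stages ran. The result is < 2**31.
    """
    digest = hashlib.sha256(f"{int(global_seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % MAX_SEED


def require(condition: bool, field: str, message: str) -> None:
    """Raise :class:`ConfigError` naming ``field`` unless ``condition`` holds."""
    if not condition:
        raise ConfigError(f"{field}: {message}")
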