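"""Deterministic seed fan-out.

Every stochastic stage derives its seed from the master seed plus a stable
string key, so reruns with the same config are bit-identical regardless of
iteration order.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(master_seed: int, *key_parts: object) -> int:
    """Derive a 63-bit child seed from ``master_seed`` and a stable key.

    Uses SHA-256 of the textual key, not Python's ``hash`` (which is
    salted per process and therefore not reproducible).
    """
    key = "\x1f".join([str(int(master_seed))] + [str(p) for p in key_parts])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") >> 1
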