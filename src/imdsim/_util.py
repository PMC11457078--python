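"""Small shared helpers (seed splitting)."""

from __future__ import annotations

import hashlib

__all__ = ["split_seed"]


def split_seed(seed: int, *labels) -> int:
    """Derive a child seed from a master seed and a stream label.

    The derivation hashes ``"seed|label|label..."`` with SHA-256 and
    keeps 31 bits, so every component (environment generation, walk
    batches, resampling, ...) gets an independent, reproducible stream:
    adding walks to one stage never perturbs the draws of another.
    """
    text = "|".join([str(int(seed))] + [str(x) for x in labels])
    digest = hashlib.sha256(text.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
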