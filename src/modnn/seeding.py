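"""Deterministic seed derivation.

One experiment seed fans out into per-component seeds by hashing the seed
together with a component path (e.g. ``("encoder", "go")`` or
``("run", 17)``), so repeated runs and re-orderings of independent components
reproduce exactly.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(seed: int, *tokens: object) -> int:
    """A stable child seed in [0, 2^31) from a root seed and a token path."""
    key = repr((int(seed),) + tuple(tokens)).encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
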