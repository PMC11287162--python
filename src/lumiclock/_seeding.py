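"""Stable derivation of per-stage / per-well seeds from a single root seed.

Seeds are derived by hashing the root seed together with string labels, so
adding a well or a stage never perturbs the random stream of any other.
"""

from __future__ import annotations

import hashlib


def derive_seed(root_seed: int, *labels: object) -> int:
    """Derive a deterministic 31-bit seed from a root seed and labels."""
    key = repr((int(root_seed),) + tuple(str(x) for x in labels)).encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:4], "little") & 0x7FFFFFFF
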