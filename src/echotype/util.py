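"""Small shared helpers."""

from __future__ import annotations

import hashlib


def derive_seed(seed: int, stage: str) -> int:
    """Deterministically fan a global seed out to a per-stage seed (< 2^31).

    Stages (e.g. ``"ae-fold0"``, ``"augment-fold2"``) get independent,
    reproducible streams so any stage can be re-run in isolation.
    """
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
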