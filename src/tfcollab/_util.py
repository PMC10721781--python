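"""Small shared helpers: seeded stream derivation and file checksums."""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np


def derive_rng(seed: int, *labels: str) -> np.random.Generator:
    """Derive an independent, reproducible random stream from a root seed.

    Each (seed, labels) combination yields its own stream so that partial
    regeneration of artifacts does not perturb unrelated ones.
    """
    digest = hashlib.sha256("/".join(labels).encode()).digest()
    # fold the label digest into extra entropy words (kept below 2**31 each)
    words = [int.from_bytes(digest[i : i + 4], "big") % (2**31) for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *words]))


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(path: str | Path, obj) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
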