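"""Shared helpers: seeded random streams and input validation."""

from __future__ import annotations

import numpy as np

#: named sub-streams fanned out from one global seed so each generator can be
#: re-run independently and still reproduce byte-identical output.
STREAMS = (
    "samples",
    "controls",
    "signals",
    "panel",
    "metadata",
    "models",
    "effects",
)


def substream(seed: int, name: str) -> np.random.Generator:
    """Return the named child generator of a global seed.

    One global seed fans out to per-stream sub-seeds via ``SeedSequence.spawn``
    so that, e.g., regenerating metadata does not perturb the signal draws.
    """
    if name not in STREAMS:
        raise KeyError(f"unknown stream {name!r}; expected one of {STREAMS}")
    root = np.random.SeedSequence(int(seed))
    children = root.spawn(len(STREAMS))
    return np.random.default_rng(children[STREAMS.index(name)])


def check_positive(value: float, name: str) -> None:
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be finite and > 0, got {value!r}")


def check_fraction(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
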