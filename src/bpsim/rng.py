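"""Named random-number streams derived from one master seed.

Every stochastic component of a simulation (founder sampling, trait effect
sampling, phenotyping noise, meiosis, selection tie-breaking) draws from its
own generator, all spawned deterministically from a single master seed, so
that a whole scenario is reproducible from one integer.
"""

from __future__ import annotations

import numpy as np

#: fixed stream order; changing it would silently change all simulations
_STREAMS = ("founders", "traits", "phenotypes", "meiosis", "selection", "misc")


class RngHub:
    """Per-purpose random generators spawned from a master seed."""

    def __init__(self, master_seed: int):
        self.master_seed = int(master_seed)
        children = np.random.SeedSequence(self.master_seed).spawn(len(_STREAMS))
        self._gens = {
            name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)
        }

    def __getitem__(self, name: str) -> np.random.Generator:
        try:
            return self._gens[name]
        except KeyError:
            raise KeyError(
                f"unknown rng stream {name!r}; available: {', '.join(_STREAMS)}"
            ) from None

    def __repr__(self) -> str:  # pragma: no cover
        return f"RngHub(master_seed={self.master_seed})"


def as_rng(seed_or_rng) -> np.random.Generator:
    """Coerce an int seed, Generator, or None into a Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
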