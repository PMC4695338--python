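"""Shared helpers: seeded substreams and logging."""

from __future__ import annotations

import logging
import zlib

import numpy as np

logger = logging.getLogger("ieskit")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Return a Generator for one named pipeline stage.

    A single user-facing seed is expanded into independent substreams keyed
    by stage name, so regenerating one stage (e.g. a second new-MAC sample)
    does not perturb the stream of any other stage.
    """
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
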