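"""Named, independent random substreams derived from one global seed.

Every stochastic stage (simulation, label permutation, peptide permutation)
draws from its own generator keyed by a stable string label, so toggling or
reordering one stage never perturbs the draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _label_key(label: str) -> int:
    # crc32 is stable across platforms and Python versions (unlike hash()).
    return zlib.crc32(label.encode("utf-8"))


def substream(seed: int, *labels: str) -> np.random.Generator:
    """Return a Generator for the substream named by ``labels`` under ``seed``."""
    keys = [_label_key(lab) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence([int(seed), *keys]))
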