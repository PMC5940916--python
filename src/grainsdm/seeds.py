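"""Deterministic sub-seed derivation.

Every stage and replicate derives its own seed from the master seed via a
counter scheme, so stages are independently re-runnable and the whole
study is reproducible from one integer.
"""

from __future__ import annotations

import numpy as np


def subseed(master_seed: int, *counters: int) -> int:
    """Derive a child seed < 2**31 from a master seed and counter indices."""
    ss = np.random.SeedSequence((int(master_seed),) + tuple(int(c) for c in counters))
    return int(ss.generate_state(1)[0] % (2 ** 31))
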