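"""Shared tiny Markov model for signal/assembler tests."""

import numpy as np

from selenoscan.coding_model import MarkovModel

_CACHE = {}


def toy_model(k: int = 1) -> MarkovModel:
    """Deterministic small model with mild coding/noncoding contrast."""
    if k not in _CACHE:
        rng = np.random.default_rng(777)
        nctx = 4 ** k
        coding = rng.dirichlet(np.ones(4) * 4, size=(3, nctx))
        noncoding = rng.dirichlet(np.ones(4) * 4, size=nctx)
        _CACHE[k] = MarkovModel(k=k, coding=np.log2(coding),
                                noncoding=np.log2(noncoding))
    return _CACHE[k]
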