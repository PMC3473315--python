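"""3-periodic Markov coding model vs homogeneous noncoding background.

The coding potential of an exon is the sum of its boundary signal scores and
the log-likelihood ratio (LLR, log base 2) of this model over the exon
sequence.  The coding chain is inhomogeneous with period 3: one transition
table per codon phase, where the phase of a base is its position within its
codon (0 = first codon position).  The noncoding chain is homogeneous.
Contexts are the preceding k bases and may cross codon boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_ENC = np.full(256, 4, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _ENC[ord(_b)] = _i


class TrainingError(ValueError):
    pass


def encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3; anything else (N) -> 4."""
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class MarkovModel:
    """Order-k Markov model pair (coding, 3-periodic; noncoding, homogeneous).

    coding: (3, 4**k, 4) log2 conditional probabilities, axis 0 = phase of
    the emitted base; noncoding: (4**k, 4) log2 probabilities.
    """

    k: int
    coding: np.ndarray
    noncoding: np.ndarray
    pseudocount: float = 1.0

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("order k must be >= 0")
        nctx = 4 ** self.k
        assert self.coding.shape == (3, nctx, 4)
        assert self.noncoding.shape == (nctx, 4)

    def validate(self, tol: float = 1e-9) -> None:
        """Conditional probabilities must sum to 1 for every context/phase."""
        for phase in range(3):
            s = np.exp2(self.coding[phase]).sum(axis=1)
            if not np.allclose(s, 1.0, atol=tol):
                raise ValueError(f"coding phase {phase} rows do not sum to 1")
        s = np.exp2(self.noncoding).sum(axis=1)
        if not np.allclose(s, 1.0, atol=tol):
            raise ValueError("noncoding rows do not sum to 1")

    # -- serialization ------------------------------------------------------
    def to_text(self) -> str:
        return json.dumps({
            "format": "selenoscan-markov-1",
            "k": self.k,
            "pseudocount": self.pseudocount,
            "coding_log2": self.coding.tolist(),
            "noncoding_log2": self.noncoding.tolist(),
        })

    @classmethod
    def from_text(cls, text: str) -> "MarkovModel":
        d = json.loads(text)
        if d.get("format") != "selenoscan-markov-1":
            raise ValueError("not a selenoscan Markov model file")
        return cls(k=d["k"],
                   coding=np.array(d["coding_log2"], dtype=float),
                   noncoding=np.array(d["noncoding_log2"], dtype=float),
                   pseudocount=d["pseudocount"])

    def save(self, path) -> None:
        Path(path).write_text(self.to_text())

    @classmethod
    def load(cls, path) -> "MarkovModel":
        return cls.from_text(Path(path).read_text())


def _context_indices(x: np.ndarray, k: int) -> np.ndarray:
    """Context index of each position (preceding k bases, base-4 encoded).

    Positions with incomplete or N-containing context get -1.
    """
    n = len(x)
    ctx = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(1, k + 1):
        prev = np.full(n, 4, dtype=np.int8)
        prev[j:] = x[:-j] if j else x
        bad |= prev == 4
        ctx = ctx + np.where(prev == 4, 0, prev).astype(np.int64) * (4 ** (j - 1))
    # note: context order is prev1 + 4*prev2 + ...; any fixed bijection works
    ctx[bad] = -1
    ctx[:k] = -1
    return ctx


def train_markov(coding_seqs, noncoding_seqs, k: int = 5,
                 pseudocount: float = 1.0) -> MarkovModel:
    """Maximum-likelihood tables with an additive pseudocount.

    Coding sequences must be in-frame CDS (length divisible by 3); Sec-TGA
    codons are counted like any other coding triplet.  The first k bases of
    each sequence contribute no transition (no full context).
    """
    if not coding_seqs or not noncoding_seqs:
        raise TrainingError("empty training set")
    nctx = 4 ** k
    ccounts = np.full((3, nctx, 4), pseudocount, dtype=float)
    ncounts = np.full((nctx, 4), pseudocount, dtype=float)
    for seq in coding_seqs:
        if len(seq) % 3:
            raise TrainingError(f"CDS length {len(seq)} not divisible by 3")
        x = encode(seq)
        ctx = _context_indices(x, k)
        pos = np.arange(len(x))
        valid = (ctx >= 0) & (x != 4)
        phases = pos % 3
        for phase in range(3):
            m = valid & (phases == phase)
            np.add.at(ccounts[phase], (ctx[m], x[m].astype(np.int64)), 1.0)
    for seq in noncoding_seqs:
        x = encode(seq)
        ctx = _context_indices(x, k)
        valid = (ctx >= 0) & (x != 4)
        np.add.at(ncounts, (ctx[valid], x[valid].astype(np.int64)), 1.0)
    coding = np.log2(ccounts / ccounts.sum(axis=2, keepdims=True))
    noncoding = np.log2(ncounts / ncounts.sum(axis=1, keepdims=True))
    return MarkovModel(k=k, coding=coding, noncoding=noncoding,
                       pseudocount=pseudocount)


def score_llr(model: MarkovModel, seq: str, phase: int = 0,
              context: str = "") -> float:
    """LLR (bits) of `seq` whose first base has codon phase `phase`.

    `context` supplies up to k preceding bases so that scoring is additive
    over concatenation: score(s1 + s2) = score(s1) + score(s2, shifted
    phase, context=s1[-k:]).  Without context the first k positions are
    skipped (no full context available).  N positions contribute 0.
    """
    if phase not in (0, 1, 2):
        raise ValueError("phase must be 0, 1 or 2")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"illegal characters {sorted(bad)}")
    full = context[-model.k:] + seq if model.k else seq
    off = len(full) - len(seq)
    x = encode(full)
    ctx = _context_indices(x, model.k)
    total = 0.0
    for i in range(off, len(full)):
        if x[i] == 4 or ctx[i] < 0:
            continue
        ph = (phase + (i - off)) % 3
        total += (model.coding[ph, ctx[i], x[i]]
                  - model.noncoding[ctx[i], x[i]])
    return float(total)


def llr_track(model: MarkovModel, x: np.ndarray) -> np.ndarray:
    """Per-base LLR for all 3 codon-start offset classes, vectorised.

    track[o, i] = LLR contribution of base i when codons start at positions
    congruent to o (mod 3), i.e. the base's phase is (i - o) mod 3.
    Positions without a clean context (first k, or N in context/base)
    contribute 0 -- the "N scores as background" rule.  Cumulative sums of
    these tracks give exon LLRs in O(1) per candidate.
    """
    n = len(x)
    ctx = _context_indices(x, model.k)
    valid = (ctx >= 0) & (x != 4)
    xi = np.where(valid, x, 0).astype(np.int64)
    ci = np.where(valid, ctx, 0)
    non = model.noncoding[ci, xi]
    track = np.zeros((3, n))
    pos = np.arange(n)
    for o in range(3):
        ph = (pos - o) % 3
        cod = model.coding[ph, ci, xi]
        track[o] = np.where(valid, cod - non, 0.0)
    return track


def sample_from_model(model: MarkovModel, length: int, rng,
                      coding: bool = True, phase0: int = 0) -> str:
    """Draw a sequence from the coding (3-periodic) or noncoding chain."""
    k = model.k
    if coding:
        cdf = np.cumsum(np.exp2(model.coding), axis=2)
        cdf /= cdf[:, :, -1:]
    else:
        cdf = np.cumsum(np.exp2(model.noncoding), axis=1)
        cdf /= cdf[:, -1:]
    u = rng.random(length)
    out = np.empty(length, dtype=np.int64)
    # burn in the context uniformly; ctx = prev1 + 4*prev2 + ...
    ctx_bases = list(rng.integers(0, 4, size=k))
    idx = 0
    for j in range(1, k + 1):
        idx += int(ctx_bases[-j]) * (4 ** (j - 1))
    top = 4 ** (k - 1) if k >= 1 else 1
    for i in range(length):
        row = cdf[(phase0 + i) % 3, idx] if coding else cdf[idx]
        b = min(int(np.searchsorted(row, u[i], side="right")), 3)
        out[i] = b
        if k >= 1:
            idx = b + 4 * (idx % top)
    return "".join(BASES[b] for b in out)
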