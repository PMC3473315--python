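"""Gene-signal scanning and typed exon-candidate enumeration.

Signals are ATG starts, TAA/TAG stops, GT donors, AG acceptors and in-frame
TGA codons, each scored with a position weight matrix (log-odds in bits vs a
uniform background).  Exon candidates of all four kinds (initial, internal,
terminal, single) are built from compatible signal pairs; an exon may
contain in-frame TGA codons (recorded, never rejected) but no in-frame
TAA/TAG.  The coding potential of a candidate is the sum of its boundary
signal scores and the Markov log-likelihood ratio of its sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .coding_model import MarkovModel, encode, llr_track
from .genome_io import GenomeRecord, Interval, ValidationError

SIGNAL_KINDS = ("start", "stop", "donor", "acceptor", "tga")

# core motif and anchor semantics per kind; the anchor is the position of the
# first core base; exons abut donors at d (exclusive) and acceptors at a+2
_CORE = {"start": ("ATG",), "stop": ("TAA", "TAG"), "donor": ("GT",),
         "acceptor": ("AG",), "tga": ("TGA",)}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PWM:
    """Probability matrix over a window anchored at the signal core.

    probs has shape (window, 4) over A,C,G,T; offset0 is the window offset of
    the anchor (so window column j corresponds to genomic anchor - offset0 + j).
    """

    kind: str
    offset0: int
    probs: np.ndarray

    def __post_init__(self):
        s = self.probs.sum(axis=1)
        if not np.allclose(s, 1.0, atol=1e-9):
            raise ValidationError(f"PWM {self.kind} columns do not sum to 1")

    @property
    def window(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probs / 0.25)


@dataclass
class SignalModel:
    """One PWM per signal kind."""

    pwms: dict

    def __post_init__(self):
        missing = set(SIGNAL_KINDS) - set(self.pwms)
        if missing:
            raise ValidationError(f"missing PWMs for {sorted(missing)}")


@dataclass(frozen=True)
class SignalSite:
    kind: str
    pos: int          # anchor: first base of the core motif
    score: float

    def interval(self, seqid: str, strand: str = "+") -> Interval:
        return Interval(seqid, self.pos, self.pos + len(_CORE[self.kind][0]),
                        strand)


@dataclass(frozen=True)
class ExonCandidate:
    interval: Interval
    kind: str                  # initial | internal | terminal | single
    frame5: int                # codon phase of the first base
    frame3: int                # codon phase of the base after the exon
    has_inframe_tga: bool
    tga_offsets: tuple         # codon offsets of in-frame TGAs within the exon
    coding_potential: float

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(frozen=True)
class ExonLimits:
    min_exon: int = 30
    max_exon: int = 6000
    min_intron: int = 40
    min_coding_potential: float | None = None
    max_per_mb: int = 50000

    def __post_init__(self):
        if self.min_exon > self.max_exon:
            raise ConfigError("min_exon > max_exon")
        if self.min_exon < 3 or self.min_intron < 4:
            raise ConfigError("degenerate length limits")


# ---------------------------------------------------------------------------
# default signal profiles
#
# The paper-scale method delegates signal scoring to a gene finder; here the
# package ships loose eukaryotic consensus profiles (Kozak-like start
# context, canonical GT/AG splice profiles with a polypyrimidine tract).
# The synthetic generator samples its planted sites from these same
# profiles, and train_signal_model lets a user re-estimate them.

def _profile(consensus, strengths):
    """Build a probability matrix from a consensus string and column weights.

    Each column puts `strength` mass on the consensus base (split evenly for
    IUPAC pairs) and the rest uniformly; '.' columns are uniform.
    """
    iupac = {"A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
             "M": "AC", "W": "AT", "S": "CG", "K": "GT"}
    rows = []
    for ch, w in zip(consensus, strengths):
        row = np.full(4, 0.25)
        if ch != ".":
            bases = iupac[ch]
            row = np.full(4, (1.0 - w) / (4 - len(bases)))
            for b in bases:
                row["ACGT".index(b)] = w / len(bases)
        rows.append(row)
    return np.array(rows)


def default_signal_model() -> SignalModel:
    # start context is genuinely weak (Kozak-like, ~3 bits); splice sites
    # are strongly constrained (donor ~6 bits, acceptor ~9 bits beyond the
    # GT/AG core), matching canonical eukaryotic site strength
    start = PWM("start", 6, _profile(
        "GCCACCATGG..",
        [0.4, 0.5, 0.5, 0.55, 0.5, 0.5, 0.97, 0.97, 0.97, 0.55, 0.25, 0.25]))
    donor = PWM("donor", 3, _profile(
        "MAGGTAAGT", [0.55, 0.65, 0.8, 0.97, 0.97, 0.65, 0.75, 0.85, 0.55]))
    acceptor = PWM("acceptor", 15, _profile(
        "YYYYYYYYYYYY.YCAGG",
        [0.8, 0.8, 0.8, 0.8, 0.8, 0.8, 0.8, 0.8, 0.8, 0.8, 0.8, 0.8,
         0.25, 0.75, 0.7, 0.97, 0.97, 0.5]))
    stop = PWM("stop", 0, _profile("TAR", [0.97, 0.97, 0.9]))
    tga = PWM("tga", 0, _profile("TGA", [0.97, 0.97, 0.97]))
    return SignalModel({p.kind: p for p in (start, stop, donor, acceptor, tga)})


def train_signal_model(windows_by_kind: dict, offsets: dict | None = None,
                       pseudocount: float = 1.0) -> SignalModel:
    """Estimate PWMs from aligned example windows (one string per site)."""
    defaults = default_signal_model()
    pwms = {}
    for kind in SIGNAL_KINDS:
        wins = windows_by_kind.get(kind)
        if not wins:
            pwms[kind] = defaults.pwms[kind]
            continue
        width = len(wins[0])
        counts = np.full((width, 4), pseudocount)
        for w in wins:
            if len(w) != width:
                raise ValidationError(f"ragged window for {kind}")
            x = encode(w)
            for j, b in enumerate(x):
                if b < 4:
                    counts[j, b] += 1
        probs = counts / counts.sum(axis=1, keepdims=True)
        off = (offsets or {}).get(kind, defaults.pwms[kind].offset0)
        pwms[kind] = PWM(kind, off, probs)
    return SignalModel(pwms)


# ---------------------------------------------------------------------------
# scanning

def _core_positions(x: np.ndarray, motifs) -> np.ndarray:
    hits = []
    for motif in motifs:
        m = encode(motif)
        mask = np.ones(len(x) - len(m) + 1, dtype=bool) \
            if len(x) >= len(m) else np.zeros(0, dtype=bool)
        for j, b in enumerate(m):
            mask &= x[j:len(x) - len(m) + 1 + j] == b
        hits.append(np.nonzero(mask)[0])
    return np.sort(np.concatenate(hits)) if hits else np.zeros(0, int)


def _score_sites(x: np.ndarray, positions: np.ndarray, pwm: PWM):
    """PWM scores at anchor positions.

    Windows truncated by a contig edge are scored over the in-range columns
    only; windows containing N are dropped entirely (N regions are scored
    as background and cannot host signals)."""
    if len(positions) == 0:
        return positions, np.zeros(0)
    w, off = pwm.window, pwm.offset0
    lo = pwm.log_odds
    idx = positions[:, None] - off + np.arange(w)[None, :]
    in_range = (idx >= 0) & (idx < len(x))
    bases = x[np.clip(idx, 0, len(x) - 1)]
    has_n = ((bases == 4) & in_range).any(axis=1)
    positions_out = positions[~has_n]
    bases = bases[~has_n]
    in_range = in_range[~has_n]
    col = np.broadcast_to(np.arange(w)[None, :], bases.shape)
    contrib = lo[col, np.clip(bases, 0, 3)]
    scores = np.where(in_range, contrib, 0.0).sum(axis=1)
    return positions_out, scores


def scan_signals(record: GenomeRecord, model: SignalModel | None = None
                 ) -> list[SignalSite]:
    """All signal occurrences on the given (forward) sequence, sorted by
    position.  Scan the reverse complement for the other strand."""
    model = model or default_signal_model()
    x = encode(record.seq)
    sites = []
    for kind in SIGNAL_KINDS:
        pos = _core_positions(x, _CORE[kind])
        pos, scores = _score_sites(x, pos, model.pwms[kind])
        sites.extend(SignalSite(kind, int(p), float(s))
                     for p, s in zip(pos, scores))
    sites.sort(key=lambda s: (s.pos, s.kind))
    return sites


# ---------------------------------------------------------------------------
# exon enumeration

def _ragged_pairs(lo, hi):
    """For ragged ranges [lo_i, hi_i) return (owner_index, flat_value)."""
    counts = np.maximum(hi - lo, 0)
    total = int(counts.sum())
    owners = np.repeat(np.arange(len(lo)), counts)
    cum = np.cumsum(counts) - counts
    within = np.arange(total) - np.repeat(cum, counts)
    return owners, np.repeat(lo, counts) + within


class _SignalArrays:
    """Positions/scores per kind, split by frame class where needed."""

    def __init__(self, sites_or_pairs, length):
        pos = {k: [] for k in SIGNAL_KINDS}
        score = {k: [] for k in SIGNAL_KINDS}
        for s in sites_or_pairs:
            pos[s.kind].append(s.pos)
            score[s.kind].append(s.score)
        self.pos = {k: np.asarray(v, dtype=np.int64) for k, v in pos.items()}
        self.score = {k: np.asarray(v, dtype=float) for k, v in score.items()}
        for k in SIGNAL_KINDS:
            order = np.argsort(self.pos[k], kind="stable")
            self.pos[k] = self.pos[k][order]
            self.score[k] = self.score[k][order]
        self.length = length
        # stop / TGA anchors by frame class (anchor mod 3)
        self.stop_by_class = [self.pos["stop"][self.pos["stop"] % 3 == o]
                              for o in range(3)]
        self.tga_by_class = [self.pos["tga"][self.pos["tga"] % 3 == o]
                             for o in range(3)]

    def stop_score_at(self, anchors):
        idx = np.searchsorted(self.pos["stop"], anchors)
        return self.score["stop"][idx]


def enumerate_exons(record: GenomeRecord, sites: Iterable[SignalSite],
                    coding: MarkovModel, limits: ExonLimits = ExonLimits()
                    ) -> list[ExonCandidate]:
    """All exon candidates buildable from the given signals.

    Emits, within the length limits: initial exons (ATG..donor), internal
    exons (acceptor..donor), terminal exons (acceptor..stop) and single
    exons (ATG..stop), in every reading phase, with no in-frame TAA/TAG
    internal to the reading and with in-frame TGAs recorded in tga_offsets.
    """
    x = encode(record.seq)
    track = llr_track(coding, x)
    cum = np.concatenate([np.zeros((3, 1)), np.cumsum(track, axis=1)], axis=1)
    arrays = _SignalArrays(sites, len(x))
    rows = _enumerate_rows(arrays, cum, limits)
    return _rows_to_candidates(record.id, arrays, rows, limits)


def _enumerate_rows(arr: _SignalArrays, cum, limits: ExonLimits):
    """Vectorised enumeration; returns a dict of flat numpy columns."""
    L = arr.length
    INF = L + 10
    out = {k: [] for k in ("start", "end", "kind", "frame5", "cp")}
    KINDS = {"initial": 0, "internal": 1, "terminal": 2, "single": 3}

    def emit(starts, ends, kind, frame5s, cps):
        out["start"].append(starts)
        out["end"].append(ends)
        out["kind"].append(np.full(len(starts), KINDS[kind], dtype=np.int8))
        out["frame5"].append(frame5s)
        out["cp"].append(cps)

    don_pos, don_score = arr.pos["donor"], arr.score["donor"]

    def next_stop(o, from_pos):
        so = arr.stop_by_class[o]
        idx = np.searchsorted(so, from_pos)
        ns = np.full(len(from_pos), INF, dtype=np.int64)
        has = idx < len(so)
        ns[has] = so[idx[has]]
        return ns

    def donor_bounded(starts, base_scores, frame5, o_arr, phase_is_const):
        """Emit donor-terminated exons from aligned start arrays."""
        pad = (3 - frame5) % 3
        ns = np.full(len(starts), INF, dtype=np.int64)
        for o in range(3):
            m = o_arr == o
            if m.any():
                ns[m] = next_stop(o, starts[m] + pad)
        dmax = np.minimum(starts + limits.max_exon, ns + 2)
        lo = np.searchsorted(don_pos, starts + limits.min_exon)
        hi = np.searchsorted(don_pos, dmax, side="right")
        owners, didx = _ragged_pairs(lo, hi)
        if len(owners) == 0:
            return (np.zeros(0, np.int64),) * 2 + (np.zeros(0),) * 1 + \
                (np.zeros(0, np.int8), np.zeros(0, np.int64))
        s = starts[owners]
        d = don_pos[didx]
        o_flat = o_arr[owners]
        llr = cum[o_flat, d] - cum[o_flat, s]
        cp = base_scores[owners] + don_score[didx] + llr
        f5 = np.full(len(s), frame5, dtype=np.int8)
        return s, d, cp, f5, owners

    # --- initial and single exons (from ATG; frame5 = 0) ------------------
    m_pos, m_score = arr.pos["start"], arr.score["start"]
    if len(m_pos):
        o_arr = (m_pos % 3).astype(np.int64)
        s, d, cp, f5, _ = donor_bounded(m_pos, m_score, 0, o_arr, True)
        emit(s, d, "initial", f5, cp)
        # single exons: end at the first in-frame stop
        ns = np.full(len(m_pos), INF, dtype=np.int64)
        for o in range(3):
            m = o_arr == o
            if m.any():
                ns[m] = next_stop(o, m_pos[m])
        ok = (ns < INF) & (ns + 3 - m_pos >= limits.min_exon) \
            & (ns + 3 - m_pos <= limits.max_exon)
        si, nsi = m_pos[ok], ns[ok]
        oi = o_arr[ok]
        llr = cum[oi, nsi] - cum[oi, si]
        cp = m_score[ok] + arr.stop_score_at(nsi) + llr
        emit(si, nsi + 3, "single", np.zeros(len(si), dtype=np.int8), cp)

    # --- internal and terminal exons (from acceptors) ----------------------
    a_pos, a_score = arr.pos["acceptor"], arr.score["acceptor"]
    if len(a_pos):
        starts = a_pos + 2
        for frame5 in range(3):
            pad = (3 - frame5) % 3
            o_arr = ((starts + pad) % 3).astype(np.int64)
            s, d, cp, f5, _ = donor_bounded(starts, a_score, frame5, o_arr,
                                            False)
            emit(s, d, "internal", f5, cp)
            # terminal exons
            ns = np.full(len(starts), INF, dtype=np.int64)
            for o in range(3):
                m = o_arr == o
                if m.any():
                    ns[m] = next_stop(o, starts[m] + pad)
            ok = (ns < INF) & (ns + 3 - starts >= limits.min_exon) \
                & (ns + 3 - starts <= limits.max_exon)
            st, nst = starts[ok], ns[ok]
            ot = o_arr[ok]
            llr = cum[ot, nst] - cum[ot, st]
            cp = a_score[ok] + arr.stop_score_at(nst) + llr
            emit(st, nst + 3, "terminal",
                 np.full(len(st), frame5, dtype=np.int8), cp)

    return {k: (np.concatenate(v) if v else np.zeros(0)) for k, v in out.items()}


_KIND_NAMES = ("initial", "internal", "terminal", "single")


def _rows_to_candidates(seqid, arr: _SignalArrays, rows, limits: ExonLimits
                        ) -> list[ExonCandidate]:
    starts = rows["start"].astype(np.int64)
    ends = rows["end"].astype(np.int64)
    kinds = rows["kind"].astype(np.int8)
    frame5s = rows["frame5"].astype(np.int8)
    cps = rows["cp"].astype(float)
    if limits.min_coding_potential is not None:
        keep = cps >= limits.min_coding_potential
        starts, ends, kinds, frame5s, cps = (
            a[keep] for a in (starts, ends, kinds, frame5s, cps))
    if limits.max_per_mb is not None and len(starts):
        cap = max(1, int(limits.max_per_mb * arr.length / 1e6))
        if len(starts) > cap:
            keep = np.argsort(-cps, kind="stable")[:cap]
            starts, ends, kinds, frame5s, cps = (
                a[keep] for a in (starts, ends, kinds, frame5s, cps))
    order = np.lexsort((cps, frame5s, kinds, ends, starts))
    cands = []
    for i in order:
        s, e = int(starts[i]), int(ends[i])
        kind = _KIND_NAMES[kinds[i]]
        f5 = int(frame5s[i])
        pad = (3 - f5) % 3
        o = (s + pad) % 3
        # coding part excludes the terminal stop codon
        coding_end = e - 3 if kind in ("terminal", "single") else e
        to = arr.tga_by_class[o]
        lo = np.searchsorted(to, s + pad)
        hi = np.searchsorted(to, coding_end - 2)
        # offset = index among the exon's full codons (split leading codon
        # excluded; it belongs to the upstream exon's reading)
        offs = tuple(int((p - s - pad) // 3) for p in to[lo:hi])
        f3 = (f5 + (e - s)) % 3
        cands.append(ExonCandidate(
            interval=Interval(seqid, s, e, "+"), kind=kind, frame5=f5,
            frame3=int(f3), has_inframe_tga=bool(offs), tga_offsets=offs,
            coding_potential=float(cps[i])))
    return cands
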