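"""SECIS element detection in 3' flanking sequence.

The model is the canonical eukaryotic SECIS topology: a lower helix
(helix I), an internal loop, an upper helix (helix II) whose first four
base pairs form the non-Watson-Crick quartet opening with UGA on the 5'
side, and an apical loop containing an unpaired AA.  The base immediately
preceding the quartet must be an unpaired A or G; it classifies the element
as AUGA_AA or GUGA_AA.  Scoring is a simple additive structural score:

    2 * (Watson-Crick pairs) + 1 * (GU pairs)
    - 0.5 * (loop nucleotides beyond the configured minima)
    + 3 (core-motif bonus)

which is deliberately not comparable to covariance-model scores.
All sequences are DNA (T for U); coordinates are window-local until
find_secis lifts them to the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .genome_io import GenomeRecord, Interval, ValidationError

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}


@dataclass(frozen=True)
class SECISParams:
    window: int = 3000              # nt scanned downstream of the stop codon
    helix1: tuple = (6, 16)         # bp
    helix2: tuple = (8, 18)         # bp, quartet included
    internal_loop: tuple = (1, 20)  # nt per side (5' side holds the A/G)
    apical_loop: tuple = (8, 22)    # nt, must contain AA
    allow_gu: bool = True
    min_score: float = 18.0

    def __post_init__(self):
        for lo, hi in (self.helix1, self.helix2, self.internal_loop,
                       self.apical_loop):
            if lo > hi or lo < 1:
                raise ValidationError("degenerate SECIS geometry range")
        if self.window <= 0:
            raise ValidationError("window must be positive")
        if self.helix2[0] < 5:
            raise ValidationError("helix II must extend beyond the quartet")


@dataclass(frozen=True)
class SECISHit:
    interval: Interval        # full stem-loop span, genome coordinates
    motif_class: str          # AUGA_AA | GUGA_AA
    quartet_pos: int          # genome coordinate of the UGA (quartet 5' start)
    helix1_pairs: int
    helix2_pairs: int
    apical_aa_pos: int        # genome coordinate of the AA in the apical loop
    score: float


def _pair_kind(a: str, b: str):
    if (a, b) in _WC:
        return "wc"
    if (a, b) in _GU:
        return "gu"
    return None


def _score_helix(seq, lo5, n, hi3, allow_gu, require_all=True):
    """Score n pairs between seq[lo5:lo5+n] and the reversed arm ending at
    hi3 (exclusive): position lo5+j pairs with hi3-1-j.  Returns
    (wc, gu) counts or None if a pair is neither WC nor (allowed) GU."""
    wc = gu = 0
    for j in range(n):
        kind = _pair_kind(seq[lo5 + j], seq[hi3 - 1 - j])
        if kind == "wc":
            wc += 1
        elif kind == "gu" and allow_gu:
            gu += 1
        else:
            return None
    return wc, gu


def fold_hairpin(window: str, params: SECISParams = SECISParams(),
                 origin: int = 0, seqid: str = "window", strand: str = "+",
                 enforce_min_score: bool = True):
    """Best-scoring SECIS-like stem-loop in `window`, or None.

    Enumerates every geometry within the configured ranges anchored on each
    TGA occurrence whose preceding base is A or G, checks the structural
    constraints (quartet non-WC, helices paired, AA in the apical loop) and
    returns the maximal-scoring candidate.  `origin` shifts reported
    coordinates (genome lift is origin + window offset).
    """
    best = None
    n = len(window)
    h1lo, h1hi = params.helix1
    h2lo, h2hi = params.helix2
    illo, ilhi = params.internal_loop
    aplo, aphi = params.apical_loop
    min_span = h1lo + illo + h2lo + aplo + h2lo + illo + h1lo
    if n < min_span:
        return None
    q = window.find("TGA", 1)
    while q != -1:
        pre = window[q - 1]
        if pre in "AG":
            cand = _best_at_anchor(window, q, params)
            if cand is not None and (best is None or cand[0] > best[0]):
                best = cand
        q = window.find("TGA", q + 1)
    if best is None:
        return None
    score, span5, span3, qpos, h1, h2, aapos, mclass = best
    if enforce_min_score and score < params.min_score:
        return None
    return SECISHit(
        interval=Interval(seqid, origin + span5, origin + span3, strand),
        motif_class=mclass, quartet_pos=origin + qpos, helix1_pairs=h1,
        helix2_pairs=h2, apical_aa_pos=origin + aapos, score=score)


def _best_at_anchor(window, q, params: SECISParams):
    """Best geometry with the quartet 5' side starting at TGA position q."""
    n = len(window)
    h1lo, h1hi = params.helix1
    h2lo, h2hi = params.helix2
    illo, ilhi = params.internal_loop
    aplo, aphi = params.apical_loop
    best = None
    for L2 in range(h2lo, h2hi + 1):
        if q + L2 > n:
            break
        for La in range(aplo, aphi + 1):
            e3 = q + 2 * L2 + La          # end of helix II 3' arm
            if e3 > n:
                break
            # quartet: all four pairs non-Watson-Crick
            bad = False
            for j in range(4):
                if (window[q + j], window[e3 - 1 - j]) in _WC:
                    bad = True
                    break
            if bad:
                continue
            quartet_gu = sum(
                1 for j in range(4)
                if (window[q + j], window[e3 - 1 - j]) in _GU)
            upper = _score_helix(window, q + 4, L2 - 4, e3 - 4,
                                 params.allow_gu)
            if upper is None:
                continue
            loop = window[q + L2:q + L2 + La]
            aa = loop.find("AA")
            if aa == -1:
                continue
            h2_wc, h2_gu = upper
            h2_score = 2 * h2_wc + (h2_gu + quartet_gu)
            ap_excess = La - aplo
            # lower helix: maximise over loop sizes and helix I length
            for i5 in range(illo, ilhi + 1):
                a5 = q - 1 - i5       # helix I 5' arm ends here (exclusive)
                if a5 - h1lo < 0:
                    continue
                for i3 in range(illo, ilhi + 1):
                    b3 = e3 + i3      # helix I 3' arm starts here
                    # pairs are nested in L1 (innermost pair is fixed at
                    # (a5-1, b3)), so grow the helix incrementally
                    for L1, h1_wc, h1_gu in _helix1_variants(
                            window, a5, b3, h1lo, h1hi, n, params.allow_gu):
                        loop_excess = ap_excess + (i5 - illo) + (i3 - illo)
                        score = (2 * h1_wc + h1_gu + h2_score
                                 - 0.5 * loop_excess + 3.0)
                        if best is None or score > best[0]:
                            mclass = ("AUGA_AA" if window[q - 1] == "A"
                                      else "GUGA_AA")
                            best = (score, a5 - L1, b3 + L1, q, L1,
                                    L2, q + L2 + aa, mclass)
    return best


def _helix1_variants(window, a5, b3, h1lo, h1hi, n, allow_gu):
    """All (L1, wc, gu) with every pair formed, innermost pair at
    (a5-1, b3)."""
    out = []
    wc = gu = 0
    for L1 in range(1, min(h1hi, a5, n - b3) + 1):
        kind = _pair_kind(window[a5 - L1], window[b3 + L1 - 1])
        if kind == "wc":
            wc += 1
        elif kind == "gu" and allow_gu:
            gu += 1
        else:
            break
        if L1 >= h1lo:
            out.append((L1, wc, gu))
    return out


def classify_motif(hit: SECISHit) -> str:
    if hit.motif_class not in ("AUGA_AA", "GUGA_AA"):
        raise ValidationError(f"invalid motif class {hit.motif_class!r}")
    return hit.motif_class


def find_secis(record: GenomeRecord, gene, params: SECISParams = SECISParams()
               ) -> list:
    """Non-overlapping SECIS hits in the 3' UTR window of a gene model.

    `gene` carries exon Intervals in genome coordinates (see pipeline);
    the window starts at the gene's stop codon end on the coding strand and
    is truncated at the contig edge.  Hits are returned sorted by score,
    greedily non-overlapping.
    """
    strand = gene.exon_intervals[0].strand
    if strand == "+":
        start = max(e.end for e in gene.exon_intervals)
        wseq = record.seq[start:start + params.window]
        origin = start
    else:
        end = min(e.start for e in gene.exon_intervals)
        wstart = max(0, end - params.window)
        from .genome_io import reverse_complement
        wseq = reverse_complement(record.seq[wstart:end])
        origin = 0  # window-local; reflected below
    hits = _scan_window(wseq, params, seqid=record.id, strand=strand)
    out = []
    for h in hits:
        if strand == "-":
            # reflect window-local coordinates onto the forward strand
            wlen = len(wseq)
            iv = h.interval
            end = min(e.start for e in gene.exon_intervals)
            wstart = max(0, end - params.window)
            g0 = wstart + (wlen - iv.end)
            g1 = wstart + (wlen - iv.start)
            h = replace(h, interval=Interval(record.id, g0, g1, "-"),
                        quartet_pos=wstart + (wlen - 1 - (h.quartet_pos)),
                        apical_aa_pos=wstart + (wlen - 1 - h.apical_aa_pos))
        else:
            h = replace(h, interval=Interval(record.id, origin + h.interval.start,
                                             origin + h.interval.end, "+"),
                        quartet_pos=origin + h.quartet_pos,
                        apical_aa_pos=origin + h.apical_aa_pos)
        out.append(h)
    return out


def _scan_window(wseq: str, params: SECISParams, seqid="window", strand="+"
                 ) -> list:
    """All anchor-best hits above threshold, greedily non-overlapping,
    sorted by descending score.  Coordinates are window-local."""
    cands = []
    q = wseq.find("TGA", 1)
    while q != -1:
        if wseq[q - 1] in "AG":
            c = _best_at_anchor(wseq, q, params)
            if c is not None and c[0] >= params.min_score:
                cands.append(c)
        q = wseq.find("TGA", q + 1)
    cands.sort(key=lambda c: (-c[0], c[1]))
    chosen = []
    for c in cands:
        score, s5, s3, qpos, h1, h2, aapos, mclass = c
        if any(not (s3 <= k[1] or s5 >= k[2]) for k in chosen):
            continue
        chosen.append(c)
    return [SECISHit(interval=Interval(seqid, c[1], c[2], strand),
                     motif_class=c[7], quartet_pos=c[3], helix1_pairs=c[4],
                     helix2_pairs=c[5], apical_aa_pos=c[6], score=c[0])
            for c in chosen]
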