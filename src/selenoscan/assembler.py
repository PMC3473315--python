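"""Exon-chain assembly: for each exon carrying an in-frame TGA, build the
open reading frame of maximal coding potential that contains it.

A valid chain starts at an initial (ATG) or single exon, ends at a terminal
(TAA/TAG) or single exon, and joins consecutive exons across introns of at
least the minimum length with matching reading phase.  The chain score is
the sum of member coding potentials minus a junction cost with a fixed
and a length-proportional part.  Every
in-frame TGA inside the winning chain is designated selenocysteine; a TGA
never terminates a model (the terminal stop must be TAA/TAG).

The optimum over all chains through a focal exon is found by a forward
sweep (best prefix ending at each exon) and a backward sweep (best suffix
starting at each exon), each O(E log E) over the candidate set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .genome_io import ValidationError, translate_cds
from .signals import ExonCandidate

_ADJACENT = {
    ("initial", "internal"), ("initial", "terminal"),
    ("internal", "internal"), ("internal", "terminal"),
}


@dataclass
class AssemblyParams:
    min_intron: int = 40
    max_intron: int = 3000          # compact-invertebrate gene geometry
    intron_penalty: float = 8.0     # bits per junction (fixed part)
    intron_len_cost: float = 0.02   # bits per intron nt (length part)
    dedup_overlap: float = 0.5      # CDS overlap fraction for deduplication

    def junction_cost(self, intron_len: int) -> float:
        return self.intron_penalty + self.intron_len_cost * intron_len


@dataclass(frozen=True)
class GeneModel:
    """An assembled selenoprotein ORF on the scanned strand."""

    exons: tuple                 # ExonCandidates, 5'->3' in scan coordinates
    focal_tga: int               # position of the seeding TGA (scan coords)
    sec_positions: tuple         # all in-frame TGA codon starts in the chain
    total_score: float
    protein: str                 # with U at Sec positions

    @property
    def seqid(self) -> str:
        return self.exons[0].interval.seqid

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def cds_length(self) -> int:
        return sum(len(e.interval) for e in self.exons)


def compatible(a: ExonCandidate, b: ExonCandidate, min_intron: int = 40,
               max_intron: int | None = None) -> bool:
    """Can exon b directly follow exon a in a chain?"""
    if (a.kind, b.kind) not in _ADJACENT:
        return False
    if b.start < a.end + min_intron:
        return False
    if max_intron is not None and b.start > a.end + max_intron:
        return False
    return a.frame3 == b.frame5


def chain_cds(exons: Sequence[ExonCandidate], seq: str) -> str:
    return "".join(seq[e.start:e.end] for e in exons)


def chain_sec_positions(exons: Sequence[ExonCandidate]) -> tuple:
    """Genomic (scan-coordinate) start of every in-frame TGA in the chain."""
    out = []
    for e in exons:
        pad = (3 - e.frame5) % 3
        for off in e.tga_offsets:
            out.append(e.start + pad + 3 * off)
    return tuple(out)


def validate_gene_model(exons: Sequence[ExonCandidate], seq: str,
                        params: AssemblyParams) -> str | None:
    """Return the translated protein if the chain satisfies all gene-model
    invariants, else None (e.g. a stop codon assembled across a junction)."""
    if exons[0].kind not in ("initial", "single"):
        return None
    if exons[-1].kind not in ("terminal", "single"):
        return None
    for a, b in zip(exons, exons[1:]):
        if not compatible(a, b, params.min_intron, params.max_intron):
            return None
    cds = chain_cds(exons, seq)
    if len(cds) % 3:
        return None
    if not cds.startswith("ATG") or cds[-3:] not in ("TAA", "TAG"):
        return None
    try:
        return translate_cds(cds, sec_readthrough=True)
    except ValidationError:
        return None


def chain_score(exons: Sequence[ExonCandidate], params: AssemblyParams
                ) -> float:
    """Total score of a chain: member coding potentials minus junction
    costs (fixed per-intron penalty plus length-proportional part)."""
    total = sum(e.coding_potential for e in exons)
    for a, b in zip(exons, exons[1:]):
        total -= params.junction_cost(b.start - a.end)
    return total


class _Sweeps:
    """Forward/backward best-chain tables over a sorted candidate list.

    best[i] = (score, -n_exons, -chain_start) maximised lexicographically,
    which realises the tie-break "fewer exons, then leftmost start".
    """

    def __init__(self, cands: Sequence[ExonCandidate], params: AssemblyParams):
        self.params = params
        self.cands = sorted(cands, key=lambda e: (e.start, e.end, e.kind,
                                                  e.frame5))
        self.fwd, self.fparent = self._forward()
        self.bwd, self.bchild = self._backward()

    def _forward(self):
        """fwd[i]: best chain from an initial exon to exon i.

        The junction cost a + b*intron_len separates as
        (fwd[a] + b*a.end) - b*e.start - a, so predecessors are ranked by
        the adjusted key v = fwd_score + b*end and kept in per-phase
        monotone deques (sliding-window maximum over the allowed intron
        length window)."""
        from collections import deque
        cands, p = self.cands, self.params
        b0 = p.intron_len_cost
        n = len(cands)
        fwd = [None] * n
        parent = [None] * n
        by_end = sorted(range(n), key=lambda i: (cands[i].end, i))
        dq = [deque(), deque(), deque()]   # entries (end, adj_key, idx)
        ptr = 0
        for i in sorted(range(n), key=lambda i: (cands[i].start, i)):
            e = cands[i]
            while ptr < n and cands[by_end[ptr]].end + p.min_intron <= e.start:
                j = by_end[ptr]
                ptr += 1
                a = cands[j]
                if a.kind in ("initial", "internal") and fwd[j] is not None:
                    adj = (fwd[j][0] + b0 * a.end, fwd[j][1], fwd[j][2])
                    d = dq[a.frame3]
                    while d and d[-1][1] <= adj:
                        d.pop()
                    d.append((a.end, adj, j))
            if e.kind == "initial":
                fwd[i] = (e.coding_potential, -1, -e.start)
            elif e.kind in ("internal", "terminal"):
                d = dq[e.frame5]
                while d and d[0][0] + p.max_intron < e.start:
                    d.popleft()
                if d:
                    adj = d[0][1]
                    fwd[i] = (adj[0] - b0 * e.start + e.coding_potential
                              - p.intron_penalty, adj[1] - 1, adj[2])
                    parent[i] = d[0][2]
        return fwd, parent

    def _backward(self):
        from collections import deque
        cands, p = self.cands, self.params
        b0 = p.intron_len_cost
        n = len(cands)
        bwd = [None] * n
        child = [None] * n
        by_start = sorted(range(n), key=lambda i: (-cands[i].start, -i))
        dq = [deque(), deque(), deque()]   # entries (start, adj_key, idx)
        ptr = 0
        for i in sorted(range(n), key=lambda i: (-cands[i].end, -i)):
            e = cands[i]
            while ptr < n and \
                    cands[by_start[ptr]].start >= e.end + p.min_intron:
                j = by_start[ptr]
                ptr += 1
                b_ex = cands[j]
                if b_ex.kind in ("internal", "terminal") and bwd[j] is not None:
                    adj = (bwd[j][0] - b0 * b_ex.start, bwd[j][1], bwd[j][2])
                    d = dq[b_ex.frame5]
                    while d and d[-1][1] <= adj:
                        d.pop()
                    d.append((b_ex.start, adj, j))
            if e.kind == "terminal":
                bwd[i] = (e.coding_potential, -1, 0)
            elif e.kind in ("initial", "internal"):
                d = dq[e.frame3]
                while d and d[0][0] - p.max_intron > e.end:
                    d.popleft()
                if d:
                    adj = d[0][1]
                    bwd[i] = (adj[0] + b0 * e.end + e.coding_potential
                              - p.intron_penalty, adj[1] - 1, 0)
                    child[i] = d[0][2]
        return bwd, child

    def chain_through(self, i: int):
        """(score_key, exon index list) of the best chain through exon i."""
        e = self.cands[i]
        if e.kind == "single":
            return (e.coding_potential, -1, -e.start), [i]
        if self.fwd[i] is None or self.bwd[i] is None:
            return None, None
        f, b = self.fwd[i], self.bwd[i]
        key = (f[0] + b[0] - e.coding_potential, f[1] + b[1] + 1, f[2])
        left = []
        j = i
        while j is not None:
            left.append(j)
            j = self.fparent[j]
        left.reverse()
        right = []
        j = self.bchild[i]
        while j is not None:
            right.append(j)
            j = self.bchild[j]
        return key, left + right


def assemble_best_orf(focal: ExonCandidate,
                      candidates: Iterable[ExonCandidate],
                      params: AssemblyParams = AssemblyParams(),
                      seq: str | None = None) -> GeneModel | None:
    """Best-scoring valid ORF chain containing `focal` (which must carry an
    in-frame TGA), or None if no start..stop chain through it exists.

    `seq` (the scanned strand sequence) is needed to build the CDS/protein;
    without it a model with an empty protein is returned (score/chain only).
    """
    if not focal.has_inframe_tga:
        raise ValidationError("focal exon carries no in-frame TGA")
    cands = list(candidates)
    if focal not in cands:
        raise ValidationError("focal exon not among candidates")
    sweeps = _Sweeps(cands, params)
    i = sweeps.cands.index(focal)
    key, chain_idx = sweeps.chain_through(i)
    if key is None:
        return None
    exons = [sweeps.cands[j] for j in chain_idx]
    return _finalise(exons, focal, key[0], seq, params)


def _finalise(exons, focal, score, seq, params) -> GeneModel | None:
    if seq is not None:
        protein = validate_gene_model(exons, seq, params)
        if protein is None:
            return None
    else:
        protein = ""
    secs = chain_sec_positions(exons)
    pad = (3 - focal.frame5) % 3
    focal_tgas = [focal.start + pad + 3 * o for o in focal.tga_offsets]
    return GeneModel(exons=tuple(exons), focal_tga=focal_tgas[0],
                     sec_positions=secs, total_score=float(score),
                     protein=protein)


def assemble_all(candidates: Sequence[ExonCandidate], seq: str,
                 params: AssemblyParams = AssemblyParams(),
                 min_gene_score: float = 0.0) -> list[GeneModel]:
    """One best model per focal in-frame-TGA exon, deduplicated.

    Runs the two sweeps once over the whole candidate set, extracts the
    optimal chain for every focal exon whose chain score clears
    `min_gene_score`, validates each chain, and collapses models sharing at
    least `dedup_overlap` of their CDS (keeping the best score).
    """
    sweeps = _Sweeps(candidates, params)
    models = []
    seen_chains = set()
    for i, e in enumerate(sweeps.cands):
        if not e.has_inframe_tga:
            continue
        key, chain_idx = sweeps.chain_through(i)
        if key is None or key[0] < min_gene_score:
            continue
        sig = tuple(chain_idx)
        if sig in seen_chains:
            continue
        seen_chains.add(sig)
        exons = [sweeps.cands[j] for j in chain_idx]
        model = _finalise(exons, e, key[0], seq, params)
        if model is not None:
            models.append(model)
    return dedup_models(models, params.dedup_overlap)


def dedup_models(models: list[GeneModel], min_frac: float = 0.5
                 ) -> list[GeneModel]:
    """Collapse models whose CDS overlap at least min_frac of the smaller
    CDS *and* designate the same Sec positions; the higher-scoring model
    wins.  Boundary variants that disagree on where the Sec-TGAs are all
    survive here -- the homology/SECIS evidence downstream adjudicates, and
    the pipeline collapses confirmed calls to one gene per locus."""
    # cluster by genomic span first so comparisons stay local
    clusters = []
    cur, cur_end = [], None
    for m in sorted(models, key=lambda m: (m.start, m.end)):
        if cur_end is None or m.start < cur_end:
            cur.append(m)
            cur_end = m.end if cur_end is None else max(cur_end, m.end)
        else:
            clusters.append(cur)
            cur, cur_end = [m], m.end
    if cur:
        clusters.append(cur)
    kept: list[GeneModel] = []
    for cluster in clusters:
        ckept = []
        for m in sorted(cluster, key=lambda m: (-m.total_score, m.start,
                                                m.cds_length)):
            dup = False
            for k in ckept:
                if set(m.sec_positions) != set(k.sec_positions):
                    continue
                ov = _cds_overlap(m, k)
                if ov >= min_frac * min(m.cds_length, k.cds_length):
                    dup = True
                    break
            if not dup:
                ckept.append(m)
        kept.extend(ckept)
    kept.sort(key=lambda m: m.start)
    return kept


def _cds_overlap(a: GeneModel, b: GeneModel) -> int:
    total = 0
    for ea in a.exons:
        for eb in b.exons:
            total += max(0, min(ea.end, eb.end) - max(ea.start, eb.start))
    return total


def translate_gene(model: GeneModel, seq: str) -> str:
    """Protein of the model's spliced CDS; in-frame TGA -> U, stop dropped."""
    cds = chain_cds(model.exons, seq)
    return translate_cds(cds, sec_readthrough=True)
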