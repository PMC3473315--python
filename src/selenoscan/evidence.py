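"""Homology evidence: Sec/Cys pairing, family assignment, EST read-through.

Local protein alignment plays the role a BLASTp search plays at database
scale: candidate proteins (with U at selenocysteine) are aligned against a
homolog database, scoring U as C under BLOSUM62 so that Sec- and Cys-form
homologs are interchangeable.  Positive Sec/Cys evidence means at least one
homolog places a cysteine (or selenocysteine) in the column aligned to the
query's U, with adequate conservation of the Sec-flanking window.

EST support counts expressed-sequence fragments whose placement on the
spliced transcript covers a Sec-TGA codon with anchored flanks on both
sides -- direct evidence that the TGA is read through in a spliced mRNA.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import biotite.sequence as bioseq
import biotite.sequence.align as bioalign
import edlib
import numpy as np

from .genome_io import ValidationError, reverse_complement

_BLOSUM62 = bioalign.SubstitutionMatrix.std_protein_matrix()
_GAP_OPEN = 11
_GAP_EXTEND = 1


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    aligned_query: str
    aligned_subject: str
    score: float
    identity: float            # identical columns / alignment length
    query_start: int           # query offset of the local alignment
    subject_start: int
    family: str | None = None

    def __post_init__(self):
        if len(self.aligned_query) != len(self.aligned_subject):
            raise ValidationError("aligned strings differ in length")


@dataclass
class UCEvidence:
    sec_column_found: bool
    n_cys_paired: int
    best_hit: AlignmentHit | None
    flank_identity: float

    @property
    def positive(self) -> bool:
        return self.sec_column_found and self.n_cys_paired >= 1


@dataclass
class ESTEvidence:
    n_spanning: int
    identities: list = field(default_factory=list)


@dataclass
class EvidenceParams:
    flank_window: int = 20           # residues each side of the Sec
    flank_identity_min: float = 0.3  # identical columns / flank length
    # raw-score floor standing in for a permissive E-value cutoff: 45 raw
    # (BLOSUM62, gap 11/1) is ~22 bits, i.e. E~1 for a search space of a
    # 40-residue flank against a desk-scale database; recalibrate with
    # calibrate_score_threshold for other database sizes
    min_align_score: float | None = 45.0
    est_anchor: int = 50             # nt each side of the TGA
    est_identity_min: float = 0.95


def extract_sec_flank(protein: str, sec_index: int, window: int = 20) -> str:
    """Up to `window` residues each side of the U, truncated at the termini."""
    if not (0 <= sec_index < len(protein)) or protein[sec_index] != "U":
        raise ValidationError(f"no U at position {sec_index}")
    return protein[max(0, sec_index - window):sec_index + window + 1]


def _as_cys(peptide: str) -> str:
    return peptide.replace("U", "C")


def local_align(query: str, subject: str, query_id: str = "query",
                subject_id: str = "subject", family: str | None = None
                ) -> AlignmentHit:
    """Optimal Smith-Waterman local alignment (BLOSUM62, gap 11/1).

    U is scored as C; identity counts U==C columns as matches for the same
    reason.  The highest-scoring alignment is returned; ties resolve to the
    aligner's first optimum, which is deterministic.
    """
    if not query or not subject:
        raise ValidationError("empty peptide")
    q = bioseq.ProteinSequence(_as_cys(query))
    s = bioseq.ProteinSequence(_as_cys(subject))
    aln = bioalign.align_optimal(q, s, _BLOSUM62,
                                 gap_penalty=(-_GAP_OPEN, -_GAP_EXTEND),
                                 local=True, max_number=1)[0]
    trace = aln.trace
    qs, ss = [], []
    matches = 0
    for qi, si in trace:
        cq = query[qi] if qi >= 0 else "-"
        cs = subject[si] if si >= 0 else "-"
        qs.append(cq)
        ss.append(cs)
        if cq != "-" and cs != "-" and (cq == cs or {cq, cs} == {"U", "C"}):
            matches += 1
    q0 = int(trace[trace[:, 0] >= 0, 0].min()) if len(trace) else 0
    s0 = int(trace[trace[:, 1] >= 0, 1].min()) if len(trace) else 0
    length = len(qs)
    return AlignmentHit(
        query_id=query_id, subject_id=subject_id,
        aligned_query="".join(qs), aligned_subject="".join(ss),
        score=float(aln.score), identity=matches / length if length else 0.0,
        query_start=q0, subject_start=s0, family=family)


def _column_at(hit: AlignmentHit, query_pos: int) -> str | None:
    """Subject character aligned to the given query offset, if aligned."""
    qpos = hit.query_start
    for cq, cs in zip(hit.aligned_query, hit.aligned_subject):
        if cq != "-":
            if qpos == query_pos:
                return cs if cs != "-" else None
            qpos += 1
    return None


def find_uc_pairing(flank: str, db, params: EvidenceParams = EvidenceParams()
                    ) -> UCEvidence:
    """Sec/Cys pairing of a Sec-flank against a homolog database.

    `flank` must contain exactly one U.  `db` is an iterable of
    (id, sequence, family) triples.  A subject pairs if the local alignment
    places C (or U) opposite the flank's U and the flank-window identity --
    identical columns over the flank length -- meets the threshold.
    """
    if flank.count("U") != 1:
        raise ValidationError("flank must contain exactly one U")
    upos = flank.index("U")
    n_paired = 0
    best = None
    best_flank_id = 0.0
    # align against the original (U-bearing) flank so U==C columns count
    for sid, sseq, fam in db:
        hit = local_align(flank, sseq, subject_id=sid, family=fam)
        if params.min_align_score is not None \
                and hit.score < params.min_align_score:
            continue
        matches = sum(1 for cq, cs in zip(hit.aligned_query,
                                          hit.aligned_subject)
                      if cq != "-" and cs != "-"
                      and (cq == cs or {cq, cs} == {"U", "C"}))
        flank_id = matches / len(flank)
        paired_char = _column_at(hit, upos)
        # the query U was converted to C for scoring; the subject pairs if
        # it, too, holds C (Cys-form) or U (Sec-form) at that column
        paired = paired_char in ("C", "U") and flank_id >= \
            params.flank_identity_min
        if paired:
            n_paired += 1
        if best is None or hit.score > best.score:
            best = hit
            best_flank_id = flank_id
    return UCEvidence(sec_column_found=n_paired >= 1, n_cys_paired=n_paired,
                      best_hit=best, flank_identity=best_flank_id)


# recognised selenoprotein family names; subfamily labels (DI1, Gpx3,
# SelU3_b ...) collapse onto these
KNOWN_FAMILIES = (
    "Sel15", "AphC.like", "DsbA", "MsrA", "SelH", "SelJ", "SelK", "SelL",
    "SelM", "SelN", "SelO", "SelP", "SelR", "SelS", "SelT", "SelU", "SelW",
    "Sps", "TR", "Gpx", "DI",
)


def collapse_family(label: str) -> str:
    """Map a subfamily label onto its family (DI1 -> DI, SelU3_b -> SelU)."""
    if label in KNOWN_FAMILIES:
        return label
    base = re.sub(r"[_\-][A-Za-z0-9]+$", "", label)
    if base in KNOWN_FAMILIES:
        return base
    base2 = re.sub(r"\d+$", "", base)
    if base2 in KNOWN_FAMILIES:
        return base2
    return label


def assign_family(protein: str, db,
                  min_score: float = 60.0, min_identity: float = 0.25
                  ) -> str:
    """Family of the best database hit above threshold, else "novel"."""
    best = None
    for sid, sseq, fam in db:
        hit = local_align(protein, sseq, subject_id=sid, family=fam)
        if best is None or hit.score > best.score:
            best = hit
    if best is None or best.family is None or best.score < min_score \
            or best.identity < min_identity:
        return "novel"
    return collapse_family(best.family)


def calibrate_score_threshold(db, rng, n_shuffles: int = 50,
                              flank_len: int = 41,
                              quantile: float = 0.95) -> float:
    """Raw-score threshold emulating a permissive E-value cutoff.

    Aligns shuffled-composition decoy flanks against the database and
    returns the requested quantile of the best-hit score distribution.
    """
    pool = "".join(s for _, s, _ in db).replace("U", "C")
    if not pool:
        raise ValidationError("empty database")
    scores = []
    letters = np.array(list(pool))
    for _ in range(n_shuffles):
        decoy = "".join(rng.choice(letters, size=flank_len))
        best = max(local_align(decoy, s).score for _, s, _ in db)
        scores.append(best)
    return float(np.quantile(scores, quantile))


def est_support(sec_codon_offsets, mrna: str, ests,
                params: EvidenceParams = EvidenceParams()) -> ESTEvidence:
    """ESTs whose placement on the transcript spans a Sec-TGA with anchors.

    `sec_codon_offsets` are transcript offsets of the Sec codons.  Each EST
    (either orientation) is located on `mrna` by infix edit-distance
    alignment; it supports read-through if its placement covers some Sec
    codon with at least `est_anchor` aligned nt on each side at identity
    >= est_identity_min.
    """
    n_spanning = 0
    identities = []
    for est in ests:
        placed = None
        for seq in (est, reverse_complement(est)):
            res = edlib.align(seq, mrna, mode="HW", task="locations")
            if res["editDistance"] < 0:
                continue
            ident = 1.0 - res["editDistance"] / max(1, len(seq))
            if ident < params.est_identity_min:
                continue
            loc = res["locations"][0]
            if placed is None or ident > placed[0]:
                placed = (ident, loc[0], loc[1] + 1)
        if placed is None:
            continue
        ident, t0, t1 = placed
        spans = any(t0 <= off - params.est_anchor
                    and t1 >= off + 3 + params.est_anchor
                    for off in sec_codon_offsets)
        if spans:
            n_spanning += 1
            identities.append(ident)
    return ESTEvidence(n_spanning=n_spanning, identities=identities)
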