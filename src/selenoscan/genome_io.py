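"""Sequence and annotation I/O, coordinate conventions, spliced product mapping.

All internal coordinates are 0-based half-open on the forward strand of the
record.  GFF3 emission converts to 1-based inclusive at the boundary, and
minus-strand features are stored with forward-strand coordinates plus a
strand flag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NT_ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# standard genetic code with TGA left out: the caller decides whether TGA is
# selenocysteine (U) or a stop, which is the whole point of this package
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGG": "W", "TGA": "*",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


class FormatError(ValueError):
    """Raised for malformed input files."""


class ValidationError(ValueError):
    """Raised when a value violates a domain invariant."""


class MappingError(RuntimeError):
    """Raised when a product cannot be mapped back to a locus."""


@dataclass(frozen=True)
class GenomeRecord:
    """A chromosome/scaffold: an id plus an uppercase A/C/G/T/N sequence."""

    id: str
    seq: str

    def __post_init__(self):
        if not self.id:
            raise ValidationError("record id must be non-empty")
        if not self.seq:
            raise ValidationError(f"record {self.id!r} has empty sequence")
        bad = set(self.seq) - NT_ALPHABET
        if bad:
            raise ValidationError(
                f"record {self.id!r} has illegal characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval with strand."""

    seqid: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"bad interval [{self.start}, {self.end}) on {self.seqid}")
        if self.strand not in "+-":
            raise ValidationError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Interval") -> int:
        if self.seqid != other.seqid:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def reverse_complement(seq: str) -> str:
    """Reversed Watson-Crick complement; N maps to N."""
    bad = set(seq) - NT_ALPHABET
    if bad:
        raise ValidationError(f"illegal characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def reflect_interval(iv: Interval, length: int) -> Interval:
    """Mirror an interval between a sequence and its reverse complement."""
    return Interval(iv.seqid, length - iv.end, length - iv.start,
                    "-" if iv.strand == "+" else "+")


def translate_cds(cds: str, sec_readthrough: bool = True,
                  include_stop: bool = False) -> str:
    """Translate a CDS; in-frame TGA becomes U when sec_readthrough is set.

    The terminal stop (TAA/TAG, or TGA when not read through) is dropped
    unless include_stop is requested.
    """
    if len(cds) % 3:
        raise ValidationError(f"CDS length {len(cds)} not divisible by 3")
    out = []
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3]
        if codon == "TGA" and sec_readthrough:
            aa = "U"
        else:
            aa = CODON_TABLE.get(codon, "X")
        out.append(aa)
    prot = "".join(out)
    if not include_stop and prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        raise ValidationError("internal stop codon in CDS")
    return prot


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path, nucleotide: bool = True) -> list[GenomeRecord]:
    """Read a FASTA file into GenomeRecords (uppercased; U mapped to T)."""
    path = Path(path)
    records = []
    seen = set()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise FormatError(f"cannot parse FASTA {path}: {exc}") from exc
    if not parsed:
        raise FormatError(f"no FASTA records in {path}")
    for rec in parsed:
        rid = rec.id
        if rid in seen:
            raise ValidationError(f"duplicate FASTA id {rid!r} in {path}")
        seen.add(rid)
        seq = str(rec.seq).upper()
        if nucleotide:
            seq = seq.replace("U", "T")
        if not seq:
            raise ValidationError(f"empty sequence for {rid!r} in {path}")
        records.append(GenomeRecord(rid, seq))
    return records


def write_fasta(records: Iterable, path, width: int = 70) -> None:
    recs = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="\n") as fh:
        for rec in recs:
            fh.write(f">{rec.id}\n")
            s = str(rec.seq)
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def read_fasta_with_descriptions(path) -> list[tuple[str, str, str]]:
    """(id, description, seq) triples; used for family-labeled protein DBs."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append((rec.id, rec.description, str(rec.seq).upper()))
    if not out:
        raise FormatError(f"no FASTA records in {path}")
    return out


# ---------------------------------------------------------------------------
# spliced product mapping (Sim4-style, exact-match model)

def _try_map(seq, product, is_protein, start, min_intron, max_intron,
             allow_sec_readthrough, ag_positions, min_exon=20):
    """Exact spliced match of product starting at genomic position `start`.

    Depth-first search with memoised dead states.  At each state we either
    consume the next genomic base into the current codon or open an intron at
    a GT, resuming after any AG within the intron length bounds.  Continuing
    the exon is tried first and acceptors nearest-first, which makes the
    returned exon structure deterministic (fewest exons, then leftmost
    boundaries, among exact matches).
    """
    import bisect

    n = len(seq)
    dead = set()

    def match_aa(codon, aa):
        if codon == "TGA" and allow_sec_readthrough and aa == "U":
            return True
        return CODON_TABLE.get(codon, "X") == aa

    def successors(i, j, partial, cnt):
        """Next states in preference order: extend exon, then nearest intron.

        Yields (state, junction) pairs; exon-extension first keeps the
        result at the fewest exons with leftmost boundaries among matches.
        `cnt` counts exonic bases since the last acceptor (capped at
        min_exon): an intron may only open once the exon has reached the
        minimum length, which rules out degenerate few-base exons.
        """
        if i < n:
            base = seq[i]
            cnt1 = min(cnt + 1, min_exon)
            if is_protein:
                newp = partial + base
                if len(newp) == 3:
                    if j < len(product) and match_aa(newp, product[j]):
                        yield (i + 1, j + 1, "", cnt1), None
                else:
                    yield (i + 1, j, newp, cnt1), None
            else:
                if j < len(product) and base == product[j]:
                    yield (i + 1, j + 1, "", cnt1), None
            if cnt >= min_exon and seq[i:i + 2] == "GT":
                lo = bisect.bisect_left(ag_positions, i + min_intron - 2)
                hi = bisect.bisect_right(ag_positions, i + max_intron - 2)
                for agpos in ag_positions[lo:hi]:
                    yield (agpos + 2, j, partial, 0), i

    def accepted(j, partial):
        return j == len(product) and not partial

    # iterative DFS: each frame is (state, successor-iterator); `junctions`
    # mirrors the frame stack with the intron junction taken to reach it
    start_state = (start, 0, "", 0)
    stack = [(start_state, successors(*start_state))]
    junctions = [None]
    on_path = {start_state}
    while stack:
        state, it = stack[-1]
        i, j, partial, _fresh = state
        if accepted(j, partial):
            exons = []
            exon_start = start
            for (st, _), junc in zip(stack, junctions):
                if junc is not None:
                    donor, acceptor_resume = junc
                    exons.append((exon_start, donor))
                    exon_start = acceptor_resume
            exons.append((exon_start, i))
            return exons
        advanced = False
        for nxt, donor in it:
            if nxt in dead or nxt in on_path:
                continue
            stack.append((nxt, successors(*nxt)))
            junctions.append(None if donor is None else (donor, nxt[0]))
            on_path.add(nxt)
            advanced = True
            break
        if not advanced:
            dead.add(state)
            on_path.discard(state)
            stack.pop()
            junctions.pop()
    return None


def map_product_to_genome(product: str, locus: GenomeRecord,
                          allow_sec_readthrough: bool = True,
                          min_intron: int = 40,
                          max_intron: int = 20000,
                          min_exon: int = 20,
                          search_minus: bool = True):
    """Locate the exon/intron structure encoding `product` on `locus`.

    `product` may be a protein (it then must start with M and is matched
    codon-by-codon, TGA matching U when the flag is set) or an mRNA/CDS
    nucleotide string.  Introns must be GT..AG and at least `min_intron` nt.
    Returns a list of exon Intervals in transcription order.
    """
    product = product.upper().replace(" ", "")
    is_protein = bool(set(product) - set("ACGTN"))
    for strand in ("+", "-"):
        seq = locus.seq if strand == "+" else reverse_complement(locus.seq)
        ag_positions = [m.start() for m in re.finditer("(?=AG)", seq)]
        if is_protein:
            anchors = [m.start() for m in re.finditer("(?=ATG)", seq)]
        else:
            first = product[:20]
            anchors = [m.start() for m in re.finditer(
                "(?=" + re.escape(first) + ")", seq)] or list(range(len(seq)))
        for start in anchors:
            exons = _try_map(seq, product, is_protein, start, min_intron,
                             max_intron, allow_sec_readthrough, ag_positions,
                             min_exon)
            if exons:
                ivs = [Interval(locus.id, s, e, "+") for s, e in exons]
                if strand == "-":
                    ivs = [reflect_interval(iv, locus.length)
                           for iv in reversed(ivs)]
                    # keep transcription order (5'->3' on minus strand)
                    ivs = list(reversed(ivs))
                return ivs
        if not search_minus:
            break
    raise MappingError("no full-length spliced mapping found")


def spliced_sequence(record: GenomeRecord, exons: Sequence[Interval]) -> str:
    """Concatenate exon sequences in transcription order (strand-aware)."""
    strand = exons[0].strand
    if strand == "+":
        parts = [record.seq[e.start:e.end]
                 for e in sorted(exons, key=lambda e: e.start)]
        return "".join(parts)
    parts = [reverse_complement(record.seq[e.start:e.end])
             for e in sorted(exons, key=lambda e: e.start, reverse=True)]
    return "".join(parts)


# ---------------------------------------------------------------------------
# GFF3 / BED

def write_gff3(calls, path, source: str = "selenoscan") -> None:
    """Emit gene/mRNA/CDS features (1-based inclusive) for confirmed calls.

    Sec codon genomic positions and SECIS intervals are carried in the
    mRNA attributes so that read_gff3(write_gff3(x)) restores coordinates
    exactly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = ["##gff-version 3"]
    for idx, call in enumerate(calls, start=1):
        g = call.gene
        exons = sorted(g.exon_intervals, key=lambda e: e.start)
        seqid = exons[0].seqid
        strand = exons[0].strand
        gstart, gend = exons[0].start, exons[-1].end
        gid = f"gene{idx:05d}"
        secs = ",".join(str(p) for p in g.sec_positions)
        secis = ",".join(f"{h.interval.start}-{h.interval.end}"
                         for h in call.secis_hits)
        attrs = f"ID={gid};family={call.family};sec_positions={secs}"
        if secis:
            attrs += f";secis={secis}"
        lines.append("\t".join([seqid, source, "gene", str(gstart + 1),
                                str(gend), ".", strand, ".", attrs]))
        mid = f"{gid}.m1"
        lines.append("\t".join([seqid, source, "mRNA", str(gstart + 1),
                                str(gend), f"{g.total_score:.3f}", strand,
                                ".", f"ID={mid};Parent={gid}"]))
        phase = 0
        ordered = exons if strand == "+" else list(reversed(exons))
        cds_lines = []
        for e in ordered:
            cds_lines.append((e.start, "\t".join(
                [seqid, source, "CDS", str(e.start + 1), str(e.end),
                 ".", strand, str(phase), f"Parent={mid}"])))
            phase = (3 - ((len(e) - phase) % 3)) % 3
        for _, line in sorted(cds_lines):
            lines.append(line)
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff3(path) -> list[dict]:
    """Parse a selenoscan GFF3 back into plain dicts (coordinates 0-based)."""
    genes = []
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"bad GFF3 line: {line!r}")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            start, end = int(start) - 1, int(end)
            adict = dict(kv.split("=", 1) for kv in attrs.split(";") if kv)
            if ftype == "gene":
                current = {
                    "seqid": seqid, "start": start, "end": end,
                    "strand": strand, "family": adict.get("family", "novel"),
                    "sec_positions": [int(x) for x in
                                      adict.get("sec_positions", "").split(",")
                                      if x],
                    "secis": [tuple(int(v) for v in span.split("-"))
                              for span in adict.get("secis", "").split(",")
                              if span],
                    "exons": [],
                }
                genes.append(current)
            elif ftype == "CDS" and current is not None:
                current["exons"].append((start, end))
    for g in genes:
        g["exons"].sort()
    return genes


def write_bed(hits, path, record_id: str | None = None) -> None:
    """BED6 track of SECIS hits (name = motif class, score column = score)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="\n") as fh:
        for h in hits:
            iv = h.interval
            fh.write("\t".join([
                record_id or iv.seqid, str(iv.start), str(iv.end),
                h.motif_class, f"{h.score:.1f}", iv.strand]) + "\n")
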