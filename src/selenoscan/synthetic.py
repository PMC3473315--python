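"""Synthetic benchmark genomes with planted selenoprotein genes.

The generator emulates, at desk scale, the situation the scanner faces in a
real draft assembly: multi-exon selenoprotein genes with GT/AG introns and
in-frame TGA codons, SECIS stem-loops with the (A|G)UGA core and apical AA
in the 3' UTR, Cys-form homologs at controlled identity, EST fragments with
sequencing error, and decoys -- dead pseudogene copies lacking a SECIS and
Cys-paralog genes lacking the TGA altogether.  Planted splice sites and
start contexts are sampled from the same profile family the scanner scores
with; planted coding sequence is sampled from a biased codon-usage table,
independent of the scoring tables, which are trained on a separate
training-CDS sample.

Every planted structure is recorded in a ground-truth object so each
pipeline stage can be benchmarked exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_io import (GenomeRecord, Interval, ValidationError,
                        reverse_complement, translate_cds, write_fasta)
from .signals import default_signal_model

# deterministic codon-usage bias: within each synonymous family the
# codons get geometrically decreasing weights; amino-acid frequencies are
# typical metazoan averages
_AA_FREQ = {
    "A": 0.074, "R": 0.052, "N": 0.045, "D": 0.054, "C": 0.025,
    "E": 0.063, "Q": 0.041, "G": 0.066, "H": 0.026, "I": 0.052,
    "L": 0.096, "K": 0.058, "M": 0.024, "F": 0.038, "P": 0.047,
    "S": 0.071, "T": 0.053, "W": 0.011, "Y": 0.030, "V": 0.064,
}
_SYNONYMS = {
    "F": ["TTC", "TTT"], "L": ["CTG", "CTC", "TTG", "CTT", "CTA", "TTA"],
    "I": ["ATC", "ATT", "ATA"], "M": ["ATG"],
    "V": ["GTG", "GTC", "GTT", "GTA"],
    "S": ["AGC", "TCC", "TCT", "AGT", "TCA", "TCG"],
    "P": ["CCC", "CCT", "CCA", "CCG"], "T": ["ACC", "ACT", "ACA", "ACG"],
    "A": ["GCC", "GCT", "GCA", "GCG"], "Y": ["TAC", "TAT"],
    "H": ["CAC", "CAT"], "Q": ["CAG", "CAA"], "N": ["AAC", "AAT"],
    "K": ["AAG", "AAA"], "D": ["GAC", "GAT"], "E": ["GAG", "GAA"],
    "C": ["TGC", "TGT"], "W": ["TGG"],
    "R": ["AGA", "CGC", "AGG", "CGT", "CGA", "CGG"],
    "G": ["GGC", "GGA", "GGT", "GGG"],
}
_DECAY = 0.45  # geometric codon-preference decay within a family


def codon_usage_table() -> dict:
    """Codon -> probability over the 61 sense codons."""
    table = {}
    for aa, freq in _AA_FREQ.items():
        codons = _SYNONYMS[aa]
        weights = np.array([_DECAY ** i for i in range(len(codons))])
        weights /= weights.sum()
        for c, w in zip(codons, weights):
            table[c] = freq * w
    total = sum(table.values())
    return {c: w / total for c, w in table.items()}


_FAMILY_CYCLE = ("Gpx", "DI", "SelP", "TR", "SelW", "SelU", "SelT", "SelK",
                 "MsrA", "Sel15", "SelN", "SelM", "Sps", "SelO", "SelR",
                 "SelH", "SelL", "SelS", "DsbA", "SelJ")


@dataclass
class GeneSpec:
    """Structure of one planted gene."""

    n_exons: int
    exon_codons: list            # codons per exon (split lengths need not
                                 # respect codon boundaries; see planting)
    sec_cds_codons: list         # codon indices (0-based) carrying Sec-TGA
    secis: list                  # list of motif classes, 5'->3'
    family: str = "Gpx"
    strand: str = "+"
    intron_lengths: list = field(default_factory=list)
    secis_offsets: list = field(default_factory=list)  # nt after the stop
    has_tga: bool = True         # False for the Cys-paralog decoy


@dataclass
class PlantedGene:
    gene_id: str
    family: str
    seqid: str
    strand: str
    exons: list                  # Intervals, genome forward coordinates
    sec_positions: list          # forward-strand codon start of each Sec-TGA
    secis: list                  # (Interval, motif_class)
    cds: str
    protein: str
    mrna: str                    # CDS + 3' UTR through the SECIS region
    kind: str = "gene"           # gene | pseudogene | cys_paralog

    @property
    def span(self) -> Interval:
        s = min(e.start for e in self.exons)
        e = max(e.end for e in self.exons)
        return Interval(self.seqid, s, e, self.strand)


@dataclass
class SyntheticTruth:
    genes: list = field(default_factory=list)      # confirmed-expected genes
    decoys: list = field(default_factory=list)     # pseudogenes + paralogs

    def to_json(self) -> str:
        def entry(g: PlantedGene):
            return {
                "gene_id": g.gene_id, "family": g.family, "seqid": g.seqid,
                "strand": g.strand, "kind": g.kind,
                "exons": [[e.start, e.end] for e in g.exons],
                "sec_positions": g.sec_positions,
                "secis": [[iv.start, iv.end, mc] for iv, mc in g.secis],
                "protein": g.protein,
            }
        return json.dumps({"genes": [entry(g) for g in self.genes],
                           "decoys": [entry(g) for g in self.decoys]},
                          indent=1)


@dataclass
class GeneratorConfig:
    genome_length: int = 2_000_000
    gc: float = 0.40
    n_genes: int = 20
    exon_count_range: tuple = (1, 9)
    exon_codons_range: tuple = (25, 90)
    intron_length_range: tuple = (60, 300)
    sec_per_gene_range: tuple = (1, 3)
    secis_per_gene: int = 1
    n_pseudogenes: int = 6
    n_cys_paralogs: int = 4
    homolog_identity: float = 0.6
    homologs_per_gene: int = 2
    n_ests: int = 2000
    est_length_range: tuple = (150, 600)
    est_error: float = 0.01
    seed: int = 42

    def __post_init__(self):
        for f in (self.gc, self.homolog_identity, self.est_error):
            if not (0.0 <= f <= 1.0):
                raise ValidationError("fractions must lie in [0, 1]")
        if self.seed is None:
            raise ValidationError("seed is mandatory")


# ---------------------------------------------------------------------------
# low-level generators

def generate_background(length: int, gc: float = 0.4, seed=0) -> GenomeRecord:
    """I.i.d. background at the requested GC; deterministic per seed."""
    if length <= 0:
        raise ValidationError("length must be positive")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return GenomeRecord("background", _bg(rng, length, gc))


def _bg(rng, length, gc):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), p=p, size=length))


def _sample_profile(rng, probs) -> str:
    return "".join("ACGT"[rng.choice(4, p=row / row.sum())] for row in probs)


def _sample_cds(rng, n_codons, usage=None) -> str:
    usage = usage or codon_usage_table()
    codons = list(usage)
    p = np.array([usage[c] for c in codons])
    idx = rng.choice(len(codons), p=p / p.sum(), size=n_codons)
    return "".join(codons[i] for i in idx)


_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}
_NONWC_PARTNER = {"T": "G", "G": "A", "A": "G", "C": "A"}


def make_secis_element(rng, motif_class: str = "AUGA_AA") -> str:
    """A SECIS stem-loop with geometry strictly inside the default ranges."""
    L1 = int(rng.integers(7, 13))
    L2 = int(rng.integers(9, 15))
    i5 = int(rng.integers(1, 5))
    i3 = int(rng.integers(1, 5))
    La = int(rng.integers(8, 13))
    quart5 = "TGA" + "ACGT"[rng.integers(4)]
    rest5 = "".join("ACGT"[rng.integers(4)] for _ in range(L2 - 4))
    partners = [_NONWC_PARTNER[b] for b in quart5] + [_WC[b] for b in rest5]
    arm3 = "".join(reversed(partners))
    pos = int(rng.integers(0, La - 1))
    loop = ["CGT"[rng.integers(3)] for _ in range(La)]
    loop[pos:pos + 2] = ["A", "A"]
    h1_5 = "".join("ACGT"[rng.integers(4)] for _ in range(L1))
    h1_3 = "".join(_WC[b] for b in reversed(h1_5))
    pre = "A" if motif_class == "AUGA_AA" else "G"
    int5 = "".join("CT"[rng.integers(2)] for _ in range(i5 - 1)) + pre
    int3 = "".join("CT"[rng.integers(2)] for _ in range(i3))
    return h1_5 + int5 + quart5 + rest5 + "".join(loop) + arm3 + int3 + h1_3


def random_gene_spec(rng, config: GeneratorConfig, family: str,
                     strand: str | None = None, n_secis: int | None = None,
                     has_tga: bool = True) -> GeneSpec:
    n_exons = int(rng.integers(config.exon_count_range[0],
                               config.exon_count_range[1] + 1))
    exon_codons = [int(rng.integers(*config.exon_codons_range))
                   for _ in range(n_exons)]
    total = sum(exon_codons)
    n_sec = int(rng.integers(config.sec_per_gene_range[0],
                             config.sec_per_gene_range[1] + 1))
    # Sec codons: internal, pairwise distinct, away from start/stop
    positions = sorted(rng.choice(np.arange(5, total - 5),
                                  size=min(n_sec, total - 10),
                                  replace=False).tolist())
    n_secis = config.secis_per_gene if n_secis is None else n_secis
    return GeneSpec(
        n_exons=n_exons, exon_codons=exon_codons,
        sec_cds_codons=[int(p) for p in positions],
        secis=["AUGA_AA" if rng.random() < 0.7 else "GUGA_AA"
               for _ in range(n_secis)],
        family=family,
        strand=strand or ("+" if rng.random() < 0.5 else "-"),
        intron_lengths=[int(rng.integers(*config.intron_length_range))
                        for _ in range(n_exons - 1)],
        secis_offsets=sorted(
            int(rng.integers(250, 1200)) + 250 * i
            for i in range(n_secis)),
        has_tga=has_tga)


def selp_like_spec(strand: str = "+") -> GeneSpec:
    """The multi-Sec selenoprotein-P architecture used as a worked example:
    8 coding exons, Sec-TGA on coding exons 1, 3 and 5, two further
    Sec-TGAs near the C-terminus, and two SECIS elements downstream."""
    exon_codons = [40, 38, 42, 36, 40, 38, 36, 50]
    starts = np.cumsum([0] + exon_codons[:-1])
    secs = [int(starts[0]) + 16, int(starts[2]) + 14, int(starts[4]) + 18,
            int(starts[7]) + 38, int(starts[7]) + 44]
    return GeneSpec(n_exons=8, exon_codons=exon_codons, sec_cds_codons=secs,
                    secis=["AUGA_AA", "AUGA_AA"], family="SelP",
                    strand=strand,
                    intron_lengths=[80, 120, 90, 150, 100, 110, 130],
                    secis_offsets=[350, 750])


def build_gene_cassette(spec: GeneSpec, rng, signal_model=None,
                        gc: float = 0.4):
    """Forward-strand cassette string plus local-coordinate annotations.

    Layout: [start context 6nt][exon1][intron]...[exonN+stop][3' UTR with
    SECIS elements][tail].  Returns (cassette, info) where info holds local
    exon intervals, Sec codon starts, SECIS intervals, cds, protein, mrna.
    """
    sm = signal_model or default_signal_model()
    start_probs = sm.pwms["start"].probs
    donor_probs = sm.pwms["donor"].probs
    acc_probs = sm.pwms["acceptor"].probs

    total_codons = sum(spec.exon_codons)
    cds = _sample_cds(rng, total_codons)
    cds = "ATG" + cds[3:]
    for ci in spec.sec_cds_codons:
        if not (0 < ci < total_codons):
            raise ValidationError("Sec codon index out of range")
        codon = "TGA" if spec.has_tga else "TGC"
        cds = cds[:3 * ci] + codon + cds[3 * ci + 3:]
    stop = "TAA" if rng.random() < 0.55 else "TAG"
    cds_with_stop = cds + stop

    # split the CDS+stop into exon nucleotide spans (stop in the last exon);
    # split points are deliberately not codon-aligned when a phase shift
    # is drawn, exercising split-codon junctions
    exon_nt = [3 * c for c in spec.exon_codons]
    exon_nt[-1] += 3
    shifts = [int(rng.integers(0, 3)) for _ in exon_nt[:-1]]
    for i, sh in enumerate(shifts):
        exon_nt[i] += sh
        exon_nt[i + 1] -= sh

    parts = []
    exon_local = []
    pos = 0
    ctx = _sample_profile(rng, start_probs[:6])
    parts.append(ctx)
    pos += 6
    cpos = 0
    for i, nt in enumerate(exon_nt):
        exon_seq = cds_with_stop[cpos:cpos + nt]
        cpos += nt
        parts.append(exon_seq)
        exon_local.append((pos, pos + nt))
        pos += nt
        if i < len(exon_nt) - 1:
            ilen = spec.intron_lengths[i]
            d4 = _sample_profile(rng, donor_probs[5:])
            atail = _sample_profile(rng, acc_probs[:15])
            filler = _bg(rng, ilen - 23, gc)
            intron = "GT" + d4 + filler + atail + "AG"
            parts.append(intron)
            pos += len(intron)

    utr = []
    upos = pos
    secis_local = []
    prev_end = 0
    for mclass, off in zip(spec.secis, spec.secis_offsets):
        gap = off - prev_end
        utr.append(_bg(rng, max(gap, 30), gc))
        el = make_secis_element(rng, mclass)
        start_el = upos + sum(len(u) for u in utr)
        utr.append(el)
        secis_local.append((start_el, start_el + len(el), mclass))
        prev_end = sum(len(u) for u in utr)
    utr.append(_bg(rng, 150, gc))
    cassette = "".join(parts) + "".join(utr)

    protein = translate_cds(cds_with_stop, sec_readthrough=spec.has_tga)
    mrna = cds_with_stop + "".join(utr)
    info = {
        "exons": exon_local,
        "sec_local": [6 + _cds_to_cassette_offset(exon_nt, 3 * ci,
                                                  spec.intron_lengths)
                      for ci in spec.sec_cds_codons] if spec.has_tga else [],
        "secis_local": secis_local,
        "cds": cds_with_stop,
        "protein": protein,
        "mrna": mrna,
    }
    return cassette, info


def _cds_to_cassette_offset(exon_nt, cds_off, intron_lengths):
    """Cassette offset (relative to the first exon base) of a CDS offset."""
    walked = 0
    extra = 0
    for i, nt in enumerate(exon_nt):
        if cds_off < walked + nt:
            return cds_off + extra
        walked += nt
        extra += intron_lengths[i]
    raise ValidationError("CDS offset beyond gene")


def plant_gene(record_seq: list, at: int, spec: GeneSpec, rng,
               seqid: str, gene_id: str, gc: float = 0.4) -> PlantedGene:
    """Overwrite record_seq (a mutable character list) at `at` with the gene
    cassette (reverse-complemented for minus-strand genes) and return the
    ground-truth entry in forward-strand coordinates."""
    cassette, info = build_gene_cassette(spec, rng, gc=gc)
    C = len(cassette)
    if at + C > len(record_seq):
        raise ValidationError("cassette does not fit at requested position")
    inserted = cassette if spec.strand == "+" else reverse_complement(cassette)
    record_seq[at:at + C] = list(inserted)

    def lift(local_start, local_end):
        if spec.strand == "+":
            return Interval(seqid, at + local_start, at + local_end, "+")
        return Interval(seqid, at + C - local_end, at + C - local_start, "-")

    exons = [lift(s, e) for s, e in info["exons"]]
    secis = [(lift(s, e), mc) for s, e, mc in info["secis_local"]]
    secs = []
    for p in info["sec_local"]:
        iv = lift(p, p + 3)
        secs.append(iv.start)
    kind = "gene" if spec.has_tga and spec.secis else \
        ("pseudogene" if spec.has_tga else "cys_paralog")
    return PlantedGene(
        gene_id=gene_id, family=spec.family, seqid=seqid,
        strand=spec.strand, exons=exons, sec_positions=secs, secis=secis,
        cds=info["cds"], protein=info["protein"], mrna=info["mrna"],
        kind=kind)


def plant_selenogene(record: GenomeRecord, spec: GeneSpec, seed,
                     at: int | None = None):
    """Spec-level convenience: plant one gene into a record, returning the
    modified record and the truth entry."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    chars = list(record.seq)
    cassette, _ = build_gene_cassette(spec, np.random.default_rng(0))
    if at is None:
        margin = len(cassette) + 200
        if record.length <= margin:
            raise ValidationError("record too short for the requested gene")
        at = int(rng.integers(0, record.length - margin))
    truth = plant_gene(chars, at, spec, rng, record.id, "gene1")
    return GenomeRecord(record.id, "".join(chars)), truth


# ---------------------------------------------------------------------------
# homologs and ESTs

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def mutate_protein(rng, protein: str, identity: float,
                   keep: set | None = None) -> str:
    """Substitute residues uniformly to reach the target identity."""
    n = len(protein)
    n_mut = int(round((1.0 - identity) * n))
    keep = keep or set()
    mutable = [i for i in range(n) if i not in keep and protein[i] != "U"]
    sites = rng.choice(mutable, size=min(n_mut, len(mutable)), replace=False)
    chars = list(protein)
    for i in sites:
        choices = [a for a in _AA20 if a != chars[i]]
        chars[i] = choices[rng.integers(len(choices))]
    return "".join(chars)


def make_homolog_db(truth: SyntheticTruth, identity: float = 0.6,
                    cys_substitute: bool = True, seed=0,
                    per_gene: int = 2) -> list:
    """(id, sequence, family) triples: mutated copies of planted proteins at
    the target identity, U->C when cys_substitute, family labels attached."""
    if not (0.0 < identity <= 1.0):
        raise ValidationError("identity must lie in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    db = []
    sources = [g for g in truth.genes + truth.decoys if g.protein]
    for g in sources:
        for h in range(per_gene):
            prot = mutate_protein(rng, g.protein, identity)
            if cys_substitute:
                prot = prot.replace("U", "C")
            db.append((f"{g.gene_id}_hom{h + 1}", prot, g.family))
    return db


def make_ests(truth: SyntheticTruth, n: int = 2000,
              length_range: tuple = (150, 600), error_rate: float = 0.01,
              seed=0) -> list:
    """(id, sequence) EST fragments: substrings of planted spliced mRNAs
    with point errors at the given rate."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    genes = [g for g in truth.genes if g.mrna]
    ests = []
    if not genes:
        return ests
    for i in range(n):
        g = genes[rng.integers(len(genes))]
        lo, hi = length_range
        length = int(rng.integers(lo, min(hi, len(g.mrna)) + 1))
        start = int(rng.integers(0, len(g.mrna) - length + 1))
        frag = list(g.mrna[start:start + length])
        n_err = rng.binomial(len(frag), error_rate)
        for j in rng.choice(len(frag), size=n_err, replace=False):
            frag[j] = "ACGT".replace(frag[j], "")[rng.integers(3)]
        ests.append((f"est{i + 1:05d}|{g.gene_id}", "".join(frag)))
    return ests


def make_training_cds(rng, n_seqs: int = 150, n_codons: int = 300) -> list:
    """Independent CDS sample from the codon-usage table for model training."""
    return ["ATG" + _sample_cds(rng, n_codons - 2) +
            ("TAA" if rng.random() < 0.5 else "TAG")
            for _ in range(n_seqs)]


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class SyntheticDataset:
    records: list
    truth: SyntheticTruth
    homolog_db: list             # (id, seq, family)
    ests: list                   # (id, seq)
    training_cds: list


def simulate(config: GeneratorConfig, outdir=None,
             extra_specs: list | None = None) -> SyntheticDataset:
    """Generate the full benchmark dataset deterministically from the seed.

    Features (genes, then decoys) are laid out left to right with random
    inter-feature gaps large enough to keep each gene's 3' search window
    clear of the next feature.
    """
    rng = np.random.default_rng(config.seed)
    chars = list(_bg(rng, config.genome_length, config.gc))
    seqid = "chr1"

    specs = list(extra_specs or [])
    for i in range(config.n_genes - len(specs)):
        fam = _FAMILY_CYCLE[i % len(_FAMILY_CYCLE)]
        specs.append(random_gene_spec(rng, config, fam))
    decoy_specs = []
    for i in range(config.n_pseudogenes):
        fam = _FAMILY_CYCLE[i % len(_FAMILY_CYCLE)]
        s = random_gene_spec(rng, config, fam, n_secis=0)
        decoy_specs.append(s)
    for i in range(config.n_cys_paralogs):
        fam = _FAMILY_CYCLE[(i + 3) % len(_FAMILY_CYCLE)]
        s = random_gene_spec(rng, config, fam, n_secis=0, has_tga=False)
        decoy_specs.append(s)

    truth = SyntheticTruth()
    all_specs = [(s, False) for s in specs] + [(s, True) for s in decoy_specs]
    # reserve each cassette's extent plus a clear 3' window
    extents = []
    for s, _ in all_specs:
        probe_rng = np.random.default_rng(0)
        cassette, _info = build_gene_cassette(s, probe_rng, gc=config.gc)
        extents.append(len(cassette) + 3200)
    needed = sum(extents)
    if needed >= config.genome_length:
        raise ValidationError("genome too small for requested features")
    slack = config.genome_length - needed
    gaps = rng.multinomial(slack - 1, np.ones(len(extents)) / len(extents))
    pos = 0
    for i, ((spec, is_decoy), ext) in enumerate(zip(all_specs, extents)):
        pos += int(gaps[i])
        gid = f"{'decoy' if is_decoy else 'gene'}{i + 1:03d}"
        g = plant_gene(chars, pos, spec, rng, seqid, gid, gc=config.gc)
        (truth.decoys if is_decoy else truth.genes).append(g)
        pos += ext
    record = GenomeRecord(seqid, "".join(chars))

    db = make_homolog_db(truth, identity=config.homolog_identity,
                         cys_substitute=True, seed=rng,
                         per_gene=config.homologs_per_gene)
    ests = make_ests(truth, n=config.n_ests,
                     length_range=config.est_length_range,
                     error_rate=config.est_error, seed=rng)
    training = make_training_cds(rng)
    ds = SyntheticDataset(records=[record], truth=truth, homolog_db=db,
                          ests=ests, training_cds=training)
    if outdir is not None:
        write_dataset(ds, outdir)
    return ds


class _Rec:
    def __init__(self, id, seq):
        self.id, self.seq = id, seq


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(ds.records, outdir / "genome.fa")
    write_fasta([_Rec(f"{i} family={f}", s) for i, s, f in ds.homolog_db],
                outdir / "proteins.faa")
    write_fasta([_Rec(i, s) for i, s in ds.ests], outdir / "ests.fa")
    write_fasta([_Rec(f"cds{i + 1:04d}", s)
                 for i, s in enumerate(ds.training_cds)],
                outdir / "training_cds.fa")
    (outdir / "truth.json").write_text(ds.truth.to_json())
    _write_truth_gff3(ds.truth, outdir / "truth.gff3")


def _write_truth_gff3(truth: SyntheticTruth, path) -> None:
    lines = ["##gff-version 3"]
    for g in truth.genes + truth.decoys:
        span = g.span
        attrs = f"ID={g.gene_id};family={g.family};kind={g.kind}"
        if g.sec_positions:
            attrs += ";sec_positions=" + ",".join(map(str, g.sec_positions))
        lines.append("\t".join([g.seqid, "synthetic", "gene",
                                str(span.start + 1), str(span.end), ".",
                                g.strand, ".", attrs]))
        for e in sorted(g.exons, key=lambda e: e.start):
            lines.append("\t".join([g.seqid, "synthetic", "CDS",
                                    str(e.start + 1), str(e.end), ".",
                                    g.strand, ".", f"Parent={g.gene_id}"]))
        for iv, mc in g.secis:
            lines.append("\t".join([g.seqid, "synthetic", "SECIS",
                                    str(iv.start + 1), str(iv.end), ".",
                                    g.strand, ".",
                                    f"Parent={g.gene_id};motif={mc}"]))
    Path(path).write_text("\n".join(lines) + "\n")
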