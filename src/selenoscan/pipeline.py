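"""End-to-end selenoprotein identification pipeline.

Stages: signal scan -> exon-candidate enumeration -> per-focal-TGA ORF
assembly -> translation -> Sec/Cys homology pairing -> SECIS detection ->
EST read-through annotation -> family assignment and reporting.  A call is
confirmed only if it has positive Sec/Cys pairing AND at least one SECIS
element; EST support is reported as corroboration, never required.
Rejected candidates go to an audit table with the failed criterion.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assembler, evidence, secis as secis_mod, signals
from .coding_model import MarkovModel, train_markov
from .genome_io import (GenomeRecord, Interval, ValidationError, read_fasta,
                        read_fasta_with_descriptions, reverse_complement,
                        write_bed, write_fasta, write_gff3)
from .synthetic import SyntheticTruth


@dataclass
class PipelineConfig:
    markov_k: int = 5
    pseudocount: float = 1.0
    training_cds: str | None = None      # FASTA of in-frame CDS, optional
    noncoding_sample_nt: int = 200_000   # drawn from the genome itself
    limits: signals.ExonLimits = field(default_factory=lambda:
                                       signals.ExonLimits(
                                           min_coding_potential=0.0))
    assembly: assembler.AssemblyParams = field(
        default_factory=assembler.AssemblyParams)
    evidence: evidence.EvidenceParams = field(
        default_factory=evidence.EvidenceParams)
    secis: secis_mod.SECISParams = field(default_factory=secis_mod.SECISParams)
    min_gene_score: float = 10.0         # bits; floor for assembled ORFs
    max_variants_per_locus: int = 3      # alternative structures evaluated
    cluster_max_gap: int = 50_000
    organism: str = "organism"
    seed: int = 0

    def validate(self) -> None:
        if self.markov_k < 0 or self.pseudocount <= 0:
            raise ValidationError("bad Markov settings")
        if self.min_gene_score < 0:
            raise ValidationError("min_gene_score must be >= 0")
        if self.cluster_max_gap <= 0:
            raise ValidationError("cluster_max_gap must be positive")
        # sub-configs validate in their constructors

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            if f.name == "limits":
                v = signals.ExonLimits(**v)
            elif f.name == "assembly":
                v = assembler.AssemblyParams(**v)
            elif f.name == "evidence":
                v = evidence.EvidenceParams(**v)
            elif f.name == "secis":
                v = secis_mod.SECISParams(**{k: tuple(x) if isinstance(x, list)
                                             else x for k, x in v.items()})
            kwargs[f.name] = v
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys {sorted(unknown)}")
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


@dataclass
class GenomeGene:
    """An assembled gene lifted to forward-strand genome coordinates."""

    seqid: str
    strand: str
    exon_intervals: list                 # Intervals sorted by start
    sec_positions: tuple                 # forward-strand TGA codon starts
    sec_protein_index: tuple             # protein offset of each Sec
    total_score: float
    protein: str
    cds: str                             # spliced, coding orientation
    utr3: str                            # downstream window, coding orient.

    @property
    def start(self) -> int:
        return self.exon_intervals[0].start

    @property
    def end(self) -> int:
        return self.exon_intervals[-1].end

    @property
    def span(self) -> Interval:
        return Interval(self.seqid, self.start, self.end, self.strand)

    @property
    def mrna(self) -> str:
        return self.cds + self.utr3


@dataclass
class SelenoproteinCall:
    gene: GenomeGene
    uc: evidence.UCEvidence | None
    secis_hits: list
    est: evidence.ESTEvidence | None
    family: str
    organism: str
    confirmed: bool
    rejection_reason: str | None = None


@dataclass
class GeneCluster:
    member_ids: list
    span: Interval
    family: str
    strands: list


@dataclass
class FamilySummary:
    table: pd.DataFrame       # rows = families (+ TOTAL), cols = organisms

    def validate(self) -> None:
        body = self.table.drop(index="TOTAL")
        if not (body.sum(axis=0) == self.table.loc["TOTAL"]).all():
            raise ValidationError("TOTAL row does not equal column sums")


@dataclass
class PipelineResult:
    calls: list               # confirmed
    audit: list               # rejected SelenoproteinCalls
    clusters: list
    summary: FamilySummary
    log: list


# ---------------------------------------------------------------------------

def _lift_model(model: assembler.GeneModel, record: GenomeRecord, strand: str,
                scan_seq: str, utr_window: int) -> GenomeGene:
    """Convert a scan-coordinate model to forward genome coordinates."""
    L = record.length
    exons = []
    for e in model.exons:
        if strand == "+":
            exons.append(Interval(record.id, e.start, e.end, "+"))
        else:
            exons.append(Interval(record.id, L - e.end, L - e.start, "-"))
    exons.sort(key=lambda iv: iv.start)
    cds = assembler.chain_cds(model.exons, scan_seq)
    stop_end = model.exons[-1].end          # scan coordinate after the stop
    utr3 = scan_seq[stop_end:stop_end + utr_window]
    sec_scan = model.sec_positions
    if strand == "+":
        sec_fwd = tuple(sec_scan)
    else:
        sec_fwd = tuple(L - p - 3 for p in sec_scan)
    # protein index of each Sec: offset of the codon within the spliced CDS
    offsets = []
    walked = 0
    for e in model.exons:
        pad = (3 - e.frame5) % 3
        for off in e.tga_offsets:
            offsets.append((walked + pad + 3 * off) // 3)
        walked += len(e.interval)
    return GenomeGene(seqid=record.id, strand=strand, exon_intervals=exons,
                      sec_positions=sec_fwd,
                      sec_protein_index=tuple(offsets),
                      total_score=model.total_score, protein=model.protein,
                      cds=cds, utr3=utr3)


def _cap_locus_variants(genes: list, max_variants: int) -> list:
    """Keep at most `max_variants` alternative structures per locus/strand.

    Models are clustered by genomic span overlap within a strand; each
    cluster keeps its top-scoring structures.  Evaluating an unbounded
    number of boundary variants per locus would multiply the chance of a
    spurious confirmation (each variant stop re-rolls the SECIS window),
    while the method's contract is one gene per locus.  Antisense shadow
    models are left for the evidence filter to remove."""
    out = []
    for strand in "+-":
        sub = sorted((g for g in genes if g.strand == strand),
                     key=lambda g: (g.seqid, g.start, g.end))
        cluster, cend, cseq = [], None, None
        def flush():
            cluster.sort(key=lambda g: (-g.total_score, g.start))
            out.extend(cluster[:max_variants])
        for g in sub:
            if cluster and g.seqid == cseq and g.start < cend:
                cluster.append(g)
                cend = max(cend, g.end)
            else:
                if cluster:
                    flush()
                cluster, cend, cseq = [g], g.end, g.seqid
        if cluster:
            flush()
    return sorted(out, key=lambda g: (g.seqid, g.start, g.strand))


def build_coding_model(config: PipelineConfig, records: list) -> MarkovModel:
    """Train the coding/noncoding Markov pair.

    Coding: the configured training CDS FASTA, or a built-in codon-usage
    sample when none is given.  Noncoding: windows drawn from the input
    genome itself (overwhelmingly noncoding in any draft assembly).
    """
    rng = np.random.default_rng(config.seed)
    if config.training_cds:
        coding = [r.seq for r in read_fasta(config.training_cds)]
        coding = [s[:len(s) - len(s) % 3] for s in coding]
    else:
        from .synthetic import make_training_cds
        coding = make_training_cds(np.random.default_rng(12345))
    noncoding = []
    need = config.noncoding_sample_nt
    for rec in records:
        take = min(need, rec.length)
        if take <= 0:
            break
        n_windows = max(1, take // 2000)
        maxstart = max(1, rec.length - 2000)
        starts = rng.integers(0, maxstart, size=n_windows)
        noncoding.extend(rec.seq[s:s + 2000] for s in starts)
        need -= take
    return train_markov(coding, noncoding, k=config.markov_k,
                        pseudocount=config.pseudocount)


def scan_record(record: GenomeRecord, coding: MarkovModel,
                config: PipelineConfig, signal_model=None) -> list:
    """Assemble candidate gene models on both strands of one record."""
    sm = signal_model or signals.default_signal_model()
    out = []
    for strand in "+-":
        seq = record.seq if strand == "+" else reverse_complement(record.seq)
        scan_rec = GenomeRecord(record.id, seq)
        sites = signals.scan_signals(scan_rec, sm)
        cands = signals.enumerate_exons(scan_rec, sites, coding,
                                        config.limits)
        models = assembler.assemble_all(
            cands, seq, config.assembly,
            min_gene_score=config.min_gene_score)
        for m in models:
            out.append(_lift_model(m, record, strand, seq,
                                   config.secis.window))
    return _cap_locus_variants(out, config.max_variants_per_locus)


def evaluate_gene(gene: GenomeGene, record: GenomeRecord, db,
                  config: PipelineConfig) -> SelenoproteinCall:
    """The confirmation filter (SECIS presence, then Sec/Cys pairing) for
    one gene model.  EST support and family are annotated later, once the
    surviving variants have been collapsed to one call per locus."""
    hits = secis_mod.find_secis(record, gene, config.secis)
    if not hits:
        return SelenoproteinCall(gene=gene, uc=None, secis_hits=[], est=None,
                                 family="novel", organism=config.organism,
                                 confirmed=False,
                                 rejection_reason="no_secis")
    best_uc = None
    for pidx in gene.sec_protein_index:
        if pidx >= len(gene.protein) or gene.protein[pidx] != "U":
            continue
        flank = evidence.extract_sec_flank(gene.protein, pidx,
                                           config.evidence.flank_window)
        # neighbouring Sec residues are scored as Cys; keep one focal U
        centre = min(config.evidence.flank_window, pidx)
        flank = "".join("C" if (c == "U" and i != centre) else c
                        for i, c in enumerate(flank))
        uc = evidence.find_uc_pairing(flank, db, config.evidence)
        if best_uc is None or uc.n_cys_paired > best_uc.n_cys_paired:
            best_uc = uc
        if uc.positive:
            break
    if best_uc is None or not best_uc.positive:
        return SelenoproteinCall(gene=gene, uc=best_uc, secis_hits=hits,
                                 est=None, family="novel",
                                 organism=config.organism, confirmed=False,
                                 rejection_reason="no_uc_pairing")
    return SelenoproteinCall(gene=gene, uc=best_uc, secis_hits=hits,
                             est=None, family="novel",
                             organism=config.organism, confirmed=True)


def annotate_call(call: SelenoproteinCall, db, ests,
                  config: PipelineConfig) -> None:
    """EST read-through support and family label for a confirmed call."""
    gene = call.gene
    sec_offsets = [3 * i for i in gene.sec_protein_index]
    call.est = evidence.est_support(sec_offsets, gene.mrna, ests,
                                    config.evidence) if ests else \
        evidence.ESTEvidence(n_spanning=0)
    call.family = evidence.assign_family(gene.protein, db)


def run_pipeline(genome_paths, protein_db_path, est_path=None,
                 config: PipelineConfig | None = None, outdir=None
                 ) -> PipelineResult:
    """Execute the full identification procedure and write report files."""
    config = config or PipelineConfig()
    config.validate()
    if isinstance(genome_paths, (str, Path)):
        genome_paths = [genome_paths]
    records = []
    for p in genome_paths:
        records.extend(read_fasta(p))
    db = [(rid, seq, _family_from_desc(desc))
          for rid, desc, seq in read_fasta_with_descriptions(protein_db_path)]
    ests = []
    if est_path:
        ests = [seq for _rid, _d, seq in
                read_fasta_with_descriptions(est_path)]
    return run_pipeline_objects(records, db, ests, config, outdir)


def run_pipeline_objects(records, db, ests, config: PipelineConfig,
                         outdir=None) -> PipelineResult:
    """Same as run_pipeline but over in-memory objects."""
    log = [f"config: k={config.markov_k} min_gene_score={config.min_gene_score}"
           f" secis_min_score={config.secis.min_score} seed={config.seed}"]
    coding = build_coding_model(config, records)
    confirmed, audit = [], []
    for rec in records:
        genes = scan_record(rec, coding, config)
        log.append(f"record {rec.id}: {len(genes)} candidate models")
        for gene in genes:
            call = evaluate_gene(gene, rec, db, config)
            (confirmed if call.confirmed else audit).append(call)
    n_variants = len(confirmed)
    confirmed = _dedup_confirmed(confirmed)
    for call in confirmed:
        annotate_call(call, db, ests, config)
    log.append(f"confirmed {len(confirmed)} "
               f"({n_variants - len(confirmed)} locus variants collapsed); "
               f"rejected {len(audit)}")
    clusters = detect_clusters(confirmed, config.cluster_max_gap)
    summary = summarize_families(confirmed)
    result = PipelineResult(calls=confirmed, audit=audit, clusters=clusters,
                            summary=summary, log=log)
    if outdir is not None:
        write_reports(result, outdir)
    return result


def _dedup_confirmed(calls: list) -> list:
    """One gene per locus: confirmed calls whose genomic CDS footprints
    overlap >= 50% collapse to the best-supported (then best-scoring) one."""
    kept = []
    for c in sorted(calls, key=lambda c: (-(c.uc.n_cys_paired if c.uc else 0),
                                          -c.gene.total_score,
                                          c.gene.start)):
        glen = sum(len(iv) for iv in c.gene.exon_intervals)
        dup = False
        for k in kept:
            if k.gene.seqid != c.gene.seqid or k.gene.strand != c.gene.strand:
                continue
            ov = sum(max(0, min(a.end, b.end) - max(a.start, b.start))
                     for a in c.gene.exon_intervals
                     for b in k.gene.exon_intervals)
            klen = sum(len(iv) for iv in k.gene.exon_intervals)
            if ov >= 0.5 * min(glen, klen):
                dup = True
                break
        if not dup:
            kept.append(c)
    kept.sort(key=lambda c: (c.gene.seqid, c.gene.start))
    return kept


def _family_from_desc(desc: str) -> str | None:
    for tok in desc.split():
        if tok.startswith("family="):
            return tok.split("=", 1)[1]
    return None


# ---------------------------------------------------------------------------
# reporting

def detect_clusters(calls, max_gap: int = 50_000) -> list:
    """Single-linkage tandem clusters of same-family calls on one seqid.

    Strand is ignored for membership (tandem arrays mix strands) and
    recorded per member.  A cluster needs at least 2 members.
    """
    by_key = {}
    for i, c in enumerate(calls):
        fam = evidence.collapse_family(c.family)
        by_key.setdefault((c.gene.seqid, fam), []).append((i, c))
    clusters = []
    for (seqid, fam), members in sorted(by_key.items()):
        members.sort(key=lambda ic: ic[1].gene.start)
        group = [members[0]]
        for item in members[1:]:
            prev = group[-1][1].gene
            if item[1].gene.start - prev.end <= max_gap:
                group.append(item)
            else:
                if len(group) >= 2:
                    clusters.append(_mk_cluster(seqid, fam, group))
                group = [item]
        if len(group) >= 2:
            clusters.append(_mk_cluster(seqid, fam, group))
    return clusters


def _mk_cluster(seqid, fam, group) -> GeneCluster:
    genes = [c.gene for _i, c in group]
    return GeneCluster(
        member_ids=[i for i, _c in group],
        span=Interval(seqid, min(g.start for g in genes),
                      max(g.end for g in genes), "+"),
        family=fam, strands=[g.strand for g in genes])


def summarize_families(calls) -> FamilySummary:
    """Count matrix: families x organisms, subfamilies collapsed, TOTAL row."""
    counts = {}
    organisms = []
    for c in calls:
        fam = evidence.collapse_family(c.family)
        org = c.organism
        if org not in organisms:
            organisms.append(org)
        counts[(fam, org)] = counts.get((fam, org), 0) + 1
    families = sorted({f for f, _ in counts})
    df = pd.DataFrame(0, index=families, columns=organisms, dtype=int)
    for (fam, org), n in counts.items():
        df.loc[fam, org] = n
    if len(df.columns):
        df.loc["TOTAL"] = df.sum(axis=0)
    else:
        df = pd.DataFrame(index=families + ["TOTAL"])
    summary = FamilySummary(table=df)
    summary.validate()
    return summary


def write_reports(result: PipelineResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gff3(result.calls, outdir / "calls.gff3")

    class _P:
        def __init__(self, id, seq):
            self.id, self.seq = id, seq

    prots = [_P(f"call{i + 1:04d} family={c.family}", c.gene.protein)
             for i, c in enumerate(result.calls)]
    write_fasta(prots, outdir / "proteins.faa")
    hits = [h for c in result.calls for h in c.secis_hits]
    write_bed(hits, outdir / "secis.bed")
    result.summary.table.to_csv(outdir / "summary.tsv", sep="\t")
    rows = []
    for c in result.audit:
        g = c.gene
        rows.append({"seqid": g.seqid, "start": g.start, "end": g.end,
                     "strand": g.strand, "score": round(g.total_score, 3),
                     "n_sec": len(g.sec_positions),
                     "reason": c.rejection_reason})
    pd.DataFrame(rows, columns=["seqid", "start", "end", "strand", "score",
                                "n_sec", "reason"]) \
        .to_csv(outdir / "audit.tsv", sep="\t", index=False)
    (outdir / "run.log").write_text("\n".join(result.log) + "\n")


# ---------------------------------------------------------------------------
# benchmarking against planted truth

def score_against_truth(calls, truth: SyntheticTruth) -> dict:
    """Sensitivity/precision of confirmed calls against planted genes.

    A call recovers a planted gene when it lies on the same record and
    strand, overlaps its span, and reports at least one of its Sec codon
    positions exactly.
    """
    def matches(call, g) -> bool:
        gene = call.gene
        if gene.seqid != g.seqid or gene.strand != g.strand:
            return False
        if gene.span.overlap(g.span) <= 0:
            return False
        return bool(set(gene.sec_positions) & set(g.sec_positions))

    recovered = set()
    tp = 0
    for call in calls:
        hit = None
        for g in truth.genes:
            if matches(call, g):
                hit = g
                break
        if hit is not None:
            tp += 1
            recovered.add(hit.gene_id)
    n_genes = len(truth.genes)
    sens = len(recovered) / n_genes if n_genes else float("nan")
    prec = tp / len(calls) if calls else float("nan")
    decoy_confirmed = sum(
        1 for call in calls for d in truth.decoys
        if call.gene.seqid == d.seqid
        and call.gene.span.overlap(d.span) > 0)
    return {"sensitivity": sens, "precision": prec,
            "n_confirmed": len(calls), "n_recovered": len(recovered),
            "n_decoys_confirmed": decoy_confirmed}


def secis_recall(records, truth: SyntheticTruth,
                 params: secis_mod.SECISParams | None = None) -> float:
    """Detector-level recall: fraction of planted SECIS elements found when
    scanning the 3' window of each planted gene's true structure."""
    params = params or secis_mod.SECISParams()
    by_id = {r.id: r for r in records}
    planted = found = 0
    for g in truth.genes:
        if not g.secis:
            continue
        hits = secis_mod.find_secis(by_id[g.seqid], _truth_gene_view(g),
                                    params)
        for iv, _mc in g.secis:
            planted += 1
            if any(h.interval.overlap(iv) > 0 for h in hits):
                found += 1
    return found / planted if planted else float("nan")


class _truth_gene_view:
    """Adapter giving a PlantedGene the gene interface find_secis expects."""

    def __init__(self, g):
        self.exon_intervals = sorted(g.exons, key=lambda e: e.start)
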