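# Methods

This note records the models, parameter choices and numerical conventions
behind `selenoscan`, and what the synthetic benchmark does and does not
establish about behaviour on real genomes.

## Coordinates and strands

All internal coordinates are 0-based half-open on the forward strand;
GFF3/BED emission converts at the output boundary (1-based inclusive for
GFF3). Minus-strand genes are found by scanning the reverse complement
with the same code path and reflecting coordinates afterwards. Sec
positions are reported as the forward-strand coordinate of the leftmost
base of the TGA codon. Windows containing N are scored as background and
cannot host signals; windows truncated by a contig edge are scored over
their in-range columns.

## Signal model

Each signal kind (start, stop, donor, acceptor, in-frame TGA) carries a
position weight matrix scored as log-odds (bits) against a uniform
background. The shipped defaults encode canonical eukaryotic site
strength: a weak Kozak-like start context (~3 bits of information), a
donor profile `MAG|GTAAGT` (~6 bits beyond the GT core) and an acceptor
profile with a 12-base polypyrimidine tract and `YCAG|G` (~9 bits beyond
the AG core). Weak splice profiles were tried first and discarded: with
only 3–4 bits of information, pseudo-sites in random sequence score close
to real sites and exon discrimination collapses onto the noisy Markov
term. `train_signal_model` re-estimates any profile from user-supplied
aligned windows.

## Coding potential

The coding model is an order-k Markov chain, 3-periodic (one transition
table per codon phase, contexts crossing codon boundaries); the noncoding
model is homogeneous. Defaults: k = 5, pseudocount 1 per transition, log
base 2. Sec-TGA codons in training CDS are ordinary coding triplets. An
exon's log-likelihood ratio is computed with its genomic left context
(the first k bases condition on the upstream sequence, intron or not);
this makes exon scoring a cumulative-sum lookup and is additive across
abutting windows. `score_llr` exposes the same convention through its
`context` argument, which is also how the additivity invariant is stated
exactly. The pipeline trains coding tables from a user CDS FASTA (or a
built-in codon-usage sample) and noncoding tables from 2 kb windows drawn
from the input genome itself — a draft assembly is overwhelmingly
noncoding, and the small coding admixture only dilutes contrast slightly.

## ORF assembly over exon chains

A gene model is a chain: initial exon (ATG) → internal exons → terminal
exon (TAA/TAG), splice-compatible (donor/acceptor phases continue, no
in-frame TAA/TAG anywhere) with intron lengths in [40, 3000] nt. The
chain score is the sum of exon coding potentials minus a junction cost
`8 + 0.02·len` bits. The length-proportional part matters: with any flat
penalty the optimiser will happily pay a few junctions to bridge tens of
kilobases of intergenic sequence and absorb a neighbouring gene's coding
exons, because the target gene contributes hundreds of bits. A cost
linear in intron length (the standard device in generalized-HMM gene
finders) makes long-range absorption pay ~2 bits per 100 nt and kills it,
while costing planted-scale introns (60–300 nt) only ~9–14 bits. The
fixed part (8 bits) and the slope were chosen against the background
exon-score null (exons with cp ≥ 12 occur at ~2.5/kb in 40% GC
background under the default models), not against any recovery target.
The intron ceiling of 3000 nt reflects compact invertebrate gene
geometry and is configurable.

For each focal in-frame-TGA exon the optimal chain through it is
`fwd(f) + bwd(f) − cp(f)`, with both sweeps computed once for all exons
using per-phase monotone deques (sliding-window maximum over the allowed
predecessor window; the linear length cost separates into the ranking
key). Ties break toward fewer exons, then leftmost start. All in-frame
TGAs inside the winning chain are designated Sec, and a TGA may not
terminate a model — in selenoprotein genes TGA is essentially never used
as the stop.

Models sharing ≥50% of their CDS *and* the same Sec set collapse to the
best scorer; boundary variants that disagree about where the Secs are all
survive to the evidence stage, because the score argmax is not always the
generative structure and homology is the right arbiter. Per locus and
strand, at most `max_variants_per_locus` (default 5) structures are
evaluated: each variant's stop re-rolls the 3' SECIS window, so an
unbounded variant list multiplies the spurious-confirmation rate.
Candidate ORFs below `min_gene_score` (default 10 bits) are dropped;
the floor sits at the expected score of the smallest plausible gene
(~25 codons) minus sampling fluctuation, while background chain maxima
on megabase scales reach only ~15–25 bits.

## Homology evidence

`local_align` is affine-gap Smith–Waterman under BLOSUM62 (gap open 11,
extend 1), with U scored as C so Sec- and Cys-form homologs behave
identically (biotite's C implementation stands behind the module surface;
the test suite checks it against an independent textbook implementation).
Sec/Cys pairing takes a ±20-residue flank around each Sec, requires a hit
with raw score ≥45 — roughly 22 bits, i.e. an expect value near 1 for a
40-residue query against a desk-scale database; `calibrate_score_threshold`
recalibrates from shuffled-database quantiles for other database sizes —
plus C (or U) in the column aligned to the U and ≥30% identical columns
over the flank length. Without the raw-score floor, very short flanks
from junk micro-ORFs pair trivially (three matches suffice at 30% of a
10-residue flank).

Family assignment takes the best database hit above score 60 and identity
0.25, collapsing subfamily labels (DI1 → DI, SelU3_b → SelU; names that
are themselves families, like Sel15, are preserved); below threshold the
call is "novel".

EST support places each fragment on the call's transcript (spliced CDS
plus the un-spliced 3' window) by full-length infix alignment (edlib),
both orientations, and counts fragments covering a Sec codon with ≥50 nt
on each side at ≥95% identity. Because placement is full-length, ESTs
crossing a mis-predicted 3' boundary do not count — EST support is
deliberately conservative and is annotation, not a confirmation
criterion.

## SECIS detection

The structural model is the canonical eukaryotic SECIS topology: helix I
(6–16 bp), internal loop (1–20 nt per side), helix II (8–18 bp) whose
first four pairs are the non-Watson-Crick quartet opening with UGA on the
5' side, preceded by an unpaired A or G (classifying AUGA_AA vs GUGA_AA),
and an apical loop (8–22 nt) containing AA. GU pairs are allowed in
helices. The score is additive: 2 per WC pair, 1 per GU pair, −0.5 per
loop nucleotide beyond the minima, +3 core-motif bonus; it is *not*
comparable to covariance-model scores. The acceptance threshold
(min_score 18) was calibrated once on the uniform-random null to hold the
false-hit rate ≤1% per 300 nt window (measured 0.4–0.6%); elements with
geometry inside the ranges score ≥25 by construction. The search window
is 3000 nt downstream of the stop on the coding strand, truncated at
contig edges; hits are greedily non-overlapping by score.

## Confirmation filter

A call is confirmed iff U/C pairing is positive AND ≥1 SECIS hit exists.
EST evidence is never required (transcriptome coverage is an accident of
sampling). Confirmed variants then collapse to one gene per locus
(≥50% CDS footprint overlap, preferring more Cys-paired homologs, then
score). Rejected candidates are written to the audit table with the first
failed criterion (`no_secis` is tested first because it is cheap).
Antisense shadow models are not removed structurally; the evidence filter
eliminates them.

## Synthetic benchmark

The generator emulates the scanning problem at desk scale: i.i.d.
background at 40% GC; 20 genes of 1–9 exons (25–90 codons each, introns
60–300 nt, 1–3 Sec per gene placed ≥5 codons from the termini); splice
and start contexts sampled from the same default profiles the scanner
scores with; coding sequence sampled from a fixed biased codon-usage
table, while the scoring tables are trained on a *separate* CDS sample
from that distribution (no circularity through the planted genes
themselves); one SECIS per gene (the multi-Sec SelP fixture has two) with
geometry strictly inside the detector ranges; 6 pseudogene decoys (full
selenoprotein genes without SECIS — they carry homologs and must be
rejected by the SECIS criterion) and 4 Cys-paralog decoys (TGC instead of
TGA — invisible to the scanner by construction); homologs at 60% identity
with U→C; 2000 ESTs of 150–600 nt at 1% substitution error. Ground truth
records every planted coordinate.

What passing does not show: real genomes have repeats, isochores,
pseudo-exons with realistic splice-site statistics, homolog databases
with paralogy structure, and SECIS elements whose geometry drifts outside
any fixed ranges. The benchmark validates the machinery and its
composition, not field performance; the thresholds above would need
recalibration on real nulls.

## Problem sizes and determinism

The standard benchmark (2 Mb, 30 planted structures) runs the full
pipeline in ~40 s on one CPU; the acceptance script repeats it plus all
component checks in about a minute. Everything is deterministic given the
seeds: training, scanning and assembly contain no randomness, generator
and noncoding-sampling randomness comes from explicit seeded generators,
and `run.log` deliberately contains stage record counts and a parameter
echo rather than wall-clock timings so that identical runs produce
byte-identical reports.

## Known limitations

- Boundary accuracy is that of ab initio prediction: the score argmax can
  differ from the true structure at internal splice sites, and chains
  occasionally extend past the true terminal exon, displacing the SECIS
  window (the dominant residual failure mode on the benchmark).
- Stop codons split across an intron junction are not modelled during
  enumeration; the chain validator catches and discards such models.
- Sec codons whose TGA is split by an intron are not representable.
- Very short single-exon genes near the 10-bit score floor can be missed
  when their composition fluctuates low.
- The U/C pairing null rate is calibrated for desk-scale databases; large
  databases need the shuffled-quantile recalibration.
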