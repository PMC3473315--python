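# selenoscan

Selenoprotein genes are systematically broken by standard gene annotation:
their defining residue, selenocysteine (Sec, U), is encoded by the TGA stop
codon, so ordinary gene finders either truncate the open reading frame at
the Sec codon or discard the gene entirely. `selenoscan` identifies these
genes directly in genome assemblies by treating every in-frame TGA as a
potential Sec codon and demanding the two signatures that make the
recoding credible: homologs that place cysteine at the same position
(U/C pairing) and a SECIS stem-loop in the 3' UTR.

It is aimed at people annotating new (especially invertebrate) genome
assemblies, and at anyone benchmarking selenoprotein callers: the package
ships a synthetic-genome generator that plants multi-exon selenoprotein
genes, Cys-form homologs, ESTs and decoy pseudogenes with exact ground
truth.

## Method

For a genome sequence the pipeline:

1. **Scans both strands** for gene signals — ATG, TAA/TAG, GT donors, AG
   acceptors and all TGA codons — scoring each with a position weight
   matrix (log-odds, bits).
2. **Enumerates exon candidates** of all four kinds (initial, internal,
   terminal, single) from compatible signal pairs. An exon may contain
   in-frame TGA codons (recorded, never rejected) but no in-frame
   TAA/TAG. Its *coding potential* is

   `cp(exon) = signal scores + log2 P(seq | coding) − log2 P(seq | noncoding)`

   where the coding model is a 3-periodic Markov chain (one transition
   table per codon phase) and the noncoding model is homogeneous, both
   trained from data.
3. **Assembles, for every exon carrying an in-frame TGA, the maximal
   coding-potential ORF containing it** — a chain of splice-compatible
   exons from an ATG to a TAA/TAG stop, scored as the sum of member
   coding potentials minus a junction cost `a + b·(intron length)`.
   The optimum over all chains through each focal exon comes from one
   forward and one backward sweep (sliding-window maxima), so the whole
   genome costs O(E log E). Every in-frame TGA inside the winning chain is
   designated Sec; a TGA never terminates a model.
4. **Confirms** each candidate: the translated protein's Sec-flanking
   window must align to a database homolog with C (or U) opposite the U
   (Smith–Waterman, BLOSUM62, U scored as C), and the 3' UTR window must
   contain a SECIS stem-loop — two helices, an internal loop whose last
   unpaired base before the non-Watson-Crick quartet is A or G (the
   AUGA_AA / GUGA_AA core), and an apical loop with AA. Both criteria are
   required; EST read-through support (spliced fragments covering the
   Sec-TGA with anchored flanks) is reported as corroboration.
5. **Reports** confirmed calls (GFF3, protein FASTA, SECIS BED), tandem
   same-family gene clusters, and a families × organisms count matrix;
   rejected candidates go to an audit table with the failed criterion.

## Worked example

Simulate a 200 kb benchmark genome with 4 planted selenoprotein genes and
3 decoys, then run the pipeline on it:

```bash
selenoscan simulate --config sim.yaml --out demo/sim --seed 7
selenoscan run --genome demo/sim/genome.fa --proteins demo/sim/proteins.faa \
    --ests demo/sim/ests.fa --config run.yaml --out demo/out --seed 1
```

(where `sim.yaml` sets `genome_length: 200000`, `n_genes: 4`,
`n_pseudogenes: 2`, `n_cys_paralogs: 1`, `n_ests: 300`, and `run.yaml`
points `training_cds` at the simulated training set). The same run through
the Python API prints:

```
confirmed calls: 3 (rejected 44)
  chr1:23971-25730(+) family=Gpx n_sec=1 secis=1 est_support=1 score=106.8
  chr1:54477-56190(+) family=DI n_sec=2 secis=1 est_support=13 score=112.0
  chr1:85069-85443(-) family=SelP n_sec=2 secis=1 est_support=0 score=52.2
```

Each line is one confirmed selenoprotein gene: its locus and strand, the
family assigned by best homology hit, the number of Sec codons in the
model, the number of SECIS elements found downstream, how many ESTs span a
Sec-TGA with 50 nt anchors at ≥95% identity, and the ORF's coding
potential in bits. Three of the four planted genes are recovered here
(the fourth is a weak short single-exon gene below the score floor);
the two pseudogene decoys are rejected for lacking a SECIS, and the
Cys-paralog decoy never seeds a model because it has no in-frame TGA.
`demo/out/` then contains `calls.gff3`, `proteins.faa`, `secis.bed`,
`summary.tsv` (the family count matrix with its TOTAL row), `audit.tsv`
and `run.log`.

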