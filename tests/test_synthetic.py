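"""Synthetic benchmark generator: determinism, truth consistency, rates."""

import numpy as np
import pytest

from selenoscan.genome_io import (GenomeRecord, ValidationError,
                                  spliced_sequence, translate_cds)
from selenoscan.synthetic import (GeneratorConfig, GeneSpec,
                                  generate_background, make_ests,
                                  make_homolog_db, plant_selenogene,
                                  selp_like_spec, simulate)


class TestBackground:
    def test_deterministic_per_seed(self):
        a = generate_background(1000, 0.5, 7)
        b = generate_background(1000, 0.5, 7)
        assert a.seq == b.seq

    def test_gc_one_is_pure_gc(self):
        assert set(generate_background(500, 1.0, 3).seq) <= {"G", "C"}

    def test_gc_converges_at_scale(self):
        seq = generate_background(300_000, 0.40, 11).seq
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.40) < 0.01

    def test_length_must_be_positive(self):
        with pytest.raises(ValidationError):
            generate_background(0, 0.4, 1)


class TestPlanting:
    def test_truth_matches_genome(self, small_dataset):
        rec = small_dataset.records[0]
        for g in small_dataset.truth.genes + small_dataset.truth.decoys:
            cds = spliced_sequence(rec, g.exons)
            assert cds == g.cds
            assert translate_cds(
                cds, sec_readthrough=(g.kind != "cys_paralog")) == g.protein
            for sp in g.sec_positions:
                codon = rec.seq[sp:sp + 3]
                assert codon == ("TGA" if g.strand == "+" else "TCA")

    def test_structures_do_not_overlap(self, small_dataset):
        spans = sorted((g.span.start, g.span.end) for g in
                       small_dataset.truth.genes + small_dataset.truth.decoys)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_single_gene_op(self):
        bg = generate_background(10_000, 0.4, 2)
        spec = GeneSpec(n_exons=1, exon_codons=[40], sec_cds_codons=[20],
                        secis=["AUGA_AA"], secis_offsets=[300])
        rec, truth = plant_selenogene(bg, spec, seed=3)
        assert len(truth.exons) == 1
        assert len(truth.sec_positions) == 1
        assert len(truth.secis) == 1
        assert rec.length == bg.length
        assert truth.protein.count("U") == 1

    def test_gene_too_large_for_record(self):
        bg = generate_background(500, 0.4, 2)
        spec = selp_like_spec()
        with pytest.raises(ValidationError):
            plant_selenogene(bg, spec, seed=3)

    def test_selp_architecture(self):
        """The flagship fixture: 8 exons, Sec on coding exons 1/3/5 plus two
        C-terminal Secs, two SECIS elements."""
        bg = generate_background(30_000, 0.4, 5)
        rec, truth = plant_selenogene(GenomeRecord("locus", bg.seq),
                                      selp_like_spec(), seed=99, at=4000)
        assert len(truth.exons) == 8
        assert len(truth.sec_positions) == 5
        assert truth.protein.count("U") == 5
        assert len(truth.secis) == 2
        exons = sorted(truth.exons, key=lambda e: e.start)
        first_three = [p for p in sorted(truth.sec_positions)[:3]]
        hosts = []
        for p in first_three:
            hosts.append(next(i for i, e in enumerate(exons)
                              if e.start <= p < e.end))
        assert hosts == [0, 2, 4]
        assert all(exons[7].start <= p < exons[7].end
                   for p in sorted(truth.sec_positions)[3:])


class TestHomologs:
    def test_identity_one_is_cys_swap(self, small_dataset):
        db = make_homolog_db(small_dataset.truth, identity=1.0,
                             cys_substitute=True, seed=1, per_gene=1)
        prots = {g.gene_id: g.protein for g in
                 small_dataset.truth.genes + small_dataset.truth.decoys}
        for hid, seq, _fam in db:
            src = prots[hid.rsplit("_hom", 1)[0]]
            assert seq == src.replace("U", "C")

    def test_sec_form_retains_u(self, small_dataset):
        db = make_homolog_db(small_dataset.truth, identity=1.0,
                             cys_substitute=False, seed=1, per_gene=1)
        assert any("U" in seq for _i, seq, _f in db)

    def test_realized_identity_near_target(self, small_dataset):
        db = make_homolog_db(small_dataset.truth, identity=0.6,
                             cys_substitute=True, seed=5, per_gene=2)
        prots = {g.gene_id: g.protein.replace("U", "C") for g in
                 small_dataset.truth.genes + small_dataset.truth.decoys}
        for hid, seq, _f in db:
            src = prots[hid.rsplit("_hom", 1)[0]]
            ident = sum(a == b for a, b in zip(src, seq)) / len(src)
            assert abs(ident - 0.6) < 0.05

    def test_identity_zero_rejected(self, small_dataset):
        with pytest.raises(ValidationError):
            make_homolog_db(small_dataset.truth, identity=0.0)


class TestEsts:
    def test_zero_error_gives_exact_substrings(self, small_dataset):
        ests = make_ests(small_dataset.truth, n=30, error_rate=0.0, seed=2)
        mrnas = [g.mrna for g in small_dataset.truth.genes]
        for _i, seq in ests:
            assert any(seq in m for m in mrnas)

    def test_n_zero_is_empty(self, small_dataset):
        assert make_ests(small_dataset.truth, n=0) == []

    def test_error_rate_realized(self, small_dataset):
        rate = 0.01
        ests = make_ests(small_dataset.truth, n=400,
                         length_range=(200, 400), error_rate=rate, seed=9)
        mrnas = [g.mrna for g in small_dataset.truth.genes]
        import edlib
        errs = total = 0
        for _i, seq in ests:
            best = min(edlib.align(seq, m, mode="HW")["editDistance"]
                       for m in mrnas)
            errs += best
            total += len(seq)
        realized = errs / total
        assert abs(realized - rate) / rate < 0.2

    def test_provenance_recorded_in_ids(self, small_dataset):
        ests = make_ests(small_dataset.truth, n=5, seed=2)
        gene_ids = {g.gene_id for g in small_dataset.truth.genes}
        for eid, _s in ests:
            assert eid.split("|")[1] in gene_ids


class TestSimulate:
    def test_deterministic(self):
        cfg = GeneratorConfig(genome_length=80_000, n_genes=2,
                              n_pseudogenes=1, n_cys_paralogs=0,
                              n_ests=10, seed=31)
        a, b = simulate(cfg), simulate(cfg)
        assert a.records[0].seq == b.records[0].seq
        assert a.truth.to_json() == b.truth.to_json()
        assert a.homolog_db == b.homolog_db
        assert a.ests == b.ests

    def test_genome_too_small_rejected(self):
        cfg = GeneratorConfig(genome_length=10_000, n_genes=5, seed=1)
        with pytest.raises(ValidationError):
            simulate(cfg)

    def test_decoy_census(self, small_dataset):
        kinds = [d.kind for d in small_dataset.truth.decoys]
        assert kinds.count("pseudogene") == 1
        assert kinds.count("cys_paralog") == 1
        for d in small_dataset.truth.decoys:
            assert not d.secis

    def test_dataset_files_round_trip(self, small_dataset, tmp_path):
        from selenoscan.genome_io import read_fasta
        from selenoscan.synthetic import write_dataset
        write_dataset(small_dataset, tmp_path)
        for name in ("genome.fa", "proteins.faa", "ests.fa",
                     "training_cds.fa", "truth.json", "truth.gff3"):
            assert (tmp_path / name).exists(), name
        assert read_fasta(tmp_path / "genome.fa")[0].seq == \
            small_dataset.records[0].seq


def test_closed_loop_confirmation():
    """Every planted gene, given its own perfect-identity homolog database,
    is confirmed by the full pipeline."""
    from selenoscan.pipeline import (PipelineConfig, run_pipeline_objects,
                                     score_against_truth)
    cfg = GeneratorConfig(genome_length=100_000, n_genes=3, n_pseudogenes=0,
                          n_cys_paralogs=0, n_ests=50, seed=55,
                          homolog_identity=1.0)
    ds = simulate(cfg)
    res = run_pipeline_objects(ds.records, ds.homolog_db,
                               [s for _i, s in ds.ests],
                               PipelineConfig(seed=2))
    m = score_against_truth(res.calls, ds.truth)
    assert m["sensitivity"] == 1.0
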