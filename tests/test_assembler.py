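"""Exon-chain assembly: compatibility, optimality, translation."""

import itertools

import numpy as np
import pytest

from selenoscan.genome_io import Interval, ValidationError
from selenoscan.assembler import (AssemblyParams, assemble_all,
                                  assemble_best_orf, chain_score, compatible,
                                  translate_gene, validate_gene_model)
from selenoscan.signals import ExonCandidate


def _exon(start, end, kind, f5, cp=1.0, tga=()):
    f3 = (f5 + (end - start)) % 3
    return ExonCandidate(interval=Interval("c", start, end, "+"), kind=kind,
                         frame5=f5, frame3=f3, has_inframe_tga=bool(tga),
                         tga_offsets=tuple(tga), coding_potential=cp)


class TestCompatible:
    def test_phase_continuation(self):
        a = _exon(0, 100, "internal", 0)      # frame3 = 1
        b = _exon(200, 260, "internal", a.frame3)
        assert compatible(a, b, 40)

    def test_gap_below_minimum(self):
        a = _exon(0, 99, "internal", 0)
        b = _exon(109, 160, "internal", a.frame3)
        assert not compatible(a, b, 40)

    def test_gap_above_maximum(self):
        a = _exon(0, 99, "internal", 0)
        b = _exon(5000, 5060, "internal", a.frame3)
        assert not compatible(a, b, 40, max_intron=3000)

    def test_exhaustive_kind_phase_truth_table(self):
        """All kind/phase combinations against a first-principles oracle."""
        kinds = ["initial", "internal", "terminal", "single"]
        for ka, kb, f3, f5 in itertools.product(kinds, kinds, range(3),
                                                range(3)):
            length_a = 90 + ((f3 - 0) % 3)    # frame5=0 -> frame3 == f3
            a = _exon(0, length_a, ka, 0)
            b = _exon(length_a + 100, length_a + 160, kb, f5)
            expected = (ka in ("initial", "internal")
                        and kb in ("internal", "terminal")
                        and a.frame3 == f5)
            assert compatible(a, b, 40) == expected, (ka, kb, f3, f5)


def _random_instance(rng, n_cands):
    """Random candidate set on a line; at least one exon carries a TGA."""
    cands = []
    pos = 0
    for _ in range(n_cands):
        pos += int(rng.integers(0, 400))
        length = int(rng.integers(30, 200))
        kind = ["initial", "internal", "terminal", "single"][
            rng.integers(4)]
        f5 = 0 if kind in ("initial", "single") else int(rng.integers(3))
        if kind in ("terminal", "single"):
            length += (3 - (f5 + length) % 3) % 3   # frame3 == 0
        tga = (1,) if rng.random() < 0.5 else ()
        cands.append(_exon(pos, pos + length, kind, f5,
                           cp=float(np.round(rng.normal(10, 8), 3)),
                           tga=tga))
        pos += length
    focals = [c for c in cands if c.has_inframe_tga]
    if not focals:
        c = cands[rng.integers(len(cands))]
        c = _exon(c.start, c.end, c.kind, c.frame5, c.coding_potential, (0,))
        cands[[i for i, x in enumerate(cands)][0]] = c
        focals = [c]
    return cands, focals[rng.integers(len(focals))]


def _oracle_best_chain(focal, cands, params):
    """Exhaustive enumeration of all valid chains through the focal exon."""
    best = None
    n = len(cands)
    order = sorted(range(n), key=lambda i: cands[i].start)
    for r in range(1, n + 1):
        for combo in itertools.combinations(order, r):
            chain = [cands[i] for i in combo]
            if focal not in chain:
                continue
            if chain[0].kind not in ("initial", "single"):
                continue
            if chain[-1].kind not in ("terminal", "single"):
                continue
            if len(chain) == 1 and chain[0].kind != "single":
                continue
            if len(chain) > 1 and any(c.kind == "single" for c in chain):
                continue
            if any(not compatible(a, b, params.min_intron, params.max_intron)
                   for a, b in zip(chain, chain[1:])):
                continue
            s = chain_score(chain, params)
            if best is None or s > best:
                best = s
    return best


class TestAssembleBestOrf:
    def test_valid_single_exon_alone(self):
        seq = "ATGTGATAA" + "A" * 50
        focal = _exon(0, 9, "single", 0, cp=7.5, tga=(1,))
        model = assemble_best_orf(focal, [focal], AssemblyParams(), seq=seq)
        assert model is not None
        assert model.exons == (focal,)
        assert model.total_score == pytest.approx(7.5)
        assert model.protein == "MU"
        assert model.sec_positions == (3,)

    def test_focal_without_tga_rejected(self):
        focal = _exon(0, 12, "single", 0)
        with pytest.raises(ValidationError):
            assemble_best_orf(focal, [focal])

    def test_none_when_no_chain_exists(self):
        focal = _exon(100, 190, "internal", 0, tga=(2,))
        assert assemble_best_orf(focal, [focal]) is None

    def test_matches_brute_force_on_100_instances(self):
        """DP optimum equals exhaustive chain enumeration (<=12 exons)."""
        params = AssemblyParams()
        rng = np.random.default_rng(2024)
        n_solved = 0
        for trial in range(100):
            cands, focal = _random_instance(rng, int(rng.integers(4, 13)))
            expect = _oracle_best_chain(focal, cands, params)
            model = assemble_best_orf(focal, cands, params)
            if expect is None:
                assert model is None, trial
            else:
                assert model is not None, trial
                assert model.total_score == pytest.approx(expect), trial
                n_solved += 1
        assert n_solved > 20   # the harness produced real instances

    def test_deterministic_chains(self, rng):
        params = AssemblyParams()
        cands, focal = _random_instance(np.random.default_rng(5), 12)
        a = assemble_best_orf(focal, cands, params)
        b = assemble_best_orf(focal, list(reversed(cands)), params)
        if a is not None:
            assert [(e.start, e.end) for e in a.exons] == \
                [(e.start, e.end) for e in b.exons]


class TestAssembleAll:
    def test_planted_gene_recovered_with_valid_invariants(
            self, small_dataset, small_coding_model):
        from selenoscan.genome_io import GenomeRecord
        from selenoscan.signals import (ExonLimits, default_signal_model,
                                        enumerate_exons, scan_signals)
        rec = small_dataset.records[0]
        g = next(g for g in small_dataset.truth.genes if g.strand == "+")
        lo = max(0, g.span.start - 2000)
        locus = GenomeRecord("locus", rec.seq[lo:g.span.end + 2000])
        sites = scan_signals(locus, default_signal_model())
        cands = enumerate_exons(locus, sites, small_coding_model,
                                ExonLimits(min_coding_potential=0.0))
        params = AssemblyParams()
        models = assemble_all(cands, locus.seq, params, min_gene_score=10)
        assert models
        for m in models:
            # every emitted model satisfies the gene-model invariants
            assert validate_gene_model(list(m.exons), locus.seq, params) \
                == m.protein
            assert m.protein.count("U") == len(m.sec_positions)
        shifted_secs = {p + lo for m in models for p in m.sec_positions}
        assert set(g.sec_positions) <= shifted_secs

    def test_translate_gene_matches_planted_protein(
            self, small_dataset, small_coding_model):
        from selenoscan.genome_io import GenomeRecord
        from selenoscan.signals import (ExonLimits, default_signal_model,
                                        enumerate_exons, scan_signals)
        rec = small_dataset.records[0]
        g = next(g for g in small_dataset.truth.genes if g.strand == "+")
        lo = max(0, g.span.start - 500)
        locus = GenomeRecord("locus", rec.seq[lo:g.span.end + 500])
        sites = scan_signals(locus, default_signal_model())
        cands = enumerate_exons(locus, sites, small_coding_model,
                                ExonLimits(min_coding_potential=0.0))
        models = assemble_all(cands, locus.seq, AssemblyParams(),
                              min_gene_score=10)
        exact = [m for m in models
                 if [(e.start + lo, e.end + lo) for e in m.exons]
                 == [(e.start, e.end) for e in g.exons]]
        assert exact and exact[0].protein == g.protein
        assert translate_gene(exact[0], locus.seq) == g.protein
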