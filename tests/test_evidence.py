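"""Homology evidence: alignment, Sec/Cys pairing, families, EST support."""

import numpy as np
import pytest

from selenoscan.genome_io import ValidationError
from selenoscan.evidence import (EvidenceParams, assign_family,
                                 calibrate_score_threshold, collapse_family,
                                 est_support, extract_sec_flank,
                                 find_uc_pairing, local_align)

AA = "ACDEFGHIKLMNPQRSTVWY"

# BLOSUM62 diagonal, transcribed independently of the aligner
_B62_DIAG = {"A": 4, "R": 5, "N": 6, "D": 6, "C": 9, "Q": 5, "E": 5,
             "G": 6, "H": 8, "I": 4, "L": 4, "K": 5, "M": 5, "F": 6,
             "P": 7, "S": 4, "T": 5, "W": 11, "Y": 7, "V": 4}

# full BLOSUM62 for the Smith-Waterman oracle (upper triangle spec)
_B62 = {}


def _blosum62(a, b):
    if not _B62:
        rows = """A  4 -1 -2 -2  0 -1 -1  0 -2 -1 -1 -1 -1 -2 -1  1  0 -3 -2  0
R -1  5  0 -2 -3  1  0 -2  0 -3 -2  2 -1 -3 -2 -1 -1 -3 -2 -3
N -2  0  6  1 -3  0  0  0  1 -3 -3  0 -2 -3 -2  1  0 -4 -2 -3
D -2 -2  1  6 -3  0  2 -1 -1 -3 -4 -1 -3 -3 -1  0 -1 -4 -3 -3
C  0 -3 -3 -3  9 -3 -4 -3 -3 -1 -1 -3 -1 -2 -3 -1 -1 -2 -2 -1
Q -1  1  0  0 -3  5  2 -2  0 -3 -2  1  0 -3 -1  0 -1 -2 -1 -2
E -1  0  0  2 -4  2  5 -2  0 -3 -3  1 -2 -3 -1  0 -1 -3 -2 -2
G  0 -2  0 -1 -3 -2 -2  6 -2 -4 -4 -2 -3 -3 -2  0 -2 -2 -3 -3
H -2  0  1 -1 -3  0  0 -2  8 -3 -3 -1 -2 -1 -2 -1 -2 -2  2 -3
I -1 -3 -3 -3 -1 -3 -3 -4 -3  4  2 -3  1  0 -3 -2 -1 -3 -1  3
L -1 -2 -3 -4 -1 -2 -3 -4 -3  2  4 -2  2  0 -3 -2 -1 -2 -1  1
K -1  2  0 -1 -3  1  1 -2 -1 -3 -2  5 -1 -3 -1  0 -1 -3 -2 -2
M -1 -1 -2 -3 -1  0 -2 -3 -2  1  2 -1  5  0 -2 -1 -1 -1 -1  1
F -2 -3 -3 -3 -2 -3 -3 -3 -1  0  0 -3  0  6 -4 -2 -2  1  3 -1
P -1 -2 -2 -1 -3 -1 -1 -2 -2 -3 -3 -1 -2 -4  7 -1 -1 -4 -3 -2
S  1 -1  1  0 -1  0  0  0 -1 -2 -2  0 -1 -2 -1  4  1 -3 -2 -2
T  0 -1  0 -1 -1 -1 -1 -2 -2 -1 -1 -1 -1 -2 -1  1  5 -2 -2  0
W -3 -3 -4 -4 -2 -2 -3 -2 -2 -3 -2 -3 -1  1 -4 -3 -2 11  2 -3
Y -2 -2 -2 -3 -2 -1 -2 -3  2 -1 -1 -2 -1  3 -3 -2 -2  2  7 -1
V  0 -3 -3 -3 -1 -2 -2 -3 -3  3  1 -2  1 -1 -2 -2  0 -3 -1  4"""
        order = "ARNDCQEGHILKMFPSTWYV"
        for line in rows.strip().splitlines():
            parts = line.split()
            for j, v in enumerate(parts[1:]):
                _B62[(parts[0], order[j])] = int(v)
    return _B62[(a, b)]


def _sw_oracle(q, s, gap_open=11, gap_extend=1):
    """Textbook affine-gap local alignment score (quadratic space).

    A gap of length L costs gap_open + (L-1) * gap_extend."""
    n, m = len(q), len(s)
    NEG = -10**9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG, dtype=float)   # gap in s (up)
    F = np.full((n + 1, m + 1), NEG, dtype=float)   # gap in q (left)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - gap_open, E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - gap_open, F[i][j - 1] - gap_extend)
            H[i][j] = max(0.0,
                          H[i - 1][j - 1] + _blosum62(q[i - 1], s[j - 1]),
                          E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestExtractFlank:
    def test_window_one(self):
        assert extract_sec_flank("AAUAA", 2, 1) == "AUA"

    def test_terminal_truncation(self):
        assert extract_sec_flank("UAAAAAAA", 0, 5) == "UAAAAA"

    def test_non_u_position_rejected(self):
        with pytest.raises(ValidationError):
            extract_sec_flank("ACDEF", 2, 3)

    def test_matches_slicing_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 60))
            prot = "".join(rng.choice(list(AA), size=n))
            i = int(rng.integers(n))
            prot = prot[:i] + "U" + prot[i + 1:]
            w = int(rng.integers(1, 30))
            assert extract_sec_flank(prot, i, w) == \
                prot[max(0, i - w):i + w + 1]


class TestLocalAlign:
    def test_identical_sequences(self, rng):
        pep = "".join(rng.choice(list(AA), size=20))
        hit = local_align(pep, pep)
        assert hit.identity == 1.0
        assert hit.score == sum(_B62_DIAG[c] for c in pep)

    def test_u_scored_as_cys(self):
        hit = local_align("U", "C")
        assert hit.score == 9          # BLOSUM62 C/C
        assert hit.aligned_query == "U" and hit.aligned_subject == "C"
        assert hit.identity == 1.0     # U == C by convention

    def test_empty_peptide_rejected(self):
        with pytest.raises(ValidationError):
            local_align("", "ACD")

    def test_scores_match_textbook_sw_oracle(self, rng):
        for _ in range(50):
            q = "".join(rng.choice(list(AA), size=int(rng.integers(8, 25))))
            s = "".join(rng.choice(list(AA), size=int(rng.integers(8, 30))))
            assert local_align(q, s).score == pytest.approx(_sw_oracle(q, s))

    def test_uc_substitution_symmetry(self, rng):
        """Swapping U<->C anywhere leaves the alignment score unchanged."""
        for _ in range(20):
            q = "".join(rng.choice(list(AA + "U"), size=15))
            s = "".join(rng.choice(list(AA + "U"), size=20))
            base = local_align(q, s).score
            assert local_align(q.replace("U", "C"), s).score == base
            assert local_align(q, s.replace("U", "C")).score == base


class TestUCPairing:
    def test_self_with_cys_substitution(self):
        flank = "MKVLUDGERTAKWLSNPQAYI"
        db = [("h1", flank.replace("U", "C"), "Gpx")]
        ev = find_uc_pairing(flank, db)
        assert ev.positive and ev.n_cys_paired == 1

    def test_requires_exactly_one_u(self):
        with pytest.raises(ValidationError):
            find_uc_pairing("ACDEF", [])

    def test_empty_db(self):
        ev = find_uc_pairing("ACUEF", [])
        assert not ev.positive and ev.n_cys_paired == 0

    def test_planted_homolog_at_60_percent_detected(self, small_dataset):
        g = small_dataset.truth.genes[0]
        prot = g.protein
        upos = prot.index("U")
        flank = extract_sec_flank(prot, upos, 20)
        flank = "".join("C" if (c == "U" and i != min(20, upos)) else c
                        for i, c in enumerate(flank))
        db = [(i, s, f) for i, s, f in small_dataset.homolog_db
              if i.startswith(g.gene_id)]
        assert find_uc_pairing(flank, db).positive

    def test_null_rate_below_5_percent(self, rng):
        """Random-peptide databases must almost never pair."""
        hits = 0
        trials = 60
        for _ in range(trials):
            prot = "".join(rng.choice(list(AA), size=41))
            flank = prot[:20] + "U" + prot[21:]
            db = [(f"r{k}", "".join(rng.choice(list(AA), size=200)), None)
                  for k in range(3)]
            if find_uc_pairing(flank, db).positive:
                hits += 1
        assert hits / trials <= 0.05


class TestFamilies:
    def test_exact_member(self, small_dataset):
        db = small_dataset.homolog_db
        gpx = next(s for _i, s, f in db if f == "Gpx")
        assert assign_family(gpx, db) == "Gpx"

    def test_subfamily_collapse(self):
        assert collapse_family("DI1") == "DI"
        assert collapse_family("DI3") == "DI"
        assert collapse_family("Gpx4") == "Gpx"
        assert collapse_family("SelU3_b") == "SelU"
        assert collapse_family("Sel15") == "Sel15"   # not a subfamily label

    def test_random_peptide_is_novel(self, rng, small_dataset):
        pep = "".join(rng.choice(list(AA), size=120))
        assert assign_family(pep, small_dataset.homolog_db) == "novel"


class TestCalibration:
    def test_true_hits_clear_shuffled_threshold(self, rng, small_dataset):
        db = small_dataset.homolog_db[:6]
        thr = calibrate_score_threshold(db, rng, n_shuffles=15)
        assert thr > 0
        g = small_dataset.truth.genes[0]
        flank = extract_sec_flank(g.protein, g.protein.index("U"), 20)
        own = [(i, s, f) for i, s, f in small_dataset.homolog_db
               if i.startswith(g.gene_id)]
        best = max(local_align(flank.replace("U", "C"), s).score
                   for _i, s, _f in own)
        assert best > thr


class TestESTSupport:
    def _gene(self, rng):
        cds = "ATG" + "".join(rng.choice(list("ACGT"), size=300)) + "TAA"
        mrna = cds + "".join(rng.choice(list("ACGT"), size=400))
        return mrna

    def test_full_length_est_spans(self, rng):
        mrna = self._gene(rng)
        ev = est_support([150], mrna, [mrna])
        assert ev.n_spanning == 1

    def test_ests_ending_before_tga(self, rng):
        mrna = self._gene(rng)
        ests = [mrna[:120], mrna[:80]]
        assert est_support([150], mrna, ests).n_spanning == 0

    def test_reverse_complement_ests_count(self, rng):
        from selenoscan.genome_io import reverse_complement
        mrna = self._gene(rng)
        ev = est_support([150], mrna, [reverse_complement(mrna)])
        assert ev.n_spanning == 1

    def test_matches_coverage_oracle(self, rng):
        """Error-free ESTs with known placement vs anchor arithmetic."""
        mrna = self._gene(rng)
        sec = [150]
        params = EvidenceParams()
        ests, expect = [], 0
        for _ in range(40):
            t0 = int(rng.integers(0, len(mrna) - 160))
            ln = int(rng.integers(150, min(400, len(mrna) - t0)))
            ests.append(mrna[t0:t0 + ln])
            if t0 <= sec[0] - params.est_anchor and \
                    t0 + ln >= sec[0] + 3 + params.est_anchor:
                expect += 1
        got = est_support(sec, mrna, ests, params).n_spanning
        assert got == expect
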