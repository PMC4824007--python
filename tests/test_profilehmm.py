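import itertools
import math

import numpy as np
import pytest

from oracles import enum_forward_bits, enum_viterbi_bits, random_profile
from protevo.profilehmm import (EvalueCalibration, ProfileModel, ProfileError,
                                annotate_domains, blosum62_background,
                                build_profile, calibrate, evalue,
                                forward_score, forward_score_batch,
                                sample_null_sequences, scan_proteome,
                                sequence_probability, viterbi)
from protevo.seqio import AMINO_ACIDS, Alignment, Proteome, ProteinRecord


def no_indel_profile(emit: np.ndarray) -> ProfileModel:
    M = emit.shape[0]
    one = np.ones(max(M - 1, 0))
    zero = np.zeros(max(M - 1, 0))
    return ProfileModel(id="ni", match_emit=emit, t_mm=one, t_mi=zero,
                        t_md=zero, t_im=one, t_ii=zero, t_dm=one, t_dd=zero,
                        t_bm=1.0, t_bd=0.0, background=blosum62_background())


class TestBuildProfile:
    def make_aln(self, rows):
        return Alignment(rows=[(f"r{i}", s) for i, s in enumerate(rows)])

    def test_ungapped_alignment_all_match(self):
        p = build_profile(self.make_aln(["ACDEF", "ACDEF", "ACDEY", "ACDEW"]))
        assert p.M == 5

    def test_majority_gap_column_is_insert(self):
        # column 3 is gap in 3 of 4 rows (75% >= 50%): insert
        p = build_profile(self.make_aln(["AC-DF", "AC-DF", "AC-DF", "ACWDF"]))
        assert p.M == 4

    def test_exactly_half_gaps_is_insert(self):
        p = build_profile(self.make_aln(["A-C", "AWC", "A-C", "AVC"]))
        assert p.M == 2

    def test_emission_pseudocounts(self):
        p = build_profile(self.make_aln(["A", "A", "A", "A"]))
        q_a = blosum62_background()[AMINO_ACIDS.index("A")]
        expected = (4 + q_a) / 5.0
        assert p.match_emit[0][AMINO_ACIDS.index("A")] == pytest.approx(expected)
        assert p.match_emit[0].argmax() == AMINO_ACIDS.index("A")

    def test_zero_match_columns_errors(self):
        with pytest.raises(ProfileError):
            build_profile(self.make_aln(["A---", "---C", "--G-", "-T--"]))

    def test_profile_text_round_trip(self):
        p = build_profile(self.make_aln(["ACDEF", "AC-EF", "ACDEF", "ACDEY"]))
        q = ProfileModel.from_text(p.to_text())
        np.testing.assert_allclose(q.match_emit, p.match_emit, atol=1e-9)
        np.testing.assert_allclose(q.t_mm, p.t_mm, atol=1e-9)
        assert q.M == p.M


class TestScoringOracle:
    """Forward and Viterbi must equal exhaustive path enumeration."""

    @pytest.mark.parametrize("mode", ["local", "glocal"])
    def test_small_instances(self, mode, rng):
        for _ in range(60):
            M = int(rng.integers(1, 4))
            p = random_profile(rng, M)
            L = int(rng.integers(1, 5))
            s = "".join(AMINO_ACIDS[k] for k in rng.integers(0, 20, L))
            f, fo = forward_score(p, s, mode), enum_forward_bits(p, s, mode)
            v, vo = viterbi(p, s, mode).bits, enum_viterbi_bits(p, s, mode)
            assert f == fo or math.isclose(f, fo, rel_tol=1e-9, abs_tol=1e-9)
            assert v == vo or math.isclose(v, vo, rel_tol=1e-9, abs_tol=1e-9)

    def test_forward_at_least_viterbi(self, rng):
        for _ in range(25):
            p = random_profile(rng, int(rng.integers(2, 8)))
            s = "".join(AMINO_ACIDS[k] for k in rng.integers(0, 20, 12))
            assert forward_score(p, s) >= viterbi(p, s).bits - 1e-9

    def test_background_profile_glocal_zero_bits(self):
        emit = np.tile(blosum62_background(), (4, 1))
        p = no_indel_profile(emit)
        s = "".join(AMINO_ACIDS[k] for k in np.random.default_rng(0).integers(0, 20, 4))
        assert forward_score(p, s, mode="glocal") == pytest.approx(0.0, abs=1e-9)

    def test_x_emits_background(self, rng):
        # X contributes zero log-odds at every match position
        emit = rng.dirichlet(np.full(20, 0.5), size=4)
        p = no_indel_profile(emit)
        assert forward_score(p, "XXXX", mode="glocal") == \
            pytest.approx(0.0, abs=1e-9)


class TestViterbiPath:
    def test_consensus_gives_all_match_path(self, rng):
        emit = np.full((5, 20), 0.01 / 19)
        cons = [3, 7, 11, 2, 19]
        for j, k in enumerate(cons):
            emit[j] = 0.01 / 19
            emit[j, k] = 0.99
        emit /= emit.sum(axis=1, keepdims=True)
        p = no_indel_profile(emit)
        s = "".join(AMINO_ACIDS[k] for k in cons)
        vr = viterbi(p, s)
        assert [st for st, _, _ in vr.path] == ["M"] * 5
        assert (vr.env_start, vr.env_end) == (1, 5)

    def test_envelope_ordering(self, rng):
        for _ in range(20):
            p = random_profile(rng, int(rng.integers(2, 6)))
            s = "".join(AMINO_ACIDS[k] for k in rng.integers(0, 20, 10))
            vr = viterbi(p, s)
            assert 1 <= vr.env_start <= vr.env_end <= len(s)


class TestNormalization:
    def test_no_indel_length3_profile_sums_to_one(self, rng):
        emit = rng.dirichlet(np.full(20, 0.7), size=3)
        p = no_indel_profile(emit)
        total = sum(sequence_probability(p, "".join(s))
                    for s in itertools.product(AMINO_ACIDS, repeat=3))
        assert total == pytest.approx(1.0, abs=1e-9)


class TestCalibration:
    def _profile(self, rng):
        root = "".join(AMINO_ACIDS[k]
                       for k in rng.choice(20, 40, p=blosum62_background()))
        rows = []
        for r in range(4):
            s = list(root)
            for i in range(len(s)):
                if rng.random() < 0.15:
                    s[i] = AMINO_ACIDS[rng.integers(0, 20)]
            rows.append((f"r{r}", "".join(s)))
        return build_profile(Alignment(rows=rows))

    def test_determinism(self, rng):
        p = self._profile(rng)
        c1 = calibrate(p, 300, (80, 200), seed=5)
        c2 = calibrate(p, 300, (80, 200), seed=5)
        assert (c1.mu, c1.beta) == (c2.mu, c2.beta)

    def test_pvalue_monotone_in_score(self, rng):
        p = self._profile(rng)
        cal = calibrate(p, 300, (80, 200), seed=5)
        scores = np.linspace(-5, 40, 30)
        pv = np.asarray(cal.pvalue(scores))
        assert (np.diff(pv) <= 0).all()       # non-increasing everywhere
        interior = (pv > 1e-12) & (pv < 1 - 1e-12)
        assert (np.diff(pv[interior]) < 0).all()

    def test_evalue_linearity_and_limits(self, rng):
        cal = EvalueCalibration(mu=3.0, beta=1.2, n_null=100, seed=0)
        assert evalue(5.0, cal, 200) == pytest.approx(2 * evalue(5.0, cal, 100))
        assert evalue(-50.0, cal, 50) == pytest.approx(50.0)
        assert evalue(10.0, cal, 50) < evalue(5.0, cal, 50)

    def test_n_null_minimum(self, rng):
        p = self._profile(rng)
        with pytest.raises(ProfileError):
            calibrate(p, 50, (80, 200), seed=5)

    def test_held_out_tail_at_five_percent(self, rng):
        """Empirical P(p <= 0.05) on fresh nulls within 3x binomial SE."""
        p = self._profile(rng)
        cal = calibrate(p, 4000, (100, 300), seed=11)
        held = sample_null_sequences(np.random.default_rng(99), 4000,
                                     (100, 300), p.background)
        pv = np.asarray(cal.pvalue(forward_score_batch(p, held)))
        frac = float(np.mean(pv <= 0.05))
        se = math.sqrt(0.05 * 0.95 / 4000)
        assert abs(frac - 0.05) <= 3 * se


class TestScanAndDomains:
    def _setup(self, rng):
        cons = "".join(AMINO_ACIDS[k]
                       for k in rng.choice(20, 35, p=blosum62_background()))
        rows = []
        for r in range(4):
            s = list(cons)
            for i in range(len(s)):
                if rng.random() < 0.1:
                    s[i] = AMINO_ACIDS[rng.integers(0, 20)]
            rows.append((f"r{r}", "".join(s)))
        p = build_profile(Alignment(rows=rows, id="fam"))
        cal = calibrate(p, 400, (100, 200), seed=3)
        return p, cal

    def test_planted_consensus_is_top_hit(self, rng):
        p, cal = self._setup(rng)
        bg = blosum62_background()
        records = []
        for i in range(100):
            L = int(rng.integers(100, 200))
            records.append(ProteinRecord(
                id=f"bg{i:03d}", organism="o",
                sequence="".join(AMINO_ACIDS[k] for k in rng.choice(20, L, p=bg))))
        planted = ("".join(AMINO_ACIDS[k] for k in rng.choice(20, 40, p=bg))
                   + p.consensus
                   + "".join(AMINO_ACIDS[k] for k in rng.choice(20, 40, p=bg)))
        records.append(ProteinRecord(id="planted", organism="o", sequence=planted))
        prot = Proteome(organism="o", records=records)
        hits = scan_proteome(p, prot, cal, threshold=0.01)
        assert hits and hits[0].sequence_id == "planted"
        assert 41 - 3 <= hits[0].env_start <= 41 + 3

    def test_high_evalue_hit_excluded(self, rng):
        p, cal = self._setup(rng)
        # score whose e-value is ~0.5 in a 1-sequence database
        from scipy import stats
        s_mid = float(stats.gumbel_r.ppf(0.5, loc=cal.mu, scale=cal.beta))
        assert evalue(s_mid, cal, db_size=1) > 0.01

    def test_empty_proteome_gives_empty_list(self, rng):
        p, cal = self._setup(rng)
        assert scan_proteome(p, Proteome(organism="o", records=[]), cal) == []

    def test_annotate_planted_domains_in_order(self, rng):
        bg = blosum62_background()

        def mkdomain(name, length):
            cons = rng.choice(20, length, p=bg)
            rows = []
            for r in range(4):
                s = cons.copy()
                mask = rng.random(length) < 0.1
                s[mask] = rng.integers(0, 20, mask.sum())
                rows.append((f"{name}{r}", "".join(AMINO_ACIDS[k] for k in s)))
            return build_profile(Alignment(rows=rows, id=name)), \
                "".join(AMINO_ACIDS[k] for k in cons)

        pa, cons_a = mkdomain("A", 50)
        pb, cons_b = mkdomain("B", 60)
        cals = {"A": calibrate(pa, 400, (100, 250), seed=1),
                "B": calibrate(pb, 400, (100, 250), seed=2)}
        filler = lambda n: "".join(AMINO_ACIDS[k] for k in rng.choice(20, n, p=bg))
        seq = filler(9) + cons_a + filler(20) + cons_b + filler(15)
        arch = annotate_domains(seq, [pa, pb], cals, threshold=0.01)
        assert arch.domain_ids == ["A", "B"]
        assert arch.hits[0].start < arch.hits[1].start

    def test_no_hits_empty_architecture(self, rng):
        pa, cal = self._setup(rng)
        bg_seq = "".join(AMINO_ACIDS[k]
                         for k in rng.choice(20, 150, p=blosum62_background()))
        arch = annotate_domains(bg_seq, [pa], {"fam": cal}, threshold=1e-6)
        assert len(arch) == 0

    def test_overlapping_hits_keep_better_evalue(self, rng):
        """Nested domain models of the same region: the full-length model
        scores far better, so greedy overlap resolution keeps only it."""
        bg = blosum62_background()
        cons = rng.choice(20, 55, p=bg)

        def model_from(codes, name):
            rows = []
            for r in range(4):
                s = codes.copy()
                mask = rng.random(len(s)) < 0.05
                s[mask] = rng.integers(0, 20, mask.sum())
                rows.append((f"{name}{r}", "".join(AMINO_ACIDS[k] for k in s)))
            return build_profile(Alignment(rows=rows, id=name))

        long = model_from(cons, "LONG")
        short = model_from(cons[15:35], "SHORT")
        cals = {"LONG": calibrate(long, 400, (100, 250), seed=1),
                "SHORT": calibrate(short, 400, (100, 250), seed=2)}
        filler = "".join(AMINO_ACIDS[k] for k in rng.choice(20, 30, p=bg))
        seq = filler + "".join(AMINO_ACIDS[k] for k in cons) + filler
        arch = annotate_domains(seq, [long, short], cals, threshold=0.05)
        assert arch.domain_ids == ["LONG"]
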