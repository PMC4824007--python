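import numpy as np
import pytest

from oracles import enum_motif_positions
from protevo.motifscan import (BUILTIN_PATTERNS, MotifPattern, TailRegion,
                               extract_tail, motif_occurrence, scan_motif)
from protevo.profilehmm import DomainArchitecture, DomainHit
from protevo.seqio import AMINO_ACIDS


def arch(*spans):
    return DomainArchitecture(hits=[
        DomainHit(f"D{i}", s, e, 1e-6) for i, (s, e) in enumerate(spans)])


class TestBuiltinPatterns:
    def test_registry(self):
        assert BUILTIN_PATTERNS["AP2"].pattern == r"DP[WF]|F.D.F|WV.F|F.F.[FL]"
        assert BUILTIN_PATTERNS["clathrin"].pattern == \
            r"L[FILMV].[FILMV][DE]|L[FILMV].[DE][FILMV]"
        assert BUILTIN_PATTERNS["EH"].pattern == "NPF"
        assert all(p.region_policy == "C_tail"
                   for p in BUILTIN_PATTERNS.values())


class TestExtractTail:
    SEQ = "M" * 80

    def test_c_tail_after_last_domain(self):
        region = extract_tail(self.SEQ, arch((10, 50)), "C_tail")
        assert (region.start, region.end) == (51, 80)
        assert len(region.sequence) == 30

    def test_n_tail_before_first_domain(self):
        region = extract_tail(self.SEQ, arch((10, 50)), "N_tail")
        assert (region.start, region.end) == (1, 9)

    def test_no_domains_whole_sequence(self):
        region = extract_tail(self.SEQ, arch(), "C_tail")
        assert (region.start, region.end) == (1, 80)

    def test_zero_length_tail(self):
        region = extract_tail(self.SEQ, arch((1, 80)), "C_tail")
        assert region.is_empty

    def test_tail_and_domains_partition(self):
        a = arch((10, 50))
        for policy in ("C_tail", "N_tail"):
            region = extract_tail(self.SEQ, a, policy)
            for h in a.hits:
                assert region.is_empty or region.end < h.start or region.start > h.end


class TestScanMotif:
    def test_ap2_example(self):
        count, positions = scan_motif("GSDPWKL", BUILTIN_PATTERNS["AP2"])
        assert (count, positions) == (1, [3])

    def test_clathrin_box_example(self):
        count, positions = scan_motif("LIDLE", BUILTIN_PATTERNS["clathrin"])
        assert (count, positions) == (1, [1])

    def test_empty_region(self):
        assert scan_motif("", BUILTIN_PATTERNS["EH"]) == (0, [])

    def test_overlapping_matches_all_counted(self):
        count, positions = scan_motif("NPFNPF", BUILTIN_PATTERNS["EH"])
        assert (count, positions) == (2, [1, 4])

    def test_position_matching_two_alternatives_counts_once(self):
        # "DPF" matches DP[WF]; craft a region where F.D.F also fires nearby
        count, positions = scan_motif("FADPF", BUILTIN_PATTERNS["AP2"])
        assert positions == sorted(set(positions))

    @pytest.mark.parametrize("name", sorted(BUILTIN_PATTERNS))
    def test_matches_per_position_oracle(self, name, rng):
        pat = BUILTIN_PATTERNS[name]
        for _ in range(300):
            L = int(rng.integers(0, 40))
            s = "".join(AMINO_ACIDS[k] for k in rng.integers(0, 20, L))
            count, positions = scan_motif(s, pat)
            assert positions == enum_motif_positions(s, pat.pattern)
            assert count == len(positions)


class TestMotifOccurrence:
    PAT = BUILTIN_PATTERNS["EH"]

    def test_three_of_four_organisms(self):
        counts = {"a": [1], "b": [2], "c": [4], "d": [0]}
        stats = motif_occurrence(counts, ["a", "b", "c", "d"], self.PAT)
        assert stats.occurrence == 0.75
        assert stats.median_count == 2
        assert stats.n_organisms == 4

    def test_no_possessors(self):
        stats = motif_occurrence({"a": [0], "b": []}, ["a", "b"], self.PAT)
        assert stats.occurrence == 0.0
        assert stats.median_count is None

    def test_any_paralog_counts(self):
        stats = motif_occurrence({"a": [0, 3]}, ["a"], self.PAT)
        assert stats.occurrence == 1.0
        assert stats.median_count == 3

    def test_denominator_restriction(self):
        counts = {"a": [1], "b": []}
        full = motif_occurrence(counts, ["a", "b"], self.PAT)
        restricted = motif_occurrence(counts, ["a", "b"], self.PAT,
                                      denominator="with_homolog")
        assert full.occurrence == 0.5
        assert restricted.occurrence == 1.0

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            motif_occurrence({}, [], self.PAT)

    def test_occurrence_bounds_and_median_floor(self, rng):
        for _ in range(50):
            orgs = [f"o{i}" for i in range(int(rng.integers(1, 6)))]
            counts = {o: list(rng.integers(0, 4, rng.integers(0, 3)))
                      for o in orgs}
            stats = motif_occurrence(counts, orgs, self.PAT)
            assert 0.0 <= stats.occurrence <= 1.0
            if stats.median_count is not None:
                assert stats.median_count >= 1


class TestApaSearch:
    def test_planted_consensus_passes_nulls_fail(self, rng):
        from protevo.motifscan import apa_search
        from protevo.profilehmm import (blosum62_background, build_profile,
                                        calibrate)
        from protevo.seqio import Alignment, ProteinRecord
        bg = blosum62_background()
        cons = rng.choice(20, 24, p=bg)
        rows = []
        for r in range(3):
            s = cons.copy()
            mask = rng.random(24) < 0.08
            s[mask] = rng.integers(0, 20, mask.sum())
            rows.append((f"apa{r}", "".join(AMINO_ACIDS[k] for k in s)))
        profile = build_profile(Alignment(rows=rows, id="APA"))
        cal = calibrate(profile, 1000, (150, 300), seed=4)
        mk = lambda i, seq: ProteinRecord(id=f"r{i}", organism="o", sequence=seq)
        pos = mk(0, "".join(AMINO_ACIDS[k] for k in rng.choice(20, 80, p=bg))
                 + "".join(AMINO_ACIDS[k] for k in cons)
                 + "".join(AMINO_ACIDS[k] for k in rng.choice(20, 80, p=bg)))
        nulls = [mk(i + 1, "".join(AMINO_ACIDS[k]
                                   for k in rng.choice(20, 200, p=bg)))
                 for i in range(60)]
        results = apa_search([pos] + nulls, profile, cal, threshold=0.01)
        assert results[0].passes
        assert results[0].neg_log10_evalue >= 2.0
        n_false = sum(r.passes for r in results[1:])
        assert n_false <= 3
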