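import math

import numpy as np
import pytest

from protevo.conserve_struct import (LOG2_20, ContactQuery, classify_contact,
                                     conservation_profile,
                                     map_reference_positions,
                                     min_heavy_atom_distance, residue_contacts)
from protevo.seqio import Alignment, Atom, Residue, StructureModel


def aln_of(columns):
    """Build an alignment whose i-th column is the i-th string."""
    n_rows = len(columns[0])
    rows = [(f"r{i}", "".join(col[i] for col in columns))
            for i in range(n_rows)]
    return Alignment(rows=rows)


class TestMapping:
    def test_ungapped_identity(self):
        aln = Alignment(rows=[("ref", "ACDE"), ("x", "ACDE")])
        assert map_reference_positions(aln, "ref", [1, 2, 3, 4]) == [1, 2, 3, 4]

    def test_gap_shifts_columns(self):
        aln = Alignment(rows=[("ref", "A-CD"), ("x", "AWCD")])
        assert map_reference_positions(aln, "ref", [2]) == [3]

    def test_position_zero_errors(self):
        aln = Alignment(rows=[("ref", "ACDE"), ("x", "ACDE")])
        with pytest.raises(ValueError):
            map_reference_positions(aln, "ref", [0])

    def test_mapped_column_is_never_gap(self):
        aln = Alignment(rows=[("ref", "A--CD-E"), ("x", "AWWCDWE")])
        ref_row = aln.row("ref")
        for p in range(1, 5):
            col = map_reference_positions(aln, "ref", [p])[0]
            assert ref_row[col - 1] != "-"


class TestConservation:
    def test_invariant_column_max_ic(self):
        aln = aln_of(["AAAA"])
        c = conservation_profile(aln, [1], small_sample_correction=False)[0]
        assert c.information_content == pytest.approx(LOG2_20, abs=1e-9)
        assert c.entropy == pytest.approx(0.0, abs=1e-9)

    def test_uniform_column_zero_ic(self):
        aln = aln_of(["ACDEFGHIKLMNPQRSTVWY"])
        c = conservation_profile(aln, [1], small_sample_correction=False)[0]
        assert c.information_content == pytest.approx(0.0, abs=1e-9)

    def test_fifty_fifty_one_bit_below_max(self):
        aln = aln_of(["AACC"])
        c = conservation_profile(aln, [1], small_sample_correction=False)[0]
        assert c.entropy == pytest.approx(1.0, abs=1e-9)
        assert c.information_content == pytest.approx(LOG2_20 - 1.0, abs=1e-9)

    def test_small_sample_correction_value(self):
        aln = aln_of(["AAAA"])
        c = conservation_profile(aln, [1], small_sample_correction=True)[0]
        e_n = 19.0 / (2.0 * math.log(2.0) * 4)
        assert c.information_content == pytest.approx(LOG2_20 - e_n, abs=1e-9)

    def test_gaps_excluded_from_denominator(self):
        aln = aln_of(["AA--", "CCCC"])
        c = conservation_profile(aln, [1], small_sample_correction=False)[0]
        assert c.n == 2
        assert c.frequencies == {"A": 1.0}

    def test_all_gap_column_errors(self):
        aln = Alignment(rows=[("a", "A-"), ("b", "C-")])
        with pytest.raises(ValueError):
            conservation_profile(aln, [2])

    def test_ic_weakly_decreases_as_column_flattens(self):
        """Nested distributions: moving mass toward uniform lowers IC."""
        letters = "ACDEFGHIKLMNPQRSTVWY"
        prev = math.inf
        for k in (1, 2, 4, 10, 20):
            col = "".join(letters[i % k] for i in range(20))
            c = conservation_profile(aln_of([col]), [1],
                                     small_sample_correction=False)[0]
            assert c.information_content <= prev + 1e-12
            prev = c.information_content


def residue(name, index, atoms):
    return Residue(index=index, name=name,
                   atoms=[Atom(n, *xyz) for n, xyz in atoms])


def model_of(*chain_residues):
    return StructureModel({"A": list(chain_residues[0]),
                           "B": list(chain_residues[1])})


class TestContacts:
    def test_single_atom_pair_contact(self):
        m = model_of([residue("GLY", 1, [("CA", (0, 0, 0))])],
                     [residue("GLY", 2, [("CA", (3.0, 0, 0))])])
        q = ContactQuery(pairs=((1, 2),), chain_a="A", chain_b="B", cutoff=4.5)
        r = residue_contacts(m, q)[0]
        assert r.contact and r.min_distance == pytest.approx(3.0)

    def test_beyond_cutoff_no_contact(self):
        m = model_of([residue("GLY", 1, [("CA", (0, 0, 0))])],
                     [residue("GLY", 2, [("CA", (5.0, 0, 0))])])
        q = ContactQuery(pairs=((1, 2),), chain_a="A", chain_b="B", cutoff=4.5)
        assert not residue_contacts(m, q)[0].contact

    def test_missing_residue_names_chain_and_position(self):
        m = model_of([residue("GLY", 1, [("CA", (0, 0, 0))])],
                     [residue("GLY", 2, [("CA", (1, 0, 0))])])
        q = ContactQuery(pairs=((1, 99),), chain_a="A", chain_b="B")
        with pytest.raises(KeyError, match="99"):
            residue_contacts(m, q)

    def test_min_distance_matches_exhaustive_oracle(self, rng):
        for _ in range(100):
            na, nb = rng.integers(1, 6), rng.integers(1, 6)
            xa = rng.uniform(-10, 10, (na, 3))
            xb = rng.uniform(-10, 10, (nb, 3))
            ra = residue("ALA", 1, [(f"C{i}", tuple(p)) for i, p in enumerate(xa)])
            rb = residue("ALA", 2, [(f"C{i}", tuple(p)) for i, p in enumerate(xb)])
            expected = min(math.dist(p, q) for p in xa for q in xb)
            assert min_heavy_atom_distance(ra, rb) == pytest.approx(expected)
            assert min_heavy_atom_distance(rb, ra) == pytest.approx(expected)

    def test_symmetry_under_pair_reversal(self):
        ra = residue("LYS", 1, [("NZ", (0, 0, 0)), ("CA", (1, 1, 1))])
        rb = residue("GLU", 2, [("OE1", (2, 0, 0)), ("CA", (3, 1, 1))])
        assert min_heavy_atom_distance(ra, rb) == \
            min_heavy_atom_distance(rb, ra)


class TestClassification:
    def test_salt_bridge_is_electrostatic(self):
        k = residue("LYS", 1, [("NZ", (0, 0, 0))])
        e = residue("GLU", 2, [("OE1", (3.2, 0, 0))])
        assert classify_contact(k, e) == "electrostatic"

    def test_apolar_pair_is_hydrophobic(self):
        v = residue("VAL", 1, [("CG1", (0, 0, 0)), ("CA", (1, 0, 0))])
        l = residue("LEU", 2, [("CD1", (4.0, 0, 0))])
        assert classify_contact(v, l) == "hydrophobic"

    def test_polar_apolar_pair_is_other(self):
        s = residue("SER", 1, [("OG", (0, 0, 0))])
        a = residue("ALA", 2, [("CB", (3.5, 0, 0))])
        assert classify_contact(s, a) == "other"

    def test_distant_charged_pair_is_not_electrostatic(self):
        k = residue("LYS", 1, [("NZ", (0, 0, 0))])
        e = residue("GLU", 2, [("OE1", (4.5, 0, 0))])
        assert classify_contact(k, e) != "electrostatic"
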