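import json
import math

import numpy as np
import pytest

from protevo.synthdata import (DomainGain, Duplication, FamilySpec, Loss,
                               MotifPlant, evolve_family, generate_interactions,
                               generate_survey_fixture, generate_taxonomy)


class TestTaxonomy:
    def test_leaf_counts(self):
        tax = generate_taxonomy(n_per_clade=2)
        # 6 nested + 2 outgroup clades, 2 organisms each
        assert len(tax.organisms) == 16

    def test_determinism(self):
        assert generate_taxonomy(seed=7).newick() == generate_taxonomy(seed=7).newick()

    def test_focal_path_length(self):
        tax = generate_taxonomy()
        assert len(tax.focal_path) == 6
        assert tax.focal_path[0] == tax.root_clade
        assert tax.focal_path[-1] == "Metazoa"


class TestEvolveFamily:
    def test_rate_zero_keeps_sequences_identical(self):
        tax = generate_taxonomy()
        spec = FamilySpec("F", [("DOM", 50)], rate=0.0)
        genes = evolve_family(spec, tax, seed=1)
        seqs = {g[0].sequence() for g in genes.values()}
        assert len(seqs) == 1
        assert len(genes) == len(tax.organisms)

    def test_pairwise_divergence_matches_closed_form(self):
        """Two leaves at total path distance T differ at a fraction
        (19/20)(1 - exp(-(20/19) T)) of sites (within 3 SE at L=1000)."""
        tax = generate_taxonomy()
        rate = 0.05
        spec = FamilySpec("F", [("DOM", 1000)], rate=rate,
                          domain_rate_multiplier=1.0,
                          n_tail_length=0, c_tail_length=0)
        diffs = []
        for seed in range(8):
            genes = evolve_family(spec, tax, seed=seed)
            a = genes["Metazoa_1"][0].sequence()
            b = genes["Discoba_1"][0].sequence()
            diffs.append(sum(x != y for x, y in zip(a, b)) / len(a))
        # Metazoa_1: 6 branches to root; Discoba_1: 2 branches
        T = 8 * rate
        expected = (19 / 20) * (1 - math.exp(-(20 / 19) * T))
        se = math.sqrt(expected * (1 - expected) / (1000 * len(diffs)))
        assert abs(np.mean(diffs) - expected) <= 3 * se

    def test_motif_plant_clade_semantics(self):
        tax = generate_taxonomy()
        spec = FamilySpec("F", [("DOM", 50)], rate=0.0,
                          events={"Holozoa": [MotifPlant("AP2", "DPW")]})
        genes = evolve_family(spec, tax, seed=1)
        holozoa = tax.leaves_under("Holozoa")
        for org, gs in genes.items():
            tail, _ = gs[0].tail("C_tail")
            assert ("DPW" in tail) == (org in holozoa)

    def test_origin_clade_restricts_presence(self):
        tax = generate_taxonomy()
        spec = FamilySpec("F", [("DOM", 50)], origin_clade="Holozoa")
        genes = evolve_family(spec, tax, seed=1)
        assert set(genes) == tax.leaves_under("Holozoa")

    def test_duplication_and_loss(self):
        tax = generate_taxonomy()
        spec = FamilySpec("F", [("DOM", 50)],
                          events={"Metazoa": [Duplication(2)],
                                  "Discoba": [Loss()]})
        genes = evolve_family(spec, tax, seed=1)
        assert len(genes["Metazoa_1"]) == 3
        assert len(genes["Holozoa_1"]) == 1
        assert "Discoba_1" not in genes

    def test_domain_gain_expands_architecture(self):
        tax = generate_taxonomy()
        spec = FamilySpec("F", [("A", 40), ("B", 40)],
                          events={"Holozoa": [DomainGain("B", 40, after="B",
                                                         copies=2)]})
        genes = evolve_family(spec, tax, seed=1)
        assert genes["Metazoa_1"][0].domain_ids() == ["A", "B", "B", "B"]
        assert genes["Obazoa_1"][0].domain_ids() == ["A", "B"]

    def test_unknown_clade_errors(self):
        tax = generate_taxonomy()
        spec = FamilySpec("F", [("DOM", 50)], events={"Atlantis": [Loss()]})
        with pytest.raises(ValueError, match="Atlantis"):
            evolve_family(spec, tax, seed=1)

    def test_recall_relevant_divergence_is_monotone(self):
        """Sequence identity to the root family decays with rate."""
        tax = generate_taxonomy()
        idents = []
        for rate in (0.0, 0.05, 0.15, 0.4):
            spec = FamilySpec("F", [("DOM", 400)], rate=rate,
                              domain_rate_multiplier=1.0)
            genes = evolve_family(spec, tax, seed=3)
            a = genes["Metazoa_1"][0].sequence()
            b = genes["Discoba_1"][0].sequence()
            idents.append(sum(x == y for x, y in zip(a, b)) / len(a))
        assert all(x >= y - 0.02 for x, y in zip(idents, idents[1:]))


class TestFixture:
    def test_determinism_byte_identical(self, tmp_path):
        fx1 = generate_survey_fixture(seed=9, n_decoys=5)
        fx2 = generate_survey_fixture(seed=9, n_decoys=5)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        fx1.write(d1)
        fx2.write(d2)
        for f1 in sorted(d1.rglob("*")):
            if f1.is_file():
                f2 = d2 / f1.relative_to(d1)
                assert f1.read_bytes() == f2.read_bytes(), f1.name

    def test_no_families_pure_decoys(self):
        fx = generate_survey_fixture(specs=[], seed=5, n_decoys=3)
        assert fx.families == {}
        for prot in fx.proteomes.values():
            assert len(prot) == 3
            assert all(r.id.startswith("dec_") for r in prot)

    def test_truth_consistency(self, survey_fixture):
        rows = survey_fixture.truth.rows
        assert ((rows["paralogs"] > 0) == (rows["status"] == "homolog")).all()
        for fam, epoch in survey_fixture.truth.epochs.items():
            present = set(rows[(rows["family"] == fam)
                               & (rows["status"] == "homolog")]["organism"])
            assert present, fam
            assert epoch in survey_fixture.taxonomy.focal_path

    def test_planted_duplication_counts(self, survey_fixture):
        truth = survey_fixture.truth
        assert truth.paralogs("STON", "Metazoa_1") == 3
        assert truth.paralogs("CLT", "Metazoa_1") == 1

    def test_planted_analog_rows(self, survey_fixture):
        rows = survey_fixture.truth.rows
        dnm = rows[rows["family"] == "DNM"]
        by_status = dnm.groupby("status").size().to_dict()
        assert by_status.get("homolog") == 4           # Holozoa subtree
        assert by_status.get("analog_ancestor", 0) > 0  # DRP carriers

    def test_interactions_mixed_noise(self, survey_fixture):
        methods = {r.method for r in survey_fixture.interactions}
        assert any("hybrid" in m or "high" in m or "oloc" in m for m in methods)
        assert len(survey_fixture.interaction_truth) == 10
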