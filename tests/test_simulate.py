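"""Synthetic study generators: KPD families, marker panels, cohorts."""

import dataclasses

import numpy as np
import pytest

from cladelink.io import CladelinkError, mendelian_errors
from cladelink.parsimony import parsimony_score, ratchet_search, spr_refine
from cladelink.reference import exhaustive_parsimony
from cladelink.simulate import (KPDConfig, TRAIT_MAP, TRAITS,
                                make_toy_fixture, simulate_kpd_study,
                                simulate_marker_panel, simulate_symptom_cohort)


@pytest.fixture(scope="module")
def small_study():
    cfg = KPDConfig.scaled(12, seed=77)
    return cfg, simulate_kpd_study(cfg)


class TestMarkerPanel:
    def test_positions_arithmetic_and_counted(self):
        gmap = simulate_marker_panel(n_chrom=3, spacing_cm=7.5, n_markers=12,
                                     n_alleles=4, seed=0)
        assert len(gmap) == 12
        for chrom, markers in gmap.by_chrom.items():
            pos = [m.pos_cm for m in markers]
            assert np.allclose(np.diff(pos), 7.5)

    def test_same_seed_identical(self):
        a = simulate_marker_panel(2, 10.0, 6, 4, seed=3)
        b = simulate_marker_panel(2, 10.0, 6, 4, seed=3)
        assert [m.freqs for m in a] == [m.freqs for m in b]

    def test_monomorphic_panel_accepted(self):
        gmap = simulate_marker_panel(1, 5.0, 4, n_alleles=1, seed=0)
        assert all(m.freqs == (1.0,) for m in gmap)

    def test_frequencies_valid(self):
        gmap = simulate_marker_panel(2, 7.5, 10, 6, seed=1)
        for m in gmap:
            assert abs(sum(m.freqs) - 1) < 1e-9
            assert all(f >= 0 for f in m.freqs)


class TestKPDStudy:
    def test_family_count_matches_populations(self, small_study):
        cfg, (ped, gt, traits, truth) = small_study
        assert len(ped.families) == sum(p.n_families for p in cfg.populations)

    def test_ascertainment_rules_hold_by_recount(self, small_study):
        cfg, (ped, gt, traits, truth) = small_study
        by_pop = {p.name[:3].upper(): p for p in cfg.populations}
        for fam, members in ped.families.items():
            pop = by_pop[fam[:3]]
            hits = sum(1 for i in members
                       if truth.latent[i.uid] in pop.phenotypes)
            assert hits >= pop.min_count, fam

    def test_genotypes_mendelian_consistent(self, small_study):
        _, (ped, gt, traits, truth) = small_study
        assert mendelian_errors(ped, gt) == []

    def test_trait_expression_follows_latent_map(self, small_study):
        cfg, (ped, gt, traits, truth) = small_study
        for u, ph in truth.latent.items():
            if ph is None:
                continue
            row = traits.frame.loc[u]
            for t in TRAIT_MAP[ph]:
                assert row[t] == 1.0, (u, ph, t)

    def test_affection_column_tracks_latent_truth(self, small_study):
        _, (ped, gt, traits, truth) = small_study
        for ind in ped.individuals:
            assert (ind.affection == 2) == (truth.latent[ind.uid] is not None)

    def test_deterministic_under_seed(self):
        cfg = KPDConfig.scaled(3, seed=5)
        a = simulate_kpd_study(cfg)
        b = simulate_kpd_study(cfg)
        assert (a[1].data == b[1].data).all()
        assert a[3].latent == b[3].latent

    def test_zero_penetrance_fails_ascertainment(self):
        cfg = dataclasses.replace(KPDConfig.scaled(2, seed=0),
                                  base_penetrance=0.0, max_redraws=50)
        with pytest.raises(CladelinkError, match="ascertainment"):
            simulate_kpd_study(cfg)

    def test_affected_sibs_share_excess_ibd_at_causal_locus(self, small_study):
        # P1 requires a D1 allele: affected sib pairs share the nearby
        # chromosome-1 haplotype more often than an unlinked chromosome-4 one
        _, (ped, gt, traits, truth) = small_study
        d1_chrom, d1_pos = truth.loci["D1"]
        near = min(range(len(gt.gmap)),
                   key=lambda j: (gt.gmap.markers[j].chrom != d1_chrom,
                                  abs(gt.gmap.markers[j].pos_cm - d1_pos)))
        far = next(j for j, m in enumerate(gt.gmap) if m.chrom == "4")
        share_near = share_far = pairs = 0
        for fam, members in ped.families.items():
            sibs = [i.uid for i in members if not i.is_founder
                    and truth.latent[i.uid] == "P1"]
            for a in range(len(sibs)):
                for b in range(a + 1, len(sibs)):
                    oa, ob = truth.origins[sibs[a]], truth.origins[sibs[b]]
                    pairs += 1
                    share_near += (oa[near] == ob[near]).sum() / 2
                    share_far += (oa[far] == ob[far]).sum() / 2
        assert pairs >= 10
        assert share_near / pairs > share_far / pairs
        assert share_near / pairs > 0.55  # elevated above the null 0.5


class TestToyFixture:
    def test_optimal_tree_separates_blocks(self, toy):
        matrix, expected = toy
        ts = spr_refine(ratchet_search(matrix, n_iterations=20, seed=0),
                        matrix, seed=0)
        assert ts.score == exhaustive_parsimony(matrix) == expected["score"]
        split = expected["split"]
        complement = matrix_labels(matrix) - split
        found = any(split in t.bipartitions() or complement in t.bipartitions()
                    for t in ts.trees)
        assert found

    def test_robust_to_dropping_one_symptom(self, toy):
        matrix, expected = toy
        reduced = matrix.frame.drop(columns=["s1"])
        from cladelink.io import TraitMatrix

        m2 = TraitMatrix(reduced, {k: v for k, v in matrix.trait_kinds.items()
                                   if k != "s1"})
        ts = spr_refine(ratchet_search(m2, n_iterations=20, seed=0), m2, seed=0)
        split = expected["split"]
        complement = frozenset(m2.individual_ids) - split
        assert any(split in t.bipartitions() or complement in t.bipartitions()
                   for t in ts.trees)

    def test_score_equals_variable_character_count(self, toy):
        matrix, expected = toy
        variable = sum(1 for c in matrix.trait_names
                       if matrix.frame[c].nunique() > 1)
        assert expected["score"] == variable


def matrix_labels(matrix):
    return frozenset(matrix.individual_ids)


class TestSymptomCohort:
    def test_shapes_labels_and_determinism(self):
        probs = {"g1": {"a": 0.9, "b": 0.1}, "g2": {"a": 0.1, "b": 0.9}}
        m1, l1 = simulate_symptom_cohort({"g1": 20, "g2": 30}, probs, seed=3)
        m2, l2 = simulate_symptom_cohort({"g1": 20, "g2": 30}, probs, seed=3)
        assert len(m1) == 50 and set(l1.values()) == {"g1", "g2"}
        assert (m1.states() == m2.states()).all() and l1 == l2

    def test_group_rates_close_to_specified(self):
        probs = {"g1": {"a": 0.8}, "g2": {"a": 0.2}}
        m, labels = simulate_symptom_cohort({"g1": 300, "g2": 300}, probs,
                                            seed=1)
        g1 = [u for u, g in labels.items() if g == "g1"]
        assert m.frame.loc[g1, "a"].mean() == pytest.approx(0.8, abs=0.07)

    def test_zero_variance_traits_contribute_nothing(self):
        probs = {"g1": {"a": 1.0, "b": 0.0}, "g2": {"a": 1.0, "b": 0.0}}
        m, _ = simulate_symptom_cohort({"g1": 4, "g2": 4}, probs, seed=0)
        ts = ratchet_search(m, n_iterations=5, seed=0)
        assert ts.score == 0
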