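"""Pedigree likelihood, LOD curves, HLOD admixture, and run_linkage."""

import numpy as np
import pytest

from cladelink.io import (GeneticMap, GenotypeTable, Individual, Marker,
                          Pedigree, StructureError)
from cladelink.linkage import (DEFAULT_THETA_GRID, DOM1, REC1, STANDARD_MODELS,
                               GeneticModel, MendelianInconsistency,
                               _family_lods, clade_max_statistic,
                               family_lod_curve, hlod, run_linkage)
from cladelink.nesting import Clade
from cladelink.reference import brute_force_lod

FREQS2 = np.array([0.6, 0.4])

from helpers import random_small_pedigree as _random_small_pedigree


class TestFamilyLikelihood:
    def test_all_unknown_affection_curve_is_zero(self, nuclear_family):
        ped, gt, _ = nuclear_family(n_children=3, seed=2)
        statuses = {u: "unknown" for u in gt.uids}
        curve = family_lod_curve(ped, "F", statuses, gt, "M1", DOM1)
        assert np.allclose(curve, 0.0, atol=1e-12)

    def test_lod_at_half_exactly_zero(self, nuclear_family):
        ped, gt, _ = nuclear_family(n_children=4, seed=3)
        statuses = {u: ("affected" if u.endswith(("1", "3", "5"))
                        else "unaffected") for u in gt.uids}
        curve = family_lod_curve(ped, "F", statuses, gt, "M1", DOM1,
                                 theta_grid=DEFAULT_THETA_GRID)
        assert curve[-1] == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_peeling_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        ped, gt, members, statuses, observed = _random_small_pedigree(rng)
        for model in STANDARD_MODELS:
            for theta in (0.0, 0.15, 0.4):
                bf = brute_force_lod(members, statuses, observed, FREQS2,
                                     model.disease_allele_freq,
                                     model.penetrances, theta)
                try:
                    lod = _family_lods(ped, "F", statuses, gt, "M1", [model],
                                       (theta,), FREQS2)[0, 0]
                except MendelianInconsistency:
                    lod = None
                if lod is None or np.isnan(lod):
                    assert not np.isfinite(bf)
                else:
                    assert lod == pytest.approx(bf, abs=1e-10)

    def test_likelihood_conserved_over_observations(self):
        # summing P(observed marker data) over every fully-typed configuration
        # must give 1 for a fixed pedigree with unknown affection
        gmap = GeneticMap([Marker("M1", "1", 0.0, (1, 2), (0.7, 0.3))])
        inds = [Individual("F", "1", None, None, "male", 0),
                Individual("F", "2", None, None, "female", 0),
                Individual("F", "3", "1", "2", "male", 0)]
        ped = Pedigree(inds)
        statuses = {i.uid: "unknown" for i in inds}
        genos = [(1, 1), (1, 2), (2, 2)]
        total = 0.0
        from cladelink.linkage import (_FamilyEngine, _marker_obs, _Peeler,
                                       _transmission, _unaries)
        for ga in genos:
            for gb in genos:
                for gc in genos:
                    gt = GenotypeTable([i.uid for i in inds], gmap)
                    gt.set("F:1", "M1", ga)
                    gt.set("F:2", "M1", gb)
                    gt.set("F:3", "M1", gc)
                    eng = _FamilyEngine(ped, "F")
                    obs = _marker_obs(eng, gt, "M1", (1, 2))
                    un = _unaries(eng, statuses, obs, [DOM1],
                                  np.array([0.7, 0.3]))
                    T = _transmission(2, (0.1,))
                    ll = _Peeler(eng, un, T).loglik()[0, 0]
                    if np.isfinite(ll):
                        total += 10 ** ll
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_phase_known_nonrecombinants_closed_form(self, phase_known_family):
        for n in (1, 4, 7):
            ped, gt, statuses = phase_known_family(n)
            curve = family_lod_curve(ped, "F", statuses, gt, "M1", DOM1,
                                     theta_grid=(0.0, 0.5))
            assert curve[0] == pytest.approx(n * np.log10(2), abs=1e-12)

    def test_loops_rejected(self):
        # first cousins mating: creates a loop in the family graph
        inds = [Individual("F", "1", None, None, "male", 0),
                Individual("F", "2", None, None, "female", 0),
                Individual("F", "3", "1", "2", "male", 0),
                Individual("F", "4", "1", "2", "female", 0),
                Individual("F", "5", "3", "4", "male", 0)]
        ped = Pedigree(inds)
        gmap = GeneticMap([Marker("M1", "1", 0.0, (1, 2), (0.5, 0.5))])
        gt = GenotypeTable([i.uid for i in inds], gmap)
        statuses = {i.uid: "unknown" for i in inds}
        with pytest.raises(StructureError, match="loop"):
            family_lod_curve(ped, "F", statuses, gt, "M1", DOM1)


class TestHlod:
    def test_single_family_maximizes_at_alpha_one(self, phase_known_family):
        ped, gt, statuses = phase_known_family(5)
        curve = family_lod_curve(ped, "F", statuses, gt, "M1", DOM1)
        h, alpha, theta = hlod(curve[None, :], DEFAULT_THETA_GRID)
        assert alpha == pytest.approx(1.0, abs=1e-6)
        assert h == pytest.approx(curve.max(), abs=1e-9)

    def test_alpha_zero_gives_zero(self):
        curves = np.array([[1.0, 0.5, 0.0], [-2.0, -1.0, 0.0]])
        R = 10.0 ** curves
        val = np.log10(0.0 * R + 1.0).sum(axis=0)
        assert np.allclose(val, 0.0)

    def test_hlod_at_alpha_one_is_lod_sum(self, phase_known_family):
        ped, gt, st = phase_known_family(4)
        c1 = family_lod_curve(ped, "F", st, gt, "M1", DOM1)
        curves = np.stack([c1, c1, c1])
        R = 10.0 ** curves
        manual = np.log10(1.0 * R + 0.0).sum(axis=0)
        assert np.allclose(manual, curves.sum(axis=0))
        h, alpha, theta = hlod(curves, DEFAULT_THETA_GRID)
        assert h >= max(0.0, curves.sum(axis=0).max()) - 1e-9

    def test_hlod_maximum_nonnegative_even_for_negative_lods(self):
        curves = -np.abs(np.random.default_rng(0).normal(size=(5, 12)))
        curves[:, -1] = 0.0
        h, alpha, theta = hlod(curves, DEFAULT_THETA_GRID)
        assert h >= 0.0

    def test_mixture_recovers_intermediate_alpha(self, phase_known_family):
        # half the families linked (nonrecombinant), half carrying
        # recombinant-heavy data: admixture alpha lands in the interior
        ped_l, gt_l, st_l = phase_known_family(6, recombinants=0)
        ped_u, gt_u, st_u = phase_known_family(6, recombinants=3)
        linked = family_lod_curve(ped_l, "F", st_l, gt_l, "M1", DOM1)
        unlinked = family_lod_curve(ped_u, "F", st_u, gt_u, "M1", DOM1)
        curves = np.stack([linked] * 10 + [unlinked] * 10)
        h, alpha, theta = hlod(curves, DEFAULT_THETA_GRID)
        assert 0.2 < alpha < 0.8
        assert h >= max(0.0, curves.sum(axis=0).max()) - 1e-9


class TestRunLinkage:
    def test_all_missing_marker_gives_zero_lod(self, nuclear_family):
        ped, gt, gmap = nuclear_family(n_children=3, typed=False)
        clade = Clade("1_0", 1, 0, frozenset({"F:1", "F:3"}))
        res = run_linkage([clade], ped, gt, gmap, models=[DOM1],
                          markers=["M1"])
        assert len(res) == 1
        assert np.allclose(res[0].lods, 0.0, atol=1e-12)
        assert res[0].hlod == pytest.approx(0.0, abs=1e-9)

    def test_one_result_row_per_clade_marker_model(self, nuclear_family):
        ped, gt, gmap = nuclear_family(n_children=3, seed=5)
        clade = Clade("1_0", 1, 0, frozenset({"F:1", "F:3"}))
        res = run_linkage([clade], ped, gt, gmap)
        assert {(r.clade, r.marker, r.model) for r in res} == \
            {("1_0", "M1", m.name) for m in STANDARD_MODELS}

    def test_impossible_model_excluded_with_warning(self):
        # unaffected child of two affected parents: impossible under Rec-1
        gmap = GeneticMap([Marker("M1", "1", 0.0, (1, 2), (0.5, 0.5))])
        inds = [Individual("F", "1", None, None, "male", 2),
                Individual("F", "2", None, None, "female", 2),
                Individual("F", "3", "1", "2", "male", 1)]
        ped = Pedigree(inds)
        gt = GenotypeTable([i.uid for i in inds], gmap)
        clade = Clade("1_0", 1, 0, frozenset({"F:1", "F:2"}))
        with pytest.warns(UserWarning, match="Rec-1"):
            res = run_linkage([clade], ped, gt, gmap,
                              models=[DOM1, REC1], markers=["M1"])
        assert {r.model for r in res} == {"Dom-1"}

    def test_clade_max_statistic_is_max_of_lod_and_hlod(self, nuclear_family):
        ped, gt, gmap = nuclear_family(n_children=4, seed=6)
        clade = Clade("1_0", 1, 0, frozenset({"F:1", "F:3", "F:5"}))
        res = run_linkage([clade], ped, gt, gmap)
        z, best = clade_max_statistic(res)
        assert z == max(max(r.max_lod, r.hlod) for r in res)
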