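import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from guidespec import (CfdWeightTable, GenomicInterval, MismatchDescriptor,
                       OffTargetSite, PlantSpec, aggregate_specificity,
                       cfd_site_score, default_weight_table, implant_sites,
                       random_genome, read_scores_tsv, score_guide,
                       tally_offtargets, write_scores_tsv)
from guidespec.genome import Genome

from .conftest import random_spacer


def make_site(mismatches, pam="TGG", n=None, start=100):
    descs = tuple(MismatchDescriptor(p, g, t) for p, g, t in mismatches)
    seq = list("A" * 20)
    for d in descs:
        seq[d.position - 1] = d.target_base
    return OffTargetSite(GenomicInterval("chr1", start, start + 20), "+",
                         "".join(seq), pam, descs, len(descs))


class TestCfdSiteScore:
    def test_perfect_match_ngg_is_one(self, weights):
        assert cfd_site_score(make_site([], pam="AGG"), weights) == 1.0

    def test_single_mismatch_is_table_weight(self, weights):
        site = make_site([(5, "A", "G")])
        assert cfd_site_score(site, weights) == weights.mismatch_weight(5, "A", "G")

    def test_product_with_nag_pam(self, weights):
        site = make_site([(3, "A", "C"), (18, "A", "T")], pam="TAG")
        expected = (weights.mismatch_weight(3, "A", "C")
                    * weights.mismatch_weight(18, "A", "T")
                    * weights.pam_weight("TAG"))
        assert cfd_site_score(site, weights) == pytest.approx(expected)

    def test_missing_entry_error_names_the_key(self, weights):
        broken = CfdWeightTable(
            {k: v for k, v in weights.mismatch_weights.items() if k != (7, "A", "G")},
            weights.pam_weights)
        with pytest.raises(KeyError, match="pos=7, guide=A, target=G"):
            cfd_site_score(make_site([(7, "A", "G")]), broken)

    def test_missing_pam_error(self, weights):
        table = CfdWeightTable(weights.mismatch_weights, {"GG": 1.0})
        with pytest.raises(KeyError, match="PAM"):
            cfd_site_score(make_site([], pam="TAG"), table)


class TestAggregateSpecificity:
    def test_no_qualifying_sites_scores_one(self, weights):
        res = aggregate_specificity([], weights, guide_id="g")
        assert res.score == 1.0 and res.cfd_sum == 0.0

    def test_one_full_cfd_site_scores_half(self, all_one_weights):
        res = aggregate_specificity([make_site([(1, "A", "C"), (2, "A", "C")])],
                                    all_one_weights)
        assert res.score == pytest.approx(0.5)

    def test_sum_to_one_gives_half(self, weights):
        # craft three 2-mm sites whose CFDs sum to 1.0 via a custom table
        table = CfdWeightTable(
            {**{k: 0.0 for k in weights.mismatch_weights},
             (1, "A", "C"): 1.0, (2, "A", "G"): 0.5, (3, "A", "T"): 0.25},
            {"GG": 1.0})
        sites = [make_site([(1, "A", "C"), (2, "A", "G")]),   # 0.5
                 make_site([(1, "A", "C"), (3, "A", "T")]),   # 0.25
                 make_site([(1, "A", "C"), (3, "A", "T")])]   # 0.25
        res = aggregate_specificity(sites, table)
        assert res.cfd_sum == pytest.approx(1.0)
        assert res.score == pytest.approx(0.5)

    def test_hand_computed_sums_randomized(self, weights, rng):
        # independent recomputation: explicit product loop per site
        for _ in range(100):
            n_sites = int(rng.integers(0, 8))
            sites = []
            for _ in range(n_sites):
                n_mm = int(rng.integers(2, 4))
                positions = sorted(rng.choice(np.arange(1, 21), n_mm, replace=False))
                mms = []
                for p in positions:
                    g, t = rng.choice(list("ACGT"), 2, replace=False)
                    mms.append((int(p), g, t))
                pam = "T" + "".join(rng.choice(list("ACGT"), 2))
                try:
                    weights.pam_weight(pam)
                except KeyError:
                    pam = "TGG"
                sites.append(make_site(mms, pam=pam))
            expected = 0.0
            for s in sites:
                if s.n_mismatch in {2, 3}:
                    prod = weights.pam_weights[s.pam[-2:]]
                    for d in s.mismatches:
                        prod *= weights.mismatch_weights[(d.position, d.guide_base,
                                                          d.target_base)]
                    expected += prod
            res = aggregate_specificity(sites, weights)
            assert res.cfd_sum == pytest.approx(expected, rel=1e-12)
            assert res.score == pytest.approx(1.0 / (1.0 + expected), rel=1e-12)

    def test_strict_monotonicity_under_site_addition(self, weights):
        sites = []
        score = 1.0
        for start in range(0, 200, 25):
            sites.append(make_site([(2, "A", "C"), (10, "A", "G")], start=start))
            new = aggregate_specificity(sites, weights).score
            assert new < score
            score = new

    @settings(deadline=None, max_examples=25)
    @given(perm=st.permutations(list(range(6))))
    def test_permutation_invariance(self, weights, perm):
        sites = [make_site([(i + 1, "A", "C"), (i + 2, "A", "G")], start=i * 30)
                 for i in range(6)]
        base = aggregate_specificity(sites, weights).score
        assert aggregate_specificity([sites[i] for i in perm], weights).score \
            == pytest.approx(base, rel=1e-15)

    def test_degenerate_all_one_table_closed_form(self, all_one_weights, rng):
        sites = [make_site([(1, "A", "C"), (5, "A", "G")], start=i * 30)
                 for i in range(7)]
        res = aggregate_specificity(sites, all_one_weights)
        assert res.score == pytest.approx(1.0 / (1.0 + 7))

    def test_include_classes_configurable(self, all_one_weights):
        sites = [make_site([(1, "A", "C")]),                      # 1 mm
                 make_site([(1, "A", "C"), (2, "A", "C")])]       # 2 mm
        assert aggregate_specificity(sites, all_one_weights).cfd_sum == 1.0
        assert aggregate_specificity(sites, all_one_weights,
                                     include_classes={1, 2, 3}).cfd_sum == 2.0

    def test_unsearchable_guide_is_an_error(self, weights):
        with pytest.raises(ValueError, match="unsearchable"):
            aggregate_specificity([], weights, guide_id="g", searchable=False)


class TestScoreGuide:
    def test_multi_perfect_match_guide_unscored(self, rng):
        spacer = random_spacer(rng)
        genome, _ = implant_sites(random_genome(4000, seed=31),
                                  PlantSpec(spacer, [(0, (), "TGG", 2)]), seed=32)
        res = score_guide("g", spacer, genome)
        assert not res.searchable and res.score is None and res.cfd_sum is None
        assert res.tally[0] == 2

    def test_one_mismatch_site_makes_unsearchable(self, rng):
        spacer = random_spacer(rng)
        genome, _ = implant_sites(
            random_genome(4000, seed=33),
            PlantSpec(spacer, [(0, (), "TGG", 1), (1, (), "AGG", 1)]), seed=34)
        assert not score_guide("g", spacer, genome).searchable

    def test_clean_guide_scored_from_its_23mm_sites(self, weights, rng):
        spacer = random_spacer(rng)
        genome, truth = implant_sites(
            random_genome(8000, seed=35),
            PlantSpec(spacer, [(0, (), "TGG", 1), (2, (), "TGG", 2), (3, (), "AGG", 1)]),
            seed=36)
        res = score_guide("g", spacer, genome, weights)
        assert res.searchable and 0.0 < res.score < 1.0
        expected = sum(cfd_site_score(t, weights) for t in truth if t.n_mismatch > 0)
        assert res.cfd_sum == pytest.approx(expected)


class TestWeightTableIO:
    def test_round_trip(self, weights, tmp_path):
        mp, pp = tmp_path / "mm.tsv", tmp_path / "pam.tsv"
        weights.save(mp, pp)
        loaded = CfdWeightTable.load(mp, pp)
        assert loaded.mismatch_weights == weights.mismatch_weights
        assert loaded.pam_weights == weights.pam_weights

    def test_packaged_asset_is_complete_and_valid(self):
        table = default_weight_table()
        assert len(table.mismatch_weights) == 20 * 12
        assert table.pam_weights["GG"] == 1.0
        assert all(0.0 <= w <= 1.0 for w in table.mismatch_weights.values())

    def test_ngg_weight_must_be_one(self):
        with pytest.raises(ValueError, match="NGG"):
            CfdWeightTable({}, {"GG": 0.9})

    def test_scores_tsv_round_trip(self, weights, tmp_path, rng):
        spacer = random_spacer(rng)
        genome, _ = implant_sites(random_genome(6000, seed=41),
                                  PlantSpec(spacer, [(0, (), "TGG", 1),
                                                     (2, (), "CGG", 2)]), seed=42)
        results = [score_guide("g1", spacer, genome, weights)]
        path = tmp_path / "scores.tsv"
        write_scores_tsv(results, path)
        loaded = read_scores_tsv(path)
        assert loaded["g1"].searchable
        assert loaded["g1"].score == pytest.approx(results[0].score, rel=1e-5)
        assert loaded["g1"].tally.counts == results[0].tally.counts
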