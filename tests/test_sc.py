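import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import brute_cluster, scan_tpm_filter
from tcrshare.errors import ArgumentError, DataError
from tcrshare.sc import (CellTCR, ReconstructedChain,
                         beta_only_vs_paired_similarity, cluster_cells,
                         cluster_composition_summary, cross_subset_sharing,
                         equivalence_key, expanded_clusters, tpm_filter)


def chain(cell="c1", locus="TRB", junction="ACGACGACG", v="TRBV1", j="TRBJ1",
          d=None, tpm=10.0, productive=True):
    return ReconstructedChain(cell_id=cell, locus=locus, junction_nt=junction,
                              v_segment=v, d_segment=d, j_segment=j,
                              productive=productive, tpm=tpm)


def make_cell(cell_id, alpha_junctions=(), beta_junctions=(), subset=None,
              tpms=None):
    """Cell with one chain per junction; tpms maps junction -> TPM."""
    tpms = tpms or {}
    chains = []
    for j in alpha_junctions:
        chains.append(chain(cell_id, "TRA", j, v="TRAV1", j="TRAJ1",
                            tpm=tpms.get(j, 10.0)))
    for j in beta_junctions:
        chains.append(chain(cell_id, "TRB", j, v="TRBV1", j="TRBJ1", d="TRBD1",
                            tpm=tpms.get(j, 10.0)))
    return CellTCR.from_chains(cell_id, chains, subset=subset)


class TestTpmFilter:
    def test_single_chain_always_retained(self):
        retained = tpm_filter([chain(tpm=0.01)], h=0.95)
        assert len(retained) == 1

    def test_low_tpm_tail_dropped(self):
        chains = [chain(junction=j, tpm=t) for j, t in
                  [("AAA", 50.0), ("CCC", 30.0), ("GGG", 15.0), ("TTT", 5.0)]]
        retained = tpm_filter(chains, h=0.95)
        assert [c.tpm for c in retained] == [50.0, 30.0, 15.0]

    @pytest.mark.parametrize("tpms,expected", [((96.0, 4.0), 1),
                                               ((94.0, 6.0), 2)])
    def test_cutoff_boundary(self, tpms, expected):
        chains = [chain(junction=j, tpm=t) for j, t in zip(("AAA", "CCC"), tpms)]
        assert len(tpm_filter(chains, h=0.95)) == expected

    def test_h_one_retains_everything(self):
        chains = [chain(junction=j, tpm=t)
                  for j, t in [("AAA", 99.0), ("CCC", 1.0), ("GGG", 0.5)]]
        assert len(tpm_filter(chains, h=1.0)) == 3

    def test_all_zero_tpm_retains_all_with_warning(self):
        chains = [chain(junction=j, tpm=0.0) for j in ("AAA", "CCC")]
        with pytest.warns(UserWarning, match="all-zero"):
            assert len(tpm_filter(chains, h=0.95)) == 2

    def test_empty_input_returns_empty(self):
        assert tpm_filter([], h=0.95) == []

    def test_rejects_invalid_h(self):
        with pytest.raises(ArgumentError):
            tpm_filter([chain()], h=0.0)

    @given(st.lists(st.floats(0.0, 1000.0), min_size=1, max_size=8),
           st.sampled_from([0.5, 0.8, 0.95, 0.99]))
    def test_matches_exhaustive_scan(self, tpms, h):
        chains = [chain(junction="ACG" * 3 + "AAA" * (i + 1), tpm=t)
                  for i, t in enumerate(tpms)]
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            retained = tpm_filter(chains, h=h)
        keyed = [(c.tpm, c.identity_key) for c in chains]
        expected = scan_tpm_filter(keyed, h)
        assert [(c.tpm, c.identity_key) for c in retained] == expected

    def test_retained_mass_meets_threshold(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            tpms = rng.lognormal(2, 1.5, size=rng.integers(1, 9))
            chains = [chain(junction="ACG" * 3 + "AAA" * (i + 1), tpm=float(t))
                      for i, t in enumerate(tpms)]
            retained = tpm_filter(chains, h=0.95)
            assert sum(c.tpm for c in retained) >= 0.95 * tpms.sum() * (1 - 1e-9)


class TestIdentityAndEquivalence:
    def test_allele_versions_share_identity(self):
        a = chain(v="TRBV7-2*01").identity_key
        b = chain(v="TRBV7-2*02").identity_key
        assert a == b

    def test_non_productive_chains_discarded(self):
        cell = CellTCR.from_chains("c1", [chain(productive=False)])
        assert cell.beta == ()

    def test_duplicate_chains_merged_summing_tpm(self):
        cell = CellTCR.from_chains("c1", [chain(tpm=5.0), chain(tpm=7.0)])
        assert len(cell.beta) == 1
        assert cell.beta[0].tpm == pytest.approx(12.0)

    def test_paired_cell_key_combines_both_loci(self):
        cell = make_cell("c1", ["AAA"], ["CCC"])
        key = equivalence_key(cell, relation=4)
        assert key[0] == "pair"
        assert len(key[1]) == 1 and len(key[2]) == 1

    def test_beta_only_cell_eligibility_by_relation(self):
        cell = make_cell("c1", [], ["CCC"])
        assert equivalence_key(cell, relation=2) is not None
        assert equivalence_key(cell, relation=3) is not None
        assert equivalence_key(cell, relation=1) is None
        assert equivalence_key(cell, relation=4) is None

    def test_identical_beta_different_alpha(self):
        c1 = make_cell("c1", ["AAA"], ["CCC"])
        c2 = make_cell("c2", ["GGG"], ["CCC"])
        assert equivalence_key(c1, 2) == equivalence_key(c2, 2)
        for relation in (1, 3, 4):
            assert equivalence_key(c1, relation) != equivalence_key(c2, relation)

    def test_unknown_relation_rejected(self):
        with pytest.raises(ArgumentError):
            equivalence_key(make_cell("c1", ["AAA"], ["CCC"]), relation=5)


class TestClusterCells:
    def test_identical_cells_form_one_cluster(self):
        cells = [make_cell(f"c{i}", ["AAA"], ["CCC"]) for i in range(3)]
        clusters, excluded = cluster_cells(cells)
        assert len(clusters) == 1 and clusters[0].n_cells == 3
        assert excluded == []

    def test_allele_variant_cells_cluster_together(self):
        c1 = CellTCR.from_chains("c1", [
            chain("c1", "TRA", "AAA", v="TRAV1*01", j="TRAJ1"),
            chain("c1", "TRB", "CCC", v="TRBV7-2*01", j="TRBJ1")])
        c2 = CellTCR.from_chains("c2", [
            chain("c2", "TRA", "AAA", v="TRAV1*02", j="TRAJ1"),
            chain("c2", "TRB", "CCC", v="TRBV7-2*02", j="TRBJ1")])
        clusters, _ = cluster_cells([c1, c2])
        assert len(clusters) == 1 and clusters[0].n_cells == 2

    def test_cell_over_beta_cap_excluded_and_reported(self):
        cell = make_cell("c1", ["AAA"], ["CCC", "GGG", "TTT"])
        clusters, excluded = cluster_cells([cell])
        assert clusters == []
        assert excluded[0].cell_id == "c1"
        assert "beta" in excluded[0].reason

    def test_duplicate_cell_id_rejected(self):
        cells = [make_cell("c1", ["AAA"], ["CCC"]),
                 make_cell("c1", ["GGG"], ["TTT"])]
        with pytest.raises(DataError):
            cluster_cells(cells)

    def test_partition_covers_all_inputs(self, random_cells):
        cells = random_cells(60, seed=5)
        for relation in (1, 2, 3, 4):
            clusters, excluded = cluster_cells(cells, relation=relation)
            clustered = [cid for c in clusters for cid in c.member_cells]
            assert len(clustered) == len(set(clustered))
            assert set(clustered) | {e.cell_id for e in excluded} == \
                {c.cell_id for c in cells}
            assert set(clustered).isdisjoint({e.cell_id for e in excluded})

    def test_matches_pairwise_closure_oracle(self, random_cells):
        for seed in range(12):
            cells = random_cells(40, seed=seed)
            for relation in (1, 2, 3, 4):
                clusters, excluded = cluster_cells(cells, relation=relation)
                partition = {frozenset(c.member_cells) for c in clusters}
                oracle_partition, oracle_excluded = brute_cluster(
                    cells, relation)
                assert partition == oracle_partition
                assert {e.cell_id for e in excluded} == oracle_excluded

    def test_relation_four_refines_the_others(self, random_cells):
        cells = random_cells(50, seed=99)
        fine, _ = cluster_cells(cells, relation=4)
        for coarse_relation in (1, 2, 3):
            coarse, _ = cluster_cells(cells, relation=coarse_relation)
            coarse_sets = [set(c.member_cells) for c in coarse]
            for cluster in fine:
                members = set(cluster.member_cells)
                # members eligible under the coarse relation stay together
                eligible = members & set().union(*coarse_sets) if coarse_sets \
                    else set()
                if not eligible:
                    continue
                assert any(eligible <= s for s in coarse_sets)


class TestSummaries:
    def test_composition_counts(self):
        cells = []
        for i in range(5):
            cells.append(make_cell(f"a{i}", [f"A{'A' * (i+1)}"],
                                   [f"C{'C' * (i+1)}"]))
        for i in range(2):
            cells.append(make_cell(f"b{i}", [f"G{'G' * (i+1)}", f"T{'T' * (i+1)}"],
                                   [f"CG{'C' * (i+1)}"]))
        clusters, _ = cluster_cells(cells)
        assert cluster_composition_summary(clusters) == {(1, 1): 5, (2, 1): 2}

    def test_composition_empty(self):
        assert cluster_composition_summary([]) == {}

    def test_expanded_filters_by_size(self):
        cells = ([make_cell(f"x{i}", ["AAA"], ["CCC"]) for i in range(3)]
                 + [make_cell("y0", ["GGG"], ["TTT"])]
                 + [make_cell(f"z{i}", ["AAG"], ["CCT"]) for i in range(2)])
        clusters, _ = cluster_cells(cells)
        assert len(expanded_clusters(clusters, min_cells=2)) == 2
        assert len(expanded_clusters(clusters, min_cells=1)) == 3
        assert expanded_clusters([c for c in clusters if c.n_cells == 1]) == []


class TestCrossSubsetSharing:
    def build_clusters(self, spec):
        """spec: list of lists of subset labels, one inner list per cluster."""
        cells, annotations = [], {}
        for i, labels in enumerate(spec):
            for k, label in enumerate(labels):
                cid = f"c{i}_{k}"
                cells.append(make_cell(cid, [f"A{'A' * (i+1)}"],
                                       [f"C{'C' * (i+1)}"]))
                annotations[cid] = label
        clusters, _ = cluster_cells(cells)
        return clusters, annotations

    def test_two_subset_cluster_counted_in_intersection(self):
        clusters, ann = self.build_clusters([["Tconv", "Treg"]])
        sharing = cross_subset_sharing(clusters, ann)
        assert sharing["region_counts"] == {("Tconv", "Treg"): 1}
        assert sharing["pairwise_shared"][("Tconv", "Treg")] == 1

    def test_single_subset_clusters_have_no_intersections(self):
        clusters, ann = self.build_clusters([["Treg"], ["Tconv"], ["Tconv"]])
        sharing = cross_subset_sharing(clusters, ann)
        assert all(len(region) == 1 for region in sharing["region_counts"])
        assert sharing["pairwise_shared"][("Tconv", "Treg")] == 0

    def test_triple_spanning_cluster(self):
        spec = ([["Tconv"], ["Treg"], ["ActTconv"], ["Tconv", "Treg"],
                 ["Treg", "ActTconv"], ["Tconv", "Treg", "ActTconv"]])
        clusters, ann = self.build_clusters(spec)
        sharing = cross_subset_sharing(clusters, ann)
        assert sharing["region_counts"][("ActTconv", "Tconv", "Treg")] == 1
        assert sharing["pairwise_shared"][("Tconv", "Treg")] == 2

    def test_unannotated_cell_rejected(self):
        clusters, ann = self.build_clusters([["Treg"]])
        with pytest.raises(DataError):
            cross_subset_sharing(clusters, {})


class TestBetaOnlyVsPaired:
    def test_identical_composition_scores_one_under_both(self):
        cells = [make_cell(f"a{i}", ["AAA"], ["CCC"], subset="Treg")
                 for i in range(3)]
        cells += [make_cell(f"b{i}", ["AAA"], ["CCC"], subset="Tconv")
                  for i in range(3)]
        assert beta_only_vs_paired_similarity(cells, ("Treg", "Tconv")) == \
            (pytest.approx(1.0), pytest.approx(1.0))

    def test_disjoint_clonotypes_score_zero_under_both(self):
        cells = [make_cell("a0", ["AAA"], ["CCC"], subset="Treg"),
                 make_cell("a1", ["AAA"], ["CCC"], subset="Treg"),
                 make_cell("b0", ["GGG"], ["TTT"], subset="Tconv"),
                 make_cell("b1", ["GGG"], ["TTT"], subset="Tconv")]
        assert beta_only_vs_paired_similarity(cells, ("Treg", "Tconv")) == \
            (pytest.approx(0.0), pytest.approx(0.0))

    def test_beta_identical_alpha_divergent_clones(self):
        # same beta chain in both subsets, different alpha: relation 2 sees
        # full similarity, relation 4 none
        cells = [make_cell("a0", ["AAA"], ["CCC"], subset="Treg"),
                 make_cell("b0", ["GGG"], ["CCC"], subset="Tconv")]
        mh_beta, mh_paired = beta_only_vs_paired_similarity(
            cells, ("Treg", "Tconv"))
        assert mh_beta > mh_paired
        assert mh_beta == pytest.approx(1.0)
        assert mh_paired == pytest.approx(0.0)

    def test_empty_subset_rejected(self):
        cells = [make_cell("a0", ["AAA"], ["CCC"], subset="Treg"),
                 make_cell("b0", [], ["CCC"], subset="Tconv")]
        with pytest.raises(ArgumentError):
            beta_only_vs_paired_similarity(cells, ("Treg", "Tconv"))
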