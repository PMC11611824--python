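"""Curation filters, species-level clustering and genus-level delineation."""

import numpy as np
import pytest

from cablediv import delineate, phylo, seqio
from cablediv.identity import IdentityMatrix, identity_matrix

from tests.conftest import make_record


def im_from(ids, values):
    return IdentityMatrix(list(ids), np.array(values, dtype=float))


class TestLengthFilter:
    def test_cutoff_is_inclusive_at_800(self):
        short = make_record("s", "A" * 799)
        keep = make_record("k", "A" * 800)
        retained, removed, flags = delineate.filter_length([short, keep])
        assert [r.id for r in retained] == ["k"]
        assert [r.id for r in removed] == ["s"]

    def test_nearly_complete_and_full_length_flags(self):
        recs = [make_record("a", "A" * 1199), make_record("b", "A" * 1200),
                make_record("c", "A" * 1450)]
        _, _, flags = delineate.filter_length(recs)
        assert not flags["a"].nearly_complete
        assert flags["b"].nearly_complete and not flags["b"].full_length
        assert flags["c"].nearly_complete and flags["c"].full_length

    def test_min_len_must_be_positive(self):
        with pytest.raises(ValueError):
            delineate.filter_length([], min_len=0)


def _profile_fixture():
    """Ten identical references except for a hot column block, yielding one
    long conserved run and a small variable window."""
    rng = np.random.default_rng(4)
    base = "".join(rng.choice(list("ACGT"), 120))
    refs = []
    for i in range(10):
        s = list(base)
        for p in range(55, 65):  # variable window: every reference differs
            s[p] = "ACGT"[(("ACGT".index(s[p])) + 1 + i) % 4]
        refs.append(make_record(f"ref{i}", "".join(s)))
    profile = delineate.build_conserved_profile(refs, min_conservation=0.95,
                                                min_run=10)
    return base, refs, profile


class TestConservedProfile:
    def test_variable_window_not_conserved(self):
        base, refs, profile = _profile_fixture()
        cons = profile.conserved_columns
        assert not cons[55:65].any()
        assert cons[:40].all()

    def test_clean_record_retained(self):
        base, refs, profile = _profile_fixture()
        rec = make_record("clean", profile.consensus)
        retained, flagged = delineate.flag_conserved_violations([rec], profile)
        assert [r.id for r in retained] == ["clean"]

    def test_deletion_in_conserved_region_is_flagged(self):
        base, refs, profile = _profile_fixture()
        # remove 20 bases from the middle of the leading conserved run; a
        # deletion this deep inside the sequence cannot escape as an end gap
        mutant = profile.consensus[:20] + profile.consensus[40:]
        retained, flagged = delineate.flag_conserved_violations(
            [make_record("del20", mutant)], profile
        )
        assert [r.id for r in flagged] == ["del20"]

    def test_changes_at_variable_columns_are_free(self):
        base, refs, profile = _profile_fixture()
        s = list(profile.consensus)
        for p in range(55, 65):
            s[p] = "ACGT"[("ACGT".index(s[p]) + 2) % 4]
        retained, flagged = delineate.flag_conserved_violations(
            [make_record("var", "".join(s))], profile
        )
        assert [r.id for r in retained] == ["var"]

    def test_empty_profile_is_an_error(self):
        with pytest.raises(ValueError):
            delineate.build_conserved_profile([])

    def test_exact_and_fast_counts_agree_on_clean_data(self):
        base, refs, profile = _profile_fixture()
        cons = profile.conserved_columns
        for rec in refs[:3]:
            fast = delineate.count_conserved_violations(rec, profile, cons)
            exact = delineate.count_conserved_violations_exact(rec, profile, cons)
            assert fast == exact == 0


class TestMonophylyFilter:
    def test_planted_contaminant_removed(self):
        tree = seqio.read_newick("(((s1:1,s2:1):1,x:2):1,out:3);")
        retained, removed = delineate.monophyly_filter(tree, {"s1", "s2"}, "out")
        assert retained == {"s1", "s2"}
        assert removed == {"x"}

    def test_seeds_spanning_ingroup_remove_nothing(self):
        tree = seqio.read_newick("(((s1:1,s2:1):1,x:2):1,out:3);")
        retained, removed = delineate.monophyly_filter(tree, {"s1", "s2", "x"}, "out")
        assert retained == {"s1", "s2", "x"}
        assert removed == set()

    def test_missing_seed_is_an_error(self):
        tree = seqio.read_newick("((s1:1,s2:1):1,out:3);")
        with pytest.raises(KeyError):
            delineate.monophyly_filter(tree, {"s1", "zz"}, "out")


class TestClusterSpecies:
    def test_pair_above_cutoff_forms_one_clade(self):
        im = im_from(["a", "b"], [[100, 99.0], [99.0, 100]])
        assert delineate.cluster_species(im) == [{"a", "b"}]

    def test_pair_below_cutoff_stays_split(self):
        im = im_from(["a", "b"], [[100, 98.0], [98.0, 100]])
        assert delineate.cluster_species(im) == [{"a"}, {"b"}]

    def test_chain_is_broken_by_complete_linkage(self):
        im = im_from(
            ["a", "b", "c"],
            [[100, 99.0, 98.0], [99.0, 100, 99.0], [98.0, 99.0, 100]],
        )
        assert delineate.cluster_species(im) == [{"a", "b"}, {"c"}]

    def test_chain_merges_under_single_linkage(self):
        im = im_from(
            ["a", "b", "c"],
            [[100, 99.0, 98.0], [99.0, 100, 99.0], [98.0, 99.0, 100]],
        )
        assert delineate.cluster_species(im, linkage="single") == [{"a", "b", "c"}]

    def test_matches_scipy_complete_linkage_oracle(self):
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(31)
        for _ in range(60):
            n = int(rng.integers(2, 11))
            vals = _random_identity_matrix(n, rng)
            im = IdentityMatrix([f"r{i}" for i in range(n)], vals)
            ours = delineate.cluster_species(im, cutoff=98.7)
            D = squareform(100.0 - vals, checks=False)
            labels = fcluster(linkage(D, method="complete"), t=1.3,
                              criterion="distance")
            theirs = {}
            for rid, lab in zip(im.ids, labels):
                theirs.setdefault(lab, set()).add(rid)
            assert sorted(ours, key=min) == sorted(theirs.values(), key=min)

    def test_raising_cutoff_never_merges_groups(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            n = int(rng.integers(3, 9))
            im = IdentityMatrix([f"r{i}" for i in range(n)],
                                _random_identity_matrix(n, rng))
            sizes = [len(delineate.cluster_species(im, cutoff=c))
                     for c in (97.0, 98.7, 99.5)]
            assert sizes == sorted(sizes)

    def test_every_within_clade_pair_meets_cutoff(self):
        rng = np.random.default_rng(41)
        im = IdentityMatrix([f"r{i}" for i in range(8)],
                            _random_identity_matrix(8, rng))
        for group in delineate.cluster_species(im, cutoff=98.7):
            ids = sorted(group)
            for i, a in enumerate(ids):
                for b in ids[i + 1:]:
                    assert im.get(a, b) >= 98.7


def _random_identity_matrix(n, rng):
    vals = np.full((n, n), 100.0)
    iu = np.triu_indices(n, k=1)
    draws = rng.uniform(97.0, 100.0, size=len(iu[0]))
    vals[iu] = draws
    vals[(iu[1], iu[0])] = draws
    return vals


class TestFinalizeClades:
    def test_longest_member_is_representative(self):
        recs = [make_record("x", "A" * 1500), make_record("y", "A" * 900)]
        clades = delineate.finalize_clades([{"x", "y"}], recs)
        assert clades[0].representative_id == "x"
        assert clades[0].valid and not clades[0].singleton

    def test_group_without_nearly_complete_member_is_invalid(self):
        recs = [make_record("x", "A" * 1199)]
        clades = delineate.finalize_clades([{"x"}], recs)
        assert not clades[0].valid
        assert clades[0].singleton

    def test_length_tie_broken_lexicographically(self):
        recs = [make_record("zz", "A" * 1300), make_record("aa", "C" * 1300)]
        clades = delineate.finalize_clades([{"zz", "aa"}], recs)
        assert clades[0].representative_id == "aa"

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError):
            delineate.finalize_clades([set()], [])

    def test_raising_min_rep_len_never_adds_valid_clades(self):
        recs = [make_record("a", "A" * 1250), make_record("b", "A" * 1500)]
        groups = [{"a"}, {"b"}]
        n_valid = [
            sum(c.valid for c in delineate.finalize_clades(groups, recs, m))
            for m in (1200, 1300, 1600)
        ]
        assert n_valid == sorted(n_valid, reverse=True)


class TestClusterGenus:
    def _setup(self, pid):
        ids = ["a", "b"]
        im = im_from(["a", "b", "out"],
                     [[100, pid, 80], [pid, 100, 80], [80, 80, 100]])
        tree = seqio.read_newick("((a:1,b:1):1,out:3);")
        recs = [make_record("a", "A" * 1300), make_record("b", "C" * 1300)]
        clades = delineate.finalize_clades([{"a"}, {"b"}], recs)
        return tree, im, clades

    def test_sisters_above_guide_form_one_cluster(self):
        tree, im, clades = self._setup(96.0)
        clusters = delineate.cluster_genus(tree, im, "out", clades)
        assert len(clusters) == 1
        assert clusters[0].min_intra_identity == pytest.approx(96.0)

    def test_sisters_below_guide_are_split(self):
        tree, im, clades = self._setup(93.0)
        clusters = delineate.cluster_genus(tree, im, "out", clades)
        assert len(clusters) == 2

    def test_tolerance_admits_subcutoff_pairs(self):
        tree, im, clades = self._setup(93.0)
        clusters = delineate.cluster_genus(tree, im, "out", clades, tolerance=2.0)
        assert len(clusters) == 1

    def test_leaf_matrix_mismatch_is_an_error(self):
        tree = seqio.read_newick("((a:1,zz:1):1,out:3);")
        im = im_from(["a", "out"], [[100, 80], [80, 100]])
        with pytest.raises(ValueError):
            delineate.cluster_genus(tree, im, "out", [])

    def test_clusters_partition_and_are_monophyletic(self, survey_run):
        records, sites, truth, result = survey_run
        all_clades = {c.clade_id for c in result.clades if c.valid}
        seen = set()
        for g in result.clusters:
            assert not (g.clade_ids & seen)
            seen |= g.clade_ids
            q = phylo.root_and_query(
                result.genus_tree, truth.outgroup_id,
                set(g.representative_ids),
            )
            assert q.monophyletic
        assert seen == all_clades


class TestSummaries:
    def test_empty_inputs_give_zero_summary(self):
        summary = delineate.summarize([], [], None, delineate.CurationReport())
        assert summary.n_valid_clades == 0
        assert summary.n_genus_clusters == 0
        assert summary.n_singletons == 0

    def test_statuses_partition_input(self, survey_run):
        records, sites, truth, result = survey_run
        statuses = result.report.status
        in_clade = [r for r in records if r.id != truth.outgroup_id]
        assert set(statuses) == {r.id for r in in_clade}
        tab = result.report.counts_by_source()
        assert tab["total"].sum() == len(in_clade)

    def test_survey_recovery(self, survey_run):
        records, sites, truth, result = survey_run
        s = result.summary
        assert (s.n_valid_clades, s.n_genus_clusters, s.n_singletons) == (90, 6, 38)
        # every cluster's internal cohesion exceeds the separation to the rest
        assert s.min_intra_cluster_identity > s.max_inter_cluster_identity
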