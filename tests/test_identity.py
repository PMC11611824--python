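"""Alignment, percent identity, identity matrices and reference screening."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cablediv import identity as idt
from cablediv.seqio import SequenceRecord

from tests.conftest import make_record

DNA = st.text(alphabet="ACGT", min_size=4, max_size=40)


class TestAlignPair:
    def test_identical_sequences_align_without_gaps(self):
        aln = idt.align_pair(make_record("a", "ACGT"), make_record("b", "ACGT"))
        assert aln.aligned_a == aln.aligned_b == "ACGT"
        assert idt.percent_identity(aln) == 100.0

    def test_single_deletion_keeps_seven_matches(self):
        # the optimal affine alignment opens one internal gap, not an end shift
        aln = idt.align_pair(make_record("a", "ACGTACGT"), make_record("b", "ACGACGT"))
        cols = list(zip(aln.aligned_a, aln.aligned_b))
        gap_cols = [c for c in cols if "-" in c]
        match_cols = [c for c in cols if "-" not in c and idt.bases_intersect(*c)]
        assert len(gap_cols) == 1
        assert len(match_cols) == 7

    def test_disjoint_sequences_prefer_free_end_skip(self):
        # full end-gap skip scores 0, beating four mismatches at -1 each
        aln = idt.align_pair(make_record("a", "AAAA"), make_record("b", "TTTT"))
        assert aln.score == 0.0

    def test_gap_removal_recovers_inputs(self):
        a, b = make_record("a", "ACGTACGTAA"), make_record("b", "CGTACG")
        aln = idt.align_pair(a, b)
        assert aln.aligned_a.replace("-", "") == a.residues
        assert aln.aligned_b.replace("-", "") == b.residues


class TestPercentIdentity:
    def test_seven_of_eight(self):
        aln = idt.align_pair(make_record("a", "ACGTACGT"), make_record("b", "ACGAACGT"))
        assert idt.percent_identity(aln) == pytest.approx(87.5)

    def test_pairwise_deletion_ignores_gap_columns(self):
        aln = idt.align_pair(make_record("a", "ACGTACGT"), make_record("b", "ACGACGT"))
        assert idt.percent_identity(aln) == pytest.approx(100.0)

    def test_no_comparable_columns_is_an_error(self):
        aln = idt.PairwiseAlignment("a", "b", "AA--", "--TT", 0.0)
        with pytest.raises(idt.UndefinedIdentityError):
            idt.percent_identity(aln)

    def test_degenerate_codes_match_by_intersection(self):
        aln = idt.align_pair(make_record("a", "AMGTRCGT"), make_record("b", "ACGTACGT"))
        assert idt.percent_identity(aln) == pytest.approx(100.0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=30, max_size=80), st.integers(0, 2**31 - 1))
def test_identity_symmetry_and_revcomp_invariance(sa, seed):
    """On homologous pairs (one sequence mutated from the other) identity is
    symmetric in its arguments and invariant under reverse-complementing both.

    Co-optimal alignments may differ in a match or two, hence the small slack.
    """
    rng = np.random.default_rng(seed)
    sb = list(sa)
    for p in rng.choice(len(sb), size=max(1, len(sb) // 12), replace=False):
        sb[p] = "ACGT"[("ACGT".index(sb[p]) + 1 + int(rng.integers(3))) % 4]
    if rng.random() < 0.5:  # sometimes make it a fragment
        sb = sb[3:-3]
    sb = "".join(sb)
    a, b = make_record("a", sa), make_record("b", sb)
    ra = make_record("ra", idt.reverse_complement(sa))
    rb = make_record("rb", idt.reverse_complement(sb))
    for method in ("exact", "fast"):
        pid = idt.pair_identity(a, b, method=method)
        assert idt.pair_identity(b, a, method=method) == pytest.approx(pid, abs=1.0)
        assert idt.pair_identity(ra, rb, method=method) == pytest.approx(pid, abs=1.0)
        assert 0.0 <= pid <= 100.0


class TestIdentityMatrix:
    def test_single_record(self):
        im = idt.identity_matrix([make_record("a", "ACGT")])
        assert im.values.tolist() == [[100.0]]

    def test_identical_records_have_offdiagonal_100(self):
        im = idt.identity_matrix(
            [make_record("a", "ACGTACGT"), make_record("b", "ACGTACGT")]
        )
        assert im.get("a", "b") == 100.0

    def test_matches_naive_per_pair_recomputation(self):
        rng = np.random.default_rng(5)
        recs = [
            make_record(f"r{i}", "".join(rng.choice(list("ACGT"), 60)))
            for i in range(5)
        ]
        im = idt.identity_matrix(recs, method="exact")
        for i, a in enumerate(recs):
            for j, b in enumerate(recs):
                if i < j:
                    expect = idt.percent_identity(idt.align_pair(a, b))
                    assert im.get(a.id, b.id) == pytest.approx(expect)
                    assert im.get(b.id, a.id) == pytest.approx(expect)
        assert np.allclose(np.diag(im.values), 100.0)

    def test_duplicate_ids_rejected(self):
        recs = [make_record("a", "ACGT"), make_record("a", "ACGT")]
        with pytest.raises(ValueError):
            idt.identity_matrix(recs)

    def test_csv_roundtrip(self, tmp_path):
        im = idt.identity_matrix(
            [make_record("a", "ACGTACGTAC"), make_record("b", "ACGAACGTAC")]
        )
        p = tmp_path / "im.csv"
        im.to_csv(p)
        back = idt.IdentityMatrix.from_csv(p)
        assert back.ids == im.ids
        assert np.allclose(back.values, im.values, atol=1e-4)


class TestFastEngineAgreement:
    """The edlib engine must track the affine engine on pipeline-like data."""

    @pytest.mark.parametrize("divergence,tol", [(0.01, 0.35), (0.05, 1.6)])
    def test_fast_vs_exact_on_mutated_pairs(self, divergence, tol):
        rng = np.random.default_rng(17)
        base = rng.choice(list("ACGT"), 600)
        for _ in range(8):
            other = base.copy()
            k = int(divergence * base.size)
            pos = rng.choice(base.size, size=k, replace=False)
            for p in pos:
                other[p] = "ACGT"[(("ACGT".index(other[p])) + 1 + rng.integers(3)) % 4]
            a = make_record("a", "".join(base))
            b = make_record("b", "".join(other))
            fast = idt.pair_identity(a, b, method="fast")
            exact = idt.pair_identity(a, b, method="exact")
            assert fast == pytest.approx(exact, abs=tol)

    def test_fragment_against_full_length_is_not_end_penalised(self):
        rng = np.random.default_rng(23)
        full = "".join(rng.choice(list("ACGT"), 900))
        frag = full[250:750]
        pid = idt.pair_identity(make_record("f", frag), make_record("t", full),
                                method="fast")
        assert pid == 100.0


class TestScreening:
    def _queries(self):
        rng = np.random.default_rng(2)
        q = "".join(rng.choice(list("ACGT"), 300))
        return q, [make_record("q1", q)]

    def _mutated(self, seq, n, seed=0):
        rng = np.random.default_rng(seed)
        s = list(seq)
        for p in rng.choice(len(s), size=n, replace=False):
            s[p] = "ACGT"[("ACGT".index(s[p]) + 1) % 4]
        return "".join(s)

    def test_identical_record_retained_at_100(self):
        q, queries = self._queries()
        res = idt.screen_references([make_record("r", q)], queries)
        assert res[0].retained and res[0].best_identity == 100.0

    def test_distant_record_rejected_below_cutoff(self):
        q, queries = self._queries()
        rec = make_record("r", self._mutated(q, 45))  # ~85% identity
        res = idt.screen_references([rec], queries, cutoff=92.0)
        assert not res[0].retained
        assert res[0].best_identity < 92.0

    def test_whitelisted_record_retained_despite_low_identity(self):
        # emulates the one curated sub-cutoff exception kept in the database mine
        q, queries = self._queries()
        rec = make_record("GU208270", self._mutated(q, 27))  # ~91% identity
        res = idt.screen_references([rec], queries, cutoff=92.0,
                                    whitelist={"GU208270"})
        assert res[0].retained and res[0].whitelisted
        assert res[0].best_identity < 92.0

    def test_cutoff_monotonicity(self):
        q, queries = self._queries()
        records = [
            make_record(f"r{i}", self._mutated(q, n, seed=i))
            for i, n in enumerate([0, 6, 15, 24, 33, 45])
        ]
        kept = {}
        for cutoff in (85.0, 92.0, 97.0):
            res = idt.screen_references(records, queries, cutoff=cutoff)
            kept[cutoff] = {r.record_id for r in res if r.retained}
        assert kept[97.0] <= kept[92.0] <= kept[85.0]

    def test_empty_query_set_is_an_error(self):
        with pytest.raises(ValueError):
            idt.screen_references([make_record("r", "ACGT")], [])
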