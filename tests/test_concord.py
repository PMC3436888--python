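"""Concordance engine: pairwise statistics, matrices, level summaries and
cross-panel harmonization."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import genorep as g
from genorep.core import HET, HOM_MAJ, HOM_MIN, NO_CALL
from genorep.exceptions import (
    DesignError,
    PanelError,
    UndefinedConcordanceError,
)

from conftest import make_matrix


def oracle_concordance(a, b, mode):
    """Independent nested-loop concordance."""
    n_total = len(a)
    n_compared = n_agree = 0
    for x, y in zip(a, b):
        if mode == "co_called":
            if x != NO_CALL and y != NO_CALL:
                n_compared += 1
                n_agree += int(x == y)
        else:
            n_compared += 1
            n_agree += int(x == y)
    return n_total, n_compared, n_agree


class TestPairwise:
    def test_hand_enumerated_ten_snp_example(self):
        """Identical except one mismatch and one no-call: 8/9 vs 8/10."""
        a = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, NO_CALL], dtype=np.int8)
        b = a.copy()
        b[2] = HOM_MAJ  # SNP3 differs
        b[9] = HET  # SNP10 no-call in a only
        r_co = g.pairwise_concordance(a, b, "co_called")
        assert (r_co.n_total_snps, r_co.n_compared, r_co.n_agree) == (10, 9, 8)
        assert r_co.concordance == pytest.approx(8 / 9)
        r_st = g.pairwise_concordance(a, b, "strict")
        assert (r_st.n_compared, r_st.n_agree) == (10, 8)
        assert r_st.concordance == pytest.approx(0.80)

    def test_identity_and_total_discordance(self):
        a = np.array([0, 1, 2, 1], dtype=np.int8)
        for mode in ("co_called", "strict"):
            assert g.pairwise_concordance(a, a, mode).concordance == 1.0
        b = (a + 1) % 3
        assert g.pairwise_concordance(a, b, "co_called").concordance == 0.0

    def test_errors(self):
        with pytest.raises(PanelError):
            g.pairwise_concordance(np.zeros(3, np.int8), np.zeros(4, np.int8))
        nc = np.full(5, NO_CALL, dtype=np.int8)
        with pytest.raises(UndefinedConcordanceError):
            g.pairwise_concordance(nc, nc, "co_called")
        assert g.pairwise_concordance(nc, nc, "strict").concordance == 1.0

    @given(
        st.lists(
            st.tuples(st.sampled_from([0, 1, 2, -1]), st.sampled_from([0, 1, 2, -1])),
            min_size=1,
            max_size=60,
        )
    )
    @settings(derandomize=True, max_examples=150)
    def test_symmetry_mode_ordering_and_consistency(self, pairs):
        a = np.array([p[0] for p in pairs], dtype=np.int8)
        b = np.array([p[1] for p in pairs], dtype=np.int8)
        strict_ab = g.pairwise_concordance(a, b, "strict")
        strict_ba = g.pairwise_concordance(b, a, "strict")
        assert strict_ab.concordance == strict_ba.concordance
        assert strict_ab.n_agree <= strict_ab.n_compared <= strict_ab.n_total_snps
        co_defined = bool(((a != NO_CALL) & (b != NO_CALL)).any())
        if co_defined:
            co_ab = g.pairwise_concordance(a, b, "co_called")
            assert co_ab.concordance == g.pairwise_concordance(b, a, "co_called").concordance
            no_nocall = bool((a != NO_CALL).all() and (b != NO_CALL).all())
            # strict counts double-no-calls as agreements, so the ordering
            # holds whenever neither vector contains a no-call, or when the
            # pair has no-calls only on one side
            both_nc = int(((a == NO_CALL) & (b == NO_CALL)).sum())
            if no_nocall:
                assert strict_ab.concordance == co_ab.concordance
            elif both_nc == 0:
                assert strict_ab.concordance <= co_ab.concordance


class TestMatrix:
    def test_error_free_replicates_all_ones(self):
        m = make_matrix(np.tile([0, 1, 2, 1, 0], (4, 1)))
        cm = g.concordance_matrix(m)
        assert (cm.to_numpy() == 1.0).all()

    def test_matches_nested_loop_oracle_on_fixture(self):
        rng = np.random.default_rng(55)
        calls = rng.choice([0, 1, 2, -1], size=(6, 50), p=[0.4, 0.3, 0.2, 0.1])
        m = make_matrix(calls)
        for mode in ("co_called", "strict"):
            cm = g.concordance_matrix(m, mode=mode)
            assert (cm.to_numpy() == cm.to_numpy().T).all()
            assert (np.diag(cm.to_numpy()) == 1.0).all()
            for i, j in itertools.combinations(range(6), 2):
                n, nc, na = oracle_concordance(calls[i], calls[j], mode)
                assert cm.iloc[i, j] == na / nc

    def test_empty_selection(self):
        m = make_matrix([[0, 1, 2]])
        with pytest.raises(DesignError):
            g.concordance_matrix(m, sample_ids=[])


class TestSummaries:
    def test_perfect_replicates(self):
        _, truth = g.generate_truth(6, 300, 0.05, 0.5, seed=60)
        design = g.table1_design()
        calls = g.simulate_replicate_study(truth, design, g.ErrorModel(0.0, 0.0), seed=61)
        _, summary = g.reproducibility_summary(calls, design, "intra")
        assert (summary["mean"] == 1.0).all()
        assert (summary["sd"] == 0.0).all()

    def test_group_structure_of_full_design(self):
        """Three Affy6 experiment pairs, one Illu1M pair, six cross-platform
        pairs; 6 intra pairs per subject-experiment, 16 per cross group."""
        design = g.table1_design()
        intra = g.level_pairs(design, "intra")
        assert len(intra) == 6 * 6 * 5  # C(4,2) pairs x subjects x experiments
        inter_lab = g.level_pairs(design, "inter_lab")
        groups = {grp for _, _, _, grp in inter_lab}
        assert groups == {"E1|E2", "E1|E3", "E2|E3", "E4|E5"}
        assert len(inter_lab) == 6 * 4 * 16  # 16 = 4x4 replicate pairs
        inter_plat = g.level_pairs(design, "inter_platform")
        pgroups = {grp for _, _, _, grp in inter_plat}
        assert pgroups == {f"E{i}|E{j}" for i in (1, 2, 3) for j in (4, 5)}
        assert len(inter_plat) == 6 * 6 * 16

    def test_summary_pair_counts_and_overall(self):
        _, truth = g.generate_truth(6, 200, 0.05, 0.5, seed=62)
        design = g.table1_design()
        calls = g.simulate_replicate_study(truth, design, g.ErrorModel(0.01, 0.0), seed=63)
        results, summary = g.reproducibility_summary(calls, design, "inter_lab")
        per_subject = summary[(summary["subject"] != "ALL")]
        assert (per_subject["n_pairs"] == 16).all()
        overall = summary[(summary["subject"] == "ALL") & (summary["group"] == "ALL")]
        assert overall["n_pairs"].iloc[0] == len(results) == 6 * 4 * 16
        member = np.array([r.concordance for r in results])
        assert overall["mean"].iloc[0] == pytest.approx(member.mean())
        assert overall["sd"].iloc[0] == pytest.approx(member.std(ddof=1))

    def test_single_pair_group_has_zero_sd(self):
        design = g.table1_design(n_replicates=2, subjects=["A"],
                                 experiment_platforms={"E1": "Affy6"})
        m = make_matrix([[0, 1, 2], [0, 1, 0]], sample_ids=["A1_E1", "A2_E1"])
        _, summary = g.reproducibility_summary(m, design, "intra")
        row = summary[summary["subject"] == "A"].iloc[0]
        assert row["n_pairs"] == 1 and row["sd"] == 0.0

    def test_empty_level_warns(self):
        design = g.table1_design(experiment_platforms={"E1": "Affy6"})
        with pytest.warns(UserWarning):
            out = g.summarize_reproducibility([], design, "inter_platform")
        assert out.empty


def _two_panels(alleles_a, alleles_b):
    def build(alleles):
        return g.SnpPanel(
            pd.DataFrame(
                {
                    "snp_id": [f"snp{i}" for i in range(len(alleles))],
                    "chromosome": ["1"] * len(alleles),
                    "position": np.arange(1, len(alleles) + 1, dtype=np.int64),
                    "allele_major": [a[0] for a in alleles],
                    "allele_minor": [a[1] for a in alleles],
                    "maf": [0.2] * len(alleles),
                }
            )
        )

    return build(alleles_a), build(alleles_b)


class TestHarmonization:
    def test_identical_panels(self):
        pa, pb = _two_panels([("A", "G"), ("C", "T")], [("A", "G"), ("C", "T")])
        h = g.harmonize_panels(pa, pb)
        assert h.shared["mapping"].tolist() == ["identical", "identical"]
        assert h.dropped.empty

    def test_strand_flip_recovers_equal_calls(self):
        """A/G in one panel, T/C in the other: complementary strand, calls
        compare equal after remapping."""
        pa, pb = _two_panels([("A", "G")], [("T", "C")])
        ma = g.GenotypeMatrix(pa, ["x"], np.array([[HET]], dtype=np.int8))
        mb = g.GenotypeMatrix(pb, ["y"], np.array([[HET]], dtype=np.int8))
        sa, sb, h = g.harmonize_matrices(ma, mb)
        assert h.shared["mapping"].tolist() == ["strand_flipped"]
        assert g.pairwise_concordance(sa.row("x"), sb.row("y")).concordance == 1.0

    def test_swapped_major_minor_remaps_homozygotes(self):
        pa, pb = _two_panels([("A", "G")], [("G", "A")])
        ma = g.GenotypeMatrix(pa, ["x"], np.array([[HOM_MAJ]], dtype=np.int8))
        # same physical genotype AA is HOM_MIN on the swapped panel
        mb = g.GenotypeMatrix(pb, ["y"], np.array([[HOM_MIN]], dtype=np.int8))
        sa, sb, h = g.harmonize_matrices(ma, mb)
        assert h.shared["mapping"].tolist() == ["swapped"]
        assert sb.row("y")[0] == HOM_MAJ
        assert g.pairwise_concordance(sa.row("x"), sb.row("y")).concordance == 1.0

    def test_palindromic_and_mismatched_snps_dropped(self):
        pa, pb = _two_panels(
            [("A", "T"), ("C", "G"), ("A", "G"), ("A", "C")],
            [("A", "T"), ("C", "G"), ("A", "C"), ("A", "C")],
        )
        h = g.harmonize_panels(pa, pb)
        dropped = dict(zip(h.dropped["snp_id"], h.dropped["reason"]))
        assert dropped["snp0"] == "strand_ambiguous"
        assert dropped["snp1"] == "strand_ambiguous"
        assert dropped["snp2"] == "allele_mismatch"
        assert h.shared["snp_id"].tolist() == ["snp3"]

    def test_disjoint_panels_warn(self):
        pa, pb = _two_panels([("A", "G")], [("C", "T")])
        pb = g.SnpPanel(pb.table.assign(snp_id=["other0"]))
        with pytest.warns(UserWarning):
            h = g.harmonize_panels(pa, pb)
        assert h.shared.empty

    def test_idempotence(self):
        """Harmonizing already-harmonized matrices changes nothing."""
        rng = np.random.default_rng(70)
        pa, pb = _two_panels(
            [("A", "G"), ("C", "T"), ("G", "T")],
            [("T", "C"), ("G", "A"), ("G", "T")],
        )
        ma = g.GenotypeMatrix(pa, ["x"], rng.choice([0, 1, 2], size=(1, 3)).astype(np.int8))
        mb = g.GenotypeMatrix(pb, ["y"], rng.choice([0, 1, 2], size=(1, 3)).astype(np.int8))
        sa1, sb1, _ = g.harmonize_matrices(ma, mb)
        sa2, sb2, h2 = g.harmonize_matrices(sa1, sb1)
        assert (h2.shared["mapping"] == "identical").all()
        assert (sa2.calls == sa1.calls).all()
        assert (sb2.calls == sb1.calls).all()
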