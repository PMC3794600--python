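"""TFBS-methylation-blocking inference: bin tests, consensus building,
threshold calibration, scanning and the candidate filters."""

import itertools

import numpy as np
import pandas as pd
import pytest

from methexpr import diffexp, simulate, tfbs
from methexpr.core import ExpressionMatrix, PWM, PWMSet, SubtypeTable, UsageError
from methexpr.tfbs import (
    TFBSCandidate,
    build_consensus,
    calibrate_threshold,
    filter_tf_expression,
    find_blocked_tfs,
    reverse_complement,
    scan_tfbs,
    support_rate,
)

hyper_bins = tfbs.test_bins  # imported under a non-test name


@pytest.fixture(scope="module")
def planted():
    ds = simulate.simulate_dataset(
        simulate.SimulationConfig(n_genes=30, planted_fraction=0.1, seed=5)
    )
    med = diffexp.subtype_medians(ds.expression, ds.subtypes)
    calls = diffexp.call_differential(med)
    return ds, calls


class TestTestBins:
    def test_planted_bins_significant(self, planted):
        ds, calls = planted
        hyper = hyper_bins(ds.binned, calls, ds.subtypes)
        planted_genes = ds.truth.all_planted()
        assert {h.gene_id for h in hyper} & planted_genes
        assert all(h.p_value < 0.005 for h in hyper)

    def test_identical_means_not_significant(self, panel):
        rng = np.random.default_rng(0)
        idx = pd.MultiIndex.from_product([["g1"], [-1]], names=["gene", "bin"])
        from methexpr.profiles import BinnedMethylation

        binned = BinnedMethylation(
            pd.DataFrame(rng.uniform(1, 2, size=(1, 30)), index=idx,
                         columns=panel.cell_lines)
        )
        calls = pd.DataFrame({"gene_id": ["g1"], "subtype": ["Lu"]})
        assert hyper_bins(binned, calls, panel, bins=(-1,)) == []

    def test_hypomethylated_direction_excluded(self, panel):
        idx = pd.MultiIndex.from_product([["g1"], [-1]], names=["gene", "bin"])
        vals = np.array(
            [1.0 if panel.subtype_of(cl) == "Lu" else 10.0 for cl in panel.cell_lines]
        ) + np.random.default_rng(1).normal(0, 0.1, 30)
        from methexpr.profiles import BinnedMethylation

        binned = BinnedMethylation(pd.DataFrame(vals[None, :], index=idx,
                                                columns=panel.cell_lines))
        calls = pd.DataFrame({"gene_id": ["g1"], "subtype": ["Lu"]})
        assert hyper_bins(binned, calls, panel, bins=(-1,)) == []


class TestBuildConsensus:
    REF = "ACGTACGTAC"

    def test_reads_agreeing_with_reference(self):
        cons = build_consensus([(0, self.REF)], self.REF)
        assert cons.sequence == self.REF
        assert cons.coverage == (1,) * 10

    def test_majority_vote(self):
        reads = [(0, "AAAA"), (0, "AAAA"), (0, "GAAA")]
        cons = build_consensus(reads, "TTTT")
        assert cons.sequence == "AAAA"  # 2 A beat 1 G at position 0

    def test_tie_falls_back_to_reference(self):
        reads = [(0, "A"), (0, "G")]
        assert build_consensus(reads, "G").sequence == "G"

    def test_zero_coverage_uses_reference(self):
        cons = build_consensus([], self.REF)
        assert cons.sequence == self.REF
        assert cons.coverage == (0,) * 10

    def test_overhanging_read_trimmed_with_warning(self):
        with pytest.warns(UserWarning, match="trimming"):
            cons = build_consensus([(8, "AAAA")], self.REF)
        assert len(cons.sequence) == 10


def consensus_pwm(word):
    probs = []
    for b in word:
        row = [0.01, 0.01, 0.01, 0.01]
        row["ACGT".index(b)] = 0.97
        probs.append(tuple(row))
    return PWM(f"M_{word}", tuple(probs))


class TestCalibrateThreshold:
    def test_minimal_set_is_the_consensus_word(self):
        pwm = consensus_pwm("ACGTA")
        with pytest.warns(UserWarning, match="maximal score"):
            thr = calibrate_threshold(pwm, target_fp_rate=1e-4)
        # exhaustive check: only the consensus word reaches the threshold
        lo = np.log2(pwm.as_array() / 0.25)
        smin, smax = lo.min(axis=1).sum(), lo.max(axis=1).sum()
        admitted = []
        for word in itertools.product(range(4), repeat=5):
            s = sum(lo[i, b] for i, b in enumerate(word))
            if (s - smin) / (smax - smin) >= thr:
                admitted.append(word)
        assert admitted == [(0, 1, 2, 3, 0)]  # ACGTA

    def test_achievable_rate_honoured(self):
        pwm = consensus_pwm("ACGTA")
        thr = calibrate_threshold(pwm, target_fp_rate=2e-3)
        # P(consensus word) = 0.97^5 / 4^5-weighted = (1/4)^5 ... per-word
        # uniform background: each word has probability (1/4)^5; the set of
        # admitted words must have total probability <= 2e-3, i.e. <= 2 words
        lo = np.log2(pwm.as_array() / 0.25)
        smin, smax = lo.min(axis=1).sum(), lo.max(axis=1).sum()
        n_admitted = 0
        for word in itertools.product(range(4), repeat=5):
            s = sum(lo[i, b] for i, b in enumerate(word))
            if (s - smin) / (smax - smin) >= thr:
                n_admitted += 1
        assert 1 <= n_admitted <= 2

    def test_uniform_pwm_degenerate(self):
        pwm = PWM("U", tuple((0.25, 0.25, 0.25, 0.25) for _ in range(4)))
        with pytest.warns(UserWarning):
            thr = calibrate_threshold(pwm, target_fp_rate=1e-3)
        assert thr == 0.0  # all words share the (normalized) score

    def test_threshold_monotone_in_target(self):
        pwm = consensus_pwm("ACGTACG")
        thresholds = [
            calibrate_threshold(pwm, target_fp_rate=r) for r in (0.1, 0.01, 0.001)
        ]
        assert thresholds[0] <= thresholds[1] <= thresholds[2]

    def test_monte_carlo_path_for_wide_matrices(self):
        rng = np.random.default_rng(3)
        word = "".join("ACGT"[i] for i in rng.integers(0, 4, size=12))
        thr = calibrate_threshold(consensus_pwm(word), target_fp_rate=1e-3, seed=0)
        assert 0.0 < thr <= 1.0

    def test_target_range_validated(self):
        with pytest.raises(UsageError):
            calibrate_threshold(consensus_pwm("ACGT"), target_fp_rate=0.7)


class TestScanTfbs:
    def test_planted_word_found_at_offset(self):
        pwm = consensus_pwm("ACGTACGT")
        rng = np.random.default_rng(4)
        noise = "".join("AT"[i] for i in rng.integers(0, 2, size=40))
        seq = noise[:20] + "ACGTACGT" + noise[20:]
        thr = calibrate_threshold(pwm, target_fp_rate=1e-4)
        hits = scan_tfbs(seq, PWMSet((pwm,)), {pwm.matrix_id: thr})
        assert [(h[1], h[2]) for h in hits] == [(20, "+")]

    def test_reverse_strand_hit(self):
        word = "AAAACGTC"  # not its own reverse complement
        pwm = consensus_pwm(word)
        seq = "C" * 15 + reverse_complement(word) + "C" * 15
        thr = calibrate_threshold(pwm, target_fp_rate=1e-4)
        hits = scan_tfbs(seq, PWMSet((pwm,)), {pwm.matrix_id: thr})
        assert len(hits) == 1 and hits[0][2] == "-" and hits[0][1] == 15

    def test_sequence_shorter_than_matrix(self):
        pwm = consensus_pwm("ACGTACGT")
        assert scan_tfbs("ACG", PWMSet((pwm,)), {pwm.matrix_id: 0.5}) == []

    def test_background_hit_rate_bounded(self):
        pwm = consensus_pwm("ACGTAC")
        target = 1e-3
        thr = calibrate_threshold(pwm, target_fp_rate=target)
        rng = np.random.default_rng(6)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=10_000))
        hits = scan_tfbs(seq, PWMSet((pwm,)), {pwm.matrix_id: thr})
        n_positions = 2 * (len(seq) - pwm.width + 1)
        assert len(hits) <= 3 * target * n_positions


class TestFilters:
    @pytest.fixture
    def flat_expr(self, panel):
        df = pd.DataFrame(
            [[5.0] * 30, [5.0] * 30], index=["TF_A", "TF_B"], columns=panel.cell_lines
        )
        return ExpressionMatrix(df)

    def cand(self, tf="MA", subtype="Lu"):
        return TFBSCandidate("G1", tf, -1, subtype, 100.0, 1e-4)

    def test_flat_tf_retained(self, panel, flat_expr):
        out = filter_tf_expression([self.cand("MA")], flat_expr, {"MA": "TF_A"}, panel)
        assert len(out) == 1 and out[0].tf_expression_p == 1.0

    def test_differential_tf_removed(self, panel):
        rng = np.random.default_rng(7)
        vals = np.array(
            [1.0 if panel.subtype_of(cl) == "Lu" else 5.0 for cl in panel.cell_lines]
        ) + rng.normal(0, 0.2, 30)
        expr = ExpressionMatrix(
            pd.DataFrame(vals[None, :], index=["TF_A"], columns=panel.cell_lines)
        )
        assert filter_tf_expression([self.cand("MA")], expr, {"MA": "TF_A"}, panel) == []

    def test_unmappable_matrix_dropped_with_warning(self, panel, flat_expr):
        with pytest.warns(UserWarning, match="mapping"):
            out = filter_tf_expression([self.cand("MX")], flat_expr, {}, panel)
        assert out == []

    def test_empty_input(self, panel, flat_expr):
        assert filter_tf_expression([], flat_expr, {}, panel) == []


class TestSupportRate:
    def test_half_support_at_boundary(self, panel):
        bab = panel.members("BaB")
        presence = {cl: (i < 5) for i, cl in enumerate(bab)}
        assert support_rate(presence, panel, "BaB", min_rate=50.0) == 50.0

    def test_full_support(self, panel):
        presence = {cl: True for cl in panel.members("Lu")}
        assert support_rate(presence, panel, "Lu") == 100.0

    def test_below_minimum_dropped(self, panel):
        bab = panel.members("BaB")
        presence = {cl: (i < 4) for i, cl in enumerate(bab)}
        assert support_rate(presence, panel, "BaB", min_rate=50.0) is None

    def test_reduced_denominator(self, panel):
        bab = panel.members("BaB")
        presence = {cl: None for cl in bab}
        for cl in bab[:8]:
            presence[cl] = True
        for cl in bab[:8][5:]:
            presence[cl] = False
        assert support_rate(presence, panel, "BaB") == 62.5  # 5 of 8 computable

    def test_no_computable_consensus_errors(self, panel):
        presence = {cl: None for cl in panel.members("BaA")}
        with pytest.raises(UsageError):
            support_rate(presence, panel, "BaA")


class TestEndToEnd:
    def test_planted_triple_recovered_with_full_support(self, planted):
        ds, calls = planted
        out = find_blocked_tfs(
            ds.binned, calls, ds.subtypes, ds.promoter_seqs, ds.pwms,
            ds.expression, ds.tf_gene_map, seed=5,
        )
        gene, mid, bin_idx = ds.truth.planted_tf_pairs[0]
        hit = out[(out.target_gene == gene) & (out.binding_tf == mid)]
        assert not hit.empty
        assert (hit["support_rate"] == 100.0).all()
        assert bin_idx in set(hit["bin"])

    def test_filter_composition_order_invariant(self, planted):
        ds, calls = planted
        # support-rate filtering and expression filtering act on disjoint
        # candidate fields, so their order cannot matter
        cands = [
            TFBSCandidate("G0001", "MSIM001", -1, "Lu", rate, 1e-5)
            for rate in (40.0, 60.0, 100.0)
        ]
        by_support = [c for c in cands if c.support_rate >= 50.0]
        a = filter_tf_expression(by_support, ds.expression, ds.tf_gene_map, ds.subtypes)
        b = [
            c for c in filter_tf_expression(cands, ds.expression, ds.tf_gene_map, ds.subtypes)
            if c.support_rate >= 50.0
        ]
        assert [(c.target_gene, c.tf_matrix_id, c.support_rate) for c in a] == [
            (c.target_gene, c.tf_matrix_id, c.support_rate) for c in b
        ]

    def test_no_planted_motifs_candidates_within_calibration_bound(self, planted):
        """Background hits are bounded by the calibrated false-positive
        expectation (3x slack over rate x scanned positions x matrices)."""
        ds, calls = planted
        rng = np.random.default_rng(99)
        decoy = PWMSet(
            (consensus_pwm("".join("ACGT"[i] for i in rng.integers(0, 4, 8))),)
        )
        decoy_map = {decoy.ids[0]: list(ds.tf_gene_map.values())[0]}
        target = 1e-4
        out = find_blocked_tfs(
            ds.binned, calls, ds.subtypes, ds.promoter_seqs, decoy,
            ds.expression, ds.tf_gene_map | decoy_map, seed=5,
            target_fp_rate=target,
        )
        n_hyper = len(hyper_bins(ds.binned, calls, ds.subtypes))
        window = 100 + 2 * 10  # bin plus flanks
        scanned = n_hyper * 2 * (window - 8 + 1)
        assert len(out) <= max(1.0, 3 * target * scanned * len(decoy))
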