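"""NG86 Ka/Ks against an exact enumeration oracle, dating, LRT, dup modes."""

import math

import numpy as np
import pytest

from hypmine.evolution import (
    AlignedCdsPair,
    KaKsError,
    classify_duplication,
    divergence_time,
    duplication_mode_counts,
    ks_histogram,
    lrt,
    ng_kaks,
)
from hypmine.fixtures import generate_cds_pair
from hypmine.seqio import GenePosition

from oracles import oracle_ng_kaks, random_codon_pair


class TestNgKaks:
    def test_identical_sequences(self):
        res = ng_kaks(AlignedCdsPair("a", "b", "ATGGCT", "ATGGCT"))
        assert res.Ka == 0.0 and res.Ks == 0.0
        assert res.omega is None and res.status == "undefined_omega"

    def test_hand_derived_synonymous_pair(self):
        res = ng_kaks(AlignedCdsPair("a", "b", "AAAAAAGGA", "AAAAAAGGG"))
        assert res.S == pytest.approx(5 / 3, abs=1e-12)
        assert res.N == pytest.approx(22 / 3, abs=1e-12)
        assert (res.Sd, res.Nd) == (1.0, 0.0)
        assert res.Ks == pytest.approx(-0.75 * math.log(0.2), abs=1e-12)
        assert res.Ka == 0.0

    def test_hand_derived_nonsynonymous_pair(self):
        res = ng_kaks(AlignedCdsPair("a", "b", "AAAAAA", "AAAGAA"))
        assert (res.Sd, res.Nd) == (0.0, 1.0)
        assert res.Nd / res.N == pytest.approx(3 / 16, abs=1e-12)
        assert res.Ka == pytest.approx(-0.75 * math.log(0.75), abs=1e-12)
        assert res.Ks == 0.0

    def test_symmetry(self, rng):
        for _ in range(25):
            a, b = random_codon_pair(rng)
            fwd = ng_kaks(AlignedCdsPair("x", "y", a, b))
            rev = ng_kaks(AlignedCdsPair("y", "x", b, a))
            assert (fwd.S, fwd.N, fwd.Sd, fwd.Nd) == (rev.S, rev.N, rev.Sd, rev.Nd)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(200):
            a, b = random_codon_pair(rng)
            res = ng_kaks(AlignedCdsPair("x", "y", a, b))
            expected = oracle_ng_kaks(a, b)
            for key in ("S", "N", "Sd", "Nd"):
                assert getattr(res, key) == pytest.approx(
                    expected[key], abs=1e-10
                ), (key, a, b)
            for key in ("Ka", "Ks"):
                got = getattr(res, key)
                if expected[key] is None:
                    assert got is None
                    assert res.status in ("saturated", "undefined")
                else:
                    assert got == pytest.approx(expected[key], abs=1e-10)

    def test_gap_columns_are_dropped(self):
        gapped = ng_kaks(AlignedCdsPair("a", "b", "AAA---GGA", "AAACCCGGG"))
        plain = ng_kaks(AlignedCdsPair("a", "b", "AAAGGA", "AAAGGG"))
        assert (gapped.S, gapped.Sd) == (plain.S, plain.Sd)

    def test_all_gap_pair_is_error(self):
        with pytest.raises(KaKsError, match="no gap-free"):
            ng_kaks(AlignedCdsPair("a", "b", "---", "---"))

    def test_internal_stop_is_error(self):
        with pytest.raises(KaKsError, match="stop"):
            ng_kaks(AlignedCdsPair("a", "b", "TAAAAA", "TAAAAA"))

    def test_planted_synonymous_edits_give_zero_ka(self):
        pair, _ = generate_cds_pair(100, n_syn=3, n_nonsyn=0, seed=5)
        res = ng_kaks(pair)
        assert res.Ka == 0.0 and res.Ks > 0.0

    def test_planted_nonsynonymous_edits_give_zero_ks(self):
        pair, _ = generate_cds_pair(100, n_syn=0, n_nonsyn=3, seed=5)
        res = ng_kaks(pair)
        assert res.Ks == 0.0 and res.Ka > 0.0


class TestDivergenceTime:
    def test_zero_ks(self):
        res = divergence_time(0.0)
        assert res.T == 0.0 and not res.in_recent_wgd_window

    def test_printed_inputs(self):
        res = divergence_time(0.4871, 9.1e-9)
        assert res.T == pytest.approx(0.4871 / (2 * 9.1e-9), rel=0)
        assert res.T == pytest.approx(2.6764e7, rel=1e-4)
        assert not res.in_recent_wgd_window

    @pytest.mark.parametrize(
        "ks, flagged",
        [(0.149, False), (0.15, True), (0.2, True), (0.3, True), (0.301, False)],
    )
    def test_wgd_window_is_closed(self, ks, flagged):
        assert divergence_time(ks).in_recent_wgd_window is flagged

    def test_linear_in_ks_and_inverse_in_lambda(self):
        base = divergence_time(0.1, 1e-8).T
        assert divergence_time(0.2, 1e-8).T == pytest.approx(2 * base)
        assert divergence_time(0.1, 2e-8).T == pytest.approx(base / 2)

    def test_bad_lambda_is_error(self):
        with pytest.raises(ValueError):
            divergence_time(0.1, 0.0)


class TestKsHistogram:
    def test_basic_binning(self):
        counts, dropped = ks_histogram([0.05, 0.16, 0.29], bin_width=0.1)
        assert counts == {0: 1, 1: 1, 2: 1} and dropped == 0

    def test_empty(self):
        assert ks_histogram([]) == ({}, 0)

    def test_edge_values_fall_in_upper_bin(self):
        counts, _ = ks_histogram([0.1], bin_width=0.1)
        assert counts == {1: 1}

    def test_undefined_values_counted_separately(self):
        counts, dropped = ks_histogram([0.05, None, float("nan")], bin_width=0.1)
        assert sum(counts.values()) == 1 and dropped == 2


class TestLrt:
    def test_equal_likelihoods(self):
        res = lrt(-100.0, -100.0)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_closed_form_df2(self):
        res = lrt(-100.0, -95.0, df=2)
        assert res.statistic == 10.0
        assert res.p_value == pytest.approx(math.exp(-5.0), abs=1e-12)

    def test_absolute_value_makes_order_irrelevant(self):
        assert lrt(-95.0, -100.0).statistic == 10.0

    def test_df1_zero_statistic(self):
        assert lrt(-7.0, -7.0, df=1).p_value == 1.0


def _toy_positions():
    # chr1: g0..g5 in rank order; chr2: h0..h5
    positions = []
    for chrom, prefix in (("chr1", "g"), ("chr2", "h")):
        for i in range(6):
            positions.append(
                GenePosition(f"{prefix}{i}", chrom, 1000 * i + 1, 1000 * i + 500, i)
            )
    return positions


class TestClassifyDuplication:
    def test_toy_genome_modes(self):
        positions = _toy_positions()
        homologs = [
            ("g0", "g1"),   # adjacent -> tandem
            ("g2", "g5"),   # rank gap 3 -> proximal
            ("h0", "g3"),   # cross-chromosome -> dispersed
            ("h1", "h2"),   # collinear pair below
        ]
        collinear = [("h1", "h2")]
        labels = classify_duplication(positions, homologs, collinear)
        assert labels["g0"].mode == labels["g1"].mode == "tandem"
        assert labels["g2"].mode == labels["g5"].mode == "proximal"
        assert labels["h0"].mode == labels["g3"].mode == "dispersed"
        assert labels["h1"].mode == labels["h2"].mode == "wgd_segmental"
        assert labels["g4"].mode == labels["h3"].mode == "singleton"
        assert len(labels) == 12

    def test_collinearity_outranks_adjacency(self):
        positions = _toy_positions()
        labels = classify_duplication(
            positions, [("g0", "g1")], [("g0", "g1")]
        )
        assert labels["g0"].mode == "wgd_segmental"

    def test_labels_partition_gene_set(self):
        positions = _toy_positions()
        labels = classify_duplication(positions, [("g0", "g4"), ("h0", "h5")])
        counts = duplication_mode_counts(labels)
        assert sum(counts.values()) == len(positions)

    def test_proximal_count_monotone_in_rank_gap(self):
        positions = _toy_positions()
        homologs = [("g0", "g2"), ("g1", "g5"), ("h0", "h3")]
        previous = -1
        for gap in (1, 2, 3, 4, 5):
            labels = classify_duplication(
                positions, homologs, proximal_max_rank_gap=gap
            )
            count = duplication_mode_counts(labels)["proximal"]
            assert count >= previous
            previous = count

    def test_unknown_gene_is_named_in_error(self):
        with pytest.raises(KeyError, match="ghost"):
            classify_duplication(_toy_positions(), [("g0", "ghost")])
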