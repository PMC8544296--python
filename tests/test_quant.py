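"""Read filtering, P-site assignment, region/frame stats, RPKM and TE."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riboshift.annotation import TranscriptIndex, TranscriptModel, region_of
from riboshift.quant import (
    Alignment,
    NoUsableReadsError,
    filter_reads,
    frame_distribution,
    gene_quant,
    length_histogram,
    psite,
    region_counts,
    region_distribution,
    rpkm,
    translation_efficiency,
)


def aln_frame(rows):
    return pd.DataFrame(rows, columns=["transcript_id", "start", "read_length"])


@pytest.fixture()
def one_tx():
    return TranscriptIndex([TranscriptModel("t1", "g1", 300, 60, 240)])


class TestFilterReads:
    def test_threshold_is_inclusive_at_20(self):
        df = aln_frame([("t1", 0, 19), ("t1", 0, 20), ("t1", 0, 21)])
        assert filter_reads(df)["read_length"].tolist() == [20, 21]

    def test_empty_input(self):
        assert len(filter_reads(aln_frame([]))) == 0

    @given(st.lists(st.integers(15, 40), max_size=1000))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_multiset(self, lengths):
        df = aln_frame([("t1", 0, ln) for ln in lengths])
        expected = [ln for ln in lengths if ln >= 20]
        assert filter_reads(df)["read_length"].tolist() == expected


class TestPsite:
    def test_additive_definition(self):
        assert psite(Alignment("t1", 100, 30), {30: 12}) == 112

    def test_default_offset_applies_to_unlisted_length(self):
        assert psite(Alignment("t1", 0, 31), {30: 12, 29: 12, 31: 13}) == 13
        assert psite(Alignment("t1", 5, 27), {30: 12}) == 17

    def test_region_of_psite_matches_per_base_oracle(self, small_sim, small_txindex, rng):
        from riboshift.quant import assign_psites

        m = small_sim.models[0]
        starts = rng.integers(0, m.length - 45, 300)
        df = aln_frame([(m.transcript_id, int(s), 30) for s in starts])
        ps = assign_psites(df, small_txindex)
        names = np.array(["utr5", "cds", "utr3"])
        for s, (_, row) in zip(starts, ps.iterrows()):
            assert names[row["region"]] == region_of(m, int(s) + 12)

    def test_psite_beyond_transcript_excluded(self, one_tx):
        from riboshift.quant import assign_psites

        df = aln_frame([("t1", 295, 30), ("t1", 0, 30)])  # first P-site = 307 > 300
        ps = assign_psites(df, one_tx)
        assert len(ps) == 1 and ps["psite"].iloc[0] == 12


class TestRegionDistribution:
    def test_all_cds(self, one_tx):
        df = aln_frame([("t1", 100, 30)] * 5)
        assert region_distribution(df, one_tx) == {"utr5": 0.0, "cds": 100.0, "utr3": 0.0}

    def test_two_reads_split_utr5_utr3(self, one_tx):
        df = aln_frame([("t1", 10, 30), ("t1", 250, 30)])  # P-sites 22, 262
        d = region_distribution(df, one_tx)
        assert d == {"utr5": 50.0, "cds": 0.0, "utr3": 50.0}

    def test_zero_usable_reads_is_explicit_error(self, one_tx):
        with pytest.raises(NoUsableReadsError):
            region_distribution(aln_frame([]), one_tx)

    def test_percentages_sum_to_100(self, small_sim, small_txindex):
        reads = small_sim.alignments[("control_rep1", "rpf")]
        d = region_distribution(reads, small_txindex)
        assert sum(d.values()) == pytest.approx(100.0, abs=1e-9)

    def test_simulated_mixture_recovered(self):
        from riboshift.simulate import SimConfig, simulate

        cfg = SimConfig(
            n_genes=100, reads_per_library=100_000, seed=7,
            conditions=("control",), n_replicates=1,
            uorf_fraction=0, uorf_shift_fraction=0,
            te_up_fraction=0, te_down_fraction=0,
            rna_up_fraction=0, rna_down_fraction=0,
            base_utr5_occupancy=0.07, base_utr3_occupancy=0.03,
        )
        sim = simulate(cfg)
        txs = TranscriptIndex(sim.models)
        d = region_distribution(sim.alignments[("control_rep1", "rpf")], txs)
        assert d["utr5"] == pytest.approx(7.0, abs=0.5)
        assert d["cds"] == pytest.approx(90.0, abs=0.5)
        assert d["utr3"] == pytest.approx(3.0, abs=0.5)


class TestFrameDistribution:
    def test_all_frame0(self, one_tx):
        df = aln_frame([("t1", 60 - 12 + 3 * k, 30) for k in range(10)])
        assert frame_distribution(df, one_tx) == {0: 100.0, 1: 0.0, 2: 0.0}

    def test_single_read_frame1(self, one_tx):
        df = aln_frame([("t1", 60 - 12 + 4, 30)])
        assert frame_distribution(df, one_tx) == {0: 0.0, 1: 100.0, 2: 0.0}

    def test_invariant_to_shifting_psites_by_3(self, one_tx, rng):
        starts = 60 - 12 + 3 * rng.integers(0, 50, 200) + rng.integers(0, 3, 200)
        df = aln_frame([("t1", int(s), 30) for s in starts])
        shifted = aln_frame([("t1", int(s) + 3, 30) for s in starts])
        assert frame_distribution(df, one_tx) == frame_distribution(shifted, one_tx)

    def test_no_cds_psites_is_explicit_error(self, one_tx):
        df = aln_frame([("t1", 0, 30)])  # P-site 12 -> 5'UTR
        with pytest.raises(NoUsableReadsError):
            frame_distribution(df, one_tx)


class TestLengthHistogram:
    def test_exact_multiset(self):
        df = aln_frame([("t", 0, 30), ("t", 0, 30), ("t", 0, 28)])
        assert length_histogram(df) == {28: 1, 30: 2}

    def test_empty(self):
        assert length_histogram(aln_frame([])) == {}

    def test_simulator_modal_length(self, small_sim):
        hist = length_histogram(small_sim.alignments[("control_rep1", "rpf")])
        assert max(hist, key=hist.get) == 30


class TestRpkm:
    def test_definition(self):
        assert rpkm(10, 1000, 1_000_000) == pytest.approx(10.0)
        assert rpkm(0, 500, 10_000) == 0.0

    @given(
        st.integers(0, 10**6),
        st.integers(1, 10**5),
        st.integers(1, 10**9),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_formula_oracle(self, count, length, lib):
        expected = count / (length / 1000.0) / (lib / 1e6)
        assert rpkm(count, length, lib) == pytest.approx(expected, rel=1e-12)

    @given(st.integers(1, 1000), st.integers(1, 10**4), st.integers(1, 10**7))
    @settings(max_examples=50, deadline=None)
    def test_linear_in_count_inverse_in_libsize(self, count, length, lib):
        assert rpkm(2 * count, length, lib) == pytest.approx(2 * rpkm(count, length, lib))
        assert rpkm(count, length, 2 * lib) == pytest.approx(rpkm(count, length, lib) / 2)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            rpkm(1, 0, 100)
        with pytest.raises(ValueError):
            rpkm(1, 100, 0)


class TestTranslationEfficiency:
    def test_ratio(self):
        assert translation_efficiency(20, 10, floor=1.0) == pytest.approx(2.0)

    def test_below_floor_is_undefined_not_error(self):
        assert np.isnan(translation_efficiency(5, 0, floor=1.0))
        assert np.isnan(translation_efficiency(5, 0.5, floor=1.0))


class TestGeneQuant:
    def test_region_counts_cover_all_transcripts(self, small_sim, small_txindex):
        rc = region_counts(small_sim.alignments[("control_rep1", "rpf")], small_txindex)
        assert len(rc) == len(small_txindex)
        assert (rc[["n_utr5", "n_cds", "n_utr3"]].to_numpy() >= 0).all()


def test_gene_quant_sample_mismatch_rejected(small_sim):
    from conftest import split_libraries

    rpf, rna = split_libraries(small_sim)
    rna = dict(list(rna.items())[:-1])
    with pytest.raises(ValueError, match="same samples"):
        gene_quant(small_sim.models, rpf, rna)


def test_gene_quant_te_recovery_on_small_sim(small_sim):
    """Estimated control TE tracks the generating effective TE."""
    from scipy.stats import spearmanr

    from conftest import split_libraries

    rpf, rna = split_libraries(small_sim)
    gq = gene_quant(small_sim.models, rpf, rna)
    ctrl = (
        gq[gq["sample_id"].str.startswith("control")]
        .groupby("gene_id")["te"].mean().dropna()
    )
    truth = small_sim.truth.set_index("gene_id").loc[ctrl.index, "te_eff_control"]
    assert spearmanr(truth, ctrl).statistic > 0.85
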