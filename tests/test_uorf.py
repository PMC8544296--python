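"""uORF detection, Kozak scoring, cap distance, shift scores."""

import re

import numpy as np
import pandas as pd
import pytest

from riboshift.annotation import TranscriptModel
from riboshift.uorf import (
    cap_distance,
    find_uorfs,
    kozak_score,
    shift_score,
    shift_table,
)

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_uorfs(seq, cds_start):
    """Independent scanner: test every position and every frame separately."""
    seq = seq.upper().replace("U", "T")
    found = []
    for pos in range(cds_start):
        if seq[pos : pos + 3] != "ATG":
            continue
        stop = None
        i = pos + 3
        while i + 3 <= len(seq):
            if seq[i : i + 3] in STOPS:
                stop = i + 3
                break
            i += 3
        found.append((pos, stop, stop is None or stop > cds_start))
    return found


def make_tx(seq, cds_start, cds_end=None):
    cds_end = len(seq) if cds_end is None else cds_end
    return TranscriptModel("t1", "g1", len(seq), cds_start, cds_end, sequence=seq)


class TestFindUorfs:
    def test_hand_checked_12mer(self):
        # 5'UTR CCAUGGCUUAAC then CDS: uAUG at 2, in-frame UAA at 8..10
        tx = make_tx("CCAUGGCUUAAC" + "AUGGCCUAA", cds_start=12)
        (u,) = find_uorfs(tx)
        assert u.uaug_pos == 2
        assert u.stop_pos == 11
        assert not u.overlaps_cds
        assert u.length == 9

    def test_no_aug_in_utr5(self):
        tx = make_tx("CCCCCCCCC" + "ATGTAA", cds_start=9)
        assert find_uorfs(tx) == []

    def test_uorf_overlapping_cds_flagged(self):
        # uAUG at 0, first in-frame stop lies inside the CDS
        seq = "ATGCCACCA" + "ATGTTTTAA"
        tx = make_tx(seq, cds_start=9)
        (u,) = find_uorfs(tx)
        assert u.uaug_pos == 0
        assert u.stop_pos == 18
        assert u.overlaps_cds

    def test_uorf_without_any_stop_gets_sentinel(self):
        seq = "ATGCCCCCC" + "CCCCCCCCC"
        tx = make_tx(seq, cds_start=9)
        (u,) = find_uorfs(tx)
        assert u.stop_pos is None
        assert u.length is None
        assert u.overlaps_cds

    def test_identical_under_u_t_substitution(self):
        seq_t = "CCATGGCTTAAC" + "ATGGCCTAA"
        seq_u = seq_t.replace("T", "U")
        a = find_uorfs(make_tx(seq_t, 12))
        b = find_uorfs(make_tx(seq_u, 12))
        assert [(x.uaug_pos, x.stop_pos, x.kozak) for x in a] == [
            (x.uaug_pos, x.stop_pos, x.kozak) for x in b
        ]

    def test_output_sorted_by_position(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(50):
            n = int(rng.integers(40, 200))
            seq = "".join(rng.choice(bases, n))
            cds_start = int(rng.integers(10, n - 9))
            pos = [u.uaug_pos for u in find_uorfs(make_tx(seq, cds_start))]
            assert pos == sorted(pos)

    def test_matches_brute_force_on_random_sequences(self, rng):
        """Every-position scanner oracle on random transcripts."""
        bases = np.array(list("ACGT"))
        for _ in range(300):
            n = int(rng.integers(30, 300))
            seq = "".join(rng.choice(bases, n))
            cds_start = int(rng.integers(1, n))
            got = [
                (u.uaug_pos, u.stop_pos, u.overlaps_cds)
                for u in find_uorfs(make_tx(seq, cds_start, cds_end=None))
            ]
            assert got == brute_force_uorfs(seq, cds_start)

    def test_non_acgt_characters_warn(self):
        seq = "NNATGNN" + "CC" + "ATGTAA"
        with pytest.warns(UserWarning, match="non-ACGT"):
            find_uorfs(make_tx(seq, cds_start=9))


class TestKozak:
    def test_canonical_strong_context(self):
        assert kozak_score("GCCACCAUGG", 6) == "strong"

    def test_weak_context(self):
        assert kozak_score("UUUUUUAUGC", 6) == "weak"

    @pytest.mark.parametrize("minus3", list("ACGT"))
    @pytest.mark.parametrize("plus4", list("ACGT"))
    def test_exhaustive_truth_table(self, minus3, plus4):
        seq = f"CC{minus3}CCATG{plus4}CC"
        expected = {
            (True, True): "strong",
            (True, False): "adequate",
            (False, True): "adequate",
            (False, False): "weak",
        }[(minus3 in "AG", plus4 == "G")]
        assert kozak_score(seq, 5) == expected

    def test_missing_flank_counts_as_unsatisfied(self):
        assert kozak_score("ATGG", 0) == "adequate"  # no -3, +4 = G
        assert kozak_score("ATGC", 0) == "weak"
        assert kozak_score("AATG", 1) == "weak"  # no +4 base at all


class TestCapDistance:
    def test_equals_uaug_position(self):
        tx = make_tx("CCATGTAACC" + "ATGTAA", cds_start=10)
        (u,) = find_uorfs(tx)
        assert cap_distance(u) == 2 == u.uaug_pos

    def test_matches_independent_string_search(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(50):
            seq = "".join(rng.choice(bases, 120))
            uorfs = find_uorfs(make_tx(seq, cds_start=100))
            first = seq[:102].find("ATG")  # str.find as the independent search
            if uorfs:
                assert uorfs[0].cap_distance == first
            else:
                assert first == -1 or first >= 100

    def test_uaug_at_cap(self):
        tx = make_tx("ATGTAACCCC" + "ATGTAA", cds_start=10)
        assert find_uorfs(tx)[0].cap_distance == 0


class TestShiftScore:
    def test_stated_arithmetic(self):
        s = shift_score(
            {"transcript_id": "t", "n_utr5": 20, "n_cds": 20},
            {"transcript_id": "t", "n_utr5": 5, "n_cds": 80},
            pseudocount=1,
        )
        assert s.ratio_ctrl == pytest.approx(1.0)
        assert s.ratio_treat == pytest.approx(13.5)
        assert s.log2_shift == pytest.approx(np.log2(13.5), abs=1e-12)

    def test_identical_counts_zero_shift(self):
        c = {"transcript_id": "t", "n_utr5": 7, "n_cds": 30}
        assert shift_score(c, c).log2_shift == 0.0

    def test_antisymmetric_under_condition_swap(self, rng):
        for _ in range(20):
            a = {"transcript_id": "t", "n_utr5": int(rng.integers(0, 50)),
                 "n_cds": int(rng.integers(0, 500))}
            b = {"transcript_id": "t", "n_utr5": int(rng.integers(0, 50)),
                 "n_cds": int(rng.integers(0, 500))}
            assert shift_score(a, b).log2_shift == pytest.approx(
                -shift_score(b, a).log2_shift, abs=1e-12
            )

    def test_table_skips_transcripts_missing_in_one_condition(self):
        ctrl = pd.DataFrame({"transcript_id": ["t1", "t2"],
                             "n_utr5": [5, 5], "n_cds": [10, 10], "n_utr3": [0, 0]})
        treat = pd.DataFrame({"transcript_id": ["t1"],
                              "n_utr5": [1], "n_cds": [20], "n_utr3": [0]})
        with pytest.warns(UserWarning, match="skipped"):
            out = shift_table(ctrl, treat)
        assert out["transcript_id"].tolist() == ["t1"]


def test_strong_kozak_uorfs_repress_te_more_than_weak(small_sim):
    """The simulator's Kozak-dependent repression survives the estimator."""
    from conftest import split_libraries
    from riboshift.quant import gene_quant

    rpf, rna = split_libraries(small_sim)
    gq = gene_quant(small_sim.models, rpf, rna)
    ctrl = (
        gq[gq["sample_id"].str.startswith("control")]
        .groupby("gene_id")["te"].mean()
    )
    truth = small_sim.truth.set_index("gene_id")
    strong = ctrl[truth["has_uorf"] & (truth["kozak"] == "strong")].dropna()
    weak = ctrl[truth["has_uorf"] & (truth["kozak"] == "weak")].dropna()
    assert np.median(strong) < np.median(weak)
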