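"""Point-mutant discovery and variant stratification."""

import numpy as np
import pandas as pd
import pytest

from ssrobust.mutation_variant import (MutationPair, SSUnit, align_pair,
                                       call_mutations, classify_ss_change,
                                       consensus_ss_prediction,
                                       ddg_compare, dedupe_mutations,
                                       dedupe_sequences, distance_to_unit_end,
                                       find_similar_pairs, map_variant_rsa,
                                       pathogenic_fraction_table,
                                       pp2_bin_label, read_variant_table,
                                       rsa_bin_label, scan_mutants,
                                       segment_ss_units)
from ssrobust.stats import wilson_ci


BASE = ("MKVLITGAGSGIGLELARQFAKEGAKVILVGRRKEVLDEAAASLPGAIATPL"
        "DVTDEAAVEALFAKIEALGGLDILVNNAGIMPNSPLAEMTDEQWDRVIAVNL")  # 104 aa


def _mutate(seq, pos, aa):
    assert seq[pos] != aa
    return seq[:pos] + aa + seq[pos + 1:]


class TestSegmentation:
    def test_units(self):
        units = segment_ss_units("HHHECC")
        assert units == [SSUnit("H", 0, 2), SSUnit("E", 3, 3), SSUnit("C", 4, 5)]

    def test_distance_to_unit_end(self):
        units = segment_ss_units("HHHHHCC")
        assert distance_to_unit_end(0, units) == 0
        assert distance_to_unit_end(2, units) == 2
        assert distance_to_unit_end(4, units) == 0
        assert distance_to_unit_end(5, units) is None   # coil

    def test_uncovered_index_raises(self):
        with pytest.raises(IndexError):
            distance_to_unit_end(10, segment_ss_units("HH"))


class TestDedupeSequences:
    def test_exact_and_case_duplicates_collapse(self):
        seqs = {"b": "ACDE", "a": "acde", "c": "ACDF"}
        out = dedupe_sequences(seqs)
        assert out == {"b": "ACDE", "c": "ACDF"}


class TestAlignPair:
    def test_identity_exact_for_substitution_only(self):
        s2 = _mutate(BASE, 40, "W")
        identity, cols = align_pair(BASE, s2)
        assert identity == pytest.approx(1 - 1 / len(BASE))
        assert all(c1 == c2 for c1, c2 in cols)

    def test_terminal_extension_counts_as_gap_columns(self):
        identity, cols = align_pair("ACDE", "ACDEFG")
        assert (None, 4) in cols and (None, 5) in cols
        assert identity == 1.0   # over aligned columns only


class TestFindSimilarPairs:
    def test_one_mismatch_found(self):
        seqs = {"a": BASE, "b": _mutate(BASE, 50, "W")}
        pairs = find_similar_pairs(seqs)
        assert len(pairs) == 1
        a, b, identity = pairs[0]
        assert {a, b} == {"a", "b"}
        assert identity >= 0.98

    def test_three_mismatches_over_104_rejected(self):
        # 101/104 = 0.971 < 0.98
        s2 = _mutate(_mutate(_mutate(BASE, 10, "W"), 40, "W"), 80, "W")
        assert find_similar_pairs({"a": BASE, "b": s2}) == []

    def test_short_sequences_excluded(self):
        s = BASE[:60]
        assert find_similar_pairs({"a": s, "b": _mutate(s, 30, "W")},
                                  min_len=64) == []

    def test_identical_pair_excluded(self):
        assert find_similar_pairs({"a": BASE, "b": BASE}) == []


class TestCallMutations:
    def test_single_substitution(self):
        s2 = _mutate(BASE, 40, "W")
        muts = call_mutations("a", "b", BASE, s2)
        assert len(muts) == 1
        m = muts[0]
        assert (m.pos1, m.pos2, m.wt_aa, m.mut_aa) == (40, 40, BASE[40], "W")

    def test_close_pair_dropped(self):
        s2 = _mutate(_mutate(BASE, 40, "W"), 45, "Y")   # 5 < 10 apart
        assert call_mutations("a", "b", BASE, s2) == []

    def test_spaced_pair_kept(self):
        s2 = _mutate(_mutate(BASE, 40, "W"), 55, "Y")   # 15 >= 10 apart
        muts = call_mutations("a", "b", BASE, s2)
        assert sorted(m.pos1 for m in muts) == [40, 55]

    def test_spacing_exactly_ten_kept(self):
        s2 = _mutate(_mutate(BASE, 40, "W"), 50, "Y")
        muts = call_mutations("a", "b", BASE, s2)
        assert sorted(m.pos1 for m in muts) == [40, 50]

    def test_indel_adjacent_substitution_skipped(self):
        # explicit columns: sub at column 1 adjacent to a gap column
        cols = [(0, 0), (1, 1), (None, 2), (2, 3)]
        muts = call_mutations("a", "b", "AWD", "AYXD", columns=cols,
                              min_spacing=10)
        assert muts == []


class TestDedupeMutations:
    def test_same_mutation_in_homology_group_counted_once(self):
        s_mut = _mutate(BASE, 40, "W")
        seqs = {"a": BASE, "b": s_mut, "c": s_mut + ""}
        # c identical to b collapses earlier in scan; construct explicitly:
        seqs = {"a": BASE, "b": s_mut, "d": _mutate(BASE, 70, "Y")}
        pairs = [("a", "b"), ("a", "d"), ("b", "d")]
        muts = (call_mutations("a", "b", BASE, s_mut)
                + call_mutations("a", "d", BASE, seqs["d"])
                + call_mutations("b", "d", s_mut, seqs["d"]))
        # b/d differ at 40 (W->orig) and 70 (orig->Y): the reverse of 40
        # is a different substitution; the 70 mutation duplicates a/d's
        deduped = dedupe_mutations(muts, pairs, seqs)
        keys = {(m.wt_aa, m.mut_aa, m.pos1 if m.id1 == "a" else None)
                for m in deduped}
        by_key = {}
        for m in deduped:
            by_key.setdefault((m.wt_aa, m.mut_aa), []).append(m)
        # the orig->Y mutation at 70 appears once despite two observations
        assert len(by_key[(BASE[70], "Y")]) == 1

    def test_order_invariance(self):
        s2 = _mutate(BASE, 40, "W")
        s3 = _mutate(BASE, 70, "Y")
        seqs = {"a": BASE, "b": s2, "c": s3}
        pairs = [("a", "b"), ("a", "c"), ("b", "c")]
        muts = (call_mutations("a", "b", BASE, s2)
                + call_mutations("a", "c", BASE, s3)
                + call_mutations("b", "c", s2, s3))
        d1 = dedupe_mutations(muts, pairs, seqs)
        d2 = dedupe_mutations(list(reversed(muts)), list(reversed(pairs)), seqs)
        key = lambda m: (m.id1, m.id2, m.pos1, m.wt_aa, m.mut_aa)
        assert [key(m) for m in d1] == [key(m) for m in d2]


class TestScanMutants:
    def test_end_to_end_small(self):
        seqs = {"a": BASE, "b": _mutate(BASE, 40, "W"),
                "dup": BASE.lower(), "short": BASE[:50]}
        muts = scan_mutants(seqs)
        assert len(muts) == 1
        assert (muts[0].pos1, muts[0].mut_aa) == (40, "W")


class TestClassify:
    class _Ann:
        def __init__(self, ss3, rsa):
            self.ss3, self.rsa = ss3, rsa

    def test_fills_fields(self):
        ann1 = [self._Ann(s, 0.1 * i) for i, s in enumerate("HHHHH")]
        ann2 = [self._Ann(s, 0.5) for s in "HHCHH"]
        mp = MutationPair("a", "b", 2, 2, "A", "W")
        out = classify_ss_change(mp, ann1, ann2)
        assert out.ss3_wt == "H" and out.ss3_mut == "C"
        assert out.changed is True
        assert out.rsa == pytest.approx(0.2)
        assert out.unit_end_distance == 2

    def test_out_of_range_returns_none(self):
        mp = MutationPair("a", "b", 9, 9, "A", "W")
        assert classify_ss_change(mp, [self._Ann("H", 0.1)],
                                  [self._Ann("H", 0.1)]) is None


class TestVariantHelpers:
    def test_map_variant_rsa_minimum(self):
        assert map_variant_rsa([0.4, None, 0.1, 0.7]) == 0.1
        assert map_variant_rsa([None, None]) is None

    def test_consensus_prediction(self):
        assert consensus_ss_prediction(("H", "C"), ("H", "C"), "H") == (True, True)
        assert consensus_ss_prediction(("H", "H"), ("H", "H"), "H") == (True, False)
        # disagreement on mutant -> unusable
        assert consensus_ss_prediction(("H", "C"), ("H", "E"), "H") == (False, None)
        # wrong wild type -> unusable
        assert consensus_ss_prediction(("E", "C"), ("H", "C"), "H") == (False, None)

    @pytest.mark.parametrize("pp2,label", [
        (0.0, "0-0.49"), (0.49, "0-0.49"), (0.5, "0.5-0.89"),
        (0.89, "0.5-0.89"), (0.9, "0.9-0.99"), (0.99, "0.9-0.99"),
        (0.995, "0.99-1"), (1.0, "0.99-1")])
    def test_pp2_bins(self, pp2, label):
        assert pp2_bin_label(pp2) == label

    def test_pp2_out_of_range(self):
        with pytest.raises(ValueError):
            pp2_bin_label(1.2)

    def test_rsa_bins(self):
        assert rsa_bin_label(0.0) == "[0,0.2)"
        assert rsa_bin_label(0.2) == "[0.2,0.4)"
        assert rsa_bin_label(1.0) == "[0.8,1)"
        assert rsa_bin_label(0.35, width=0.1) == "[0.3,0.4)"


class TestVariantTables:
    def _cohort(self):
        rows = []
        rng = np.random.default_rng(3)
        for i in range(400):
            change = i % 4 == 0
            pathogenic = (i % 2 == 0) if change else (i % 5 == 0)
            rows.append({"protein_id": f"p{i % 7}", "position": i,
                         "wt_aa": "A", "mut_aa": "W",
                         "label": "pathogenic" if pathogenic else "neutral",
                         "pp2": float(rng.uniform()), "rsa": float(rng.uniform()),
                         "ss_change": change, "ddg": float(rng.normal())})
        return pd.DataFrame(rows)

    def test_fraction_and_wilson_match_direct_computation(self):
        df = self._cohort()
        table = pathogenic_fraction_table(df, by=("rsa_bin",))
        for _, row in table.iterrows():
            sub = df[(df["rsa"].apply(rsa_bin_label) == row.rsa_bin)
                     & (df.ss_change == row.ss_change)]
            k = (sub.label == "pathogenic").sum()
            assert (row.n, row.n_pathogenic) == (len(sub), k)
            lo, hi = wilson_ci(k, len(sub))
            assert row.ci_lo == pytest.approx(lo)
            assert row.ci_hi == pytest.approx(hi)
        tests = table.attrs["tests"]
        assert "p_adj_bh" in tests.columns and len(tests) >= 1

    def test_read_variant_table_schema(self, tmp_path):
        path = tmp_path / "v.tsv"
        self._cohort().drop(columns=["rsa"]).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="missing required"):
            read_variant_table(path)

    def test_read_variant_table_bad_pp2(self, tmp_path):
        df = self._cohort()
        df.loc[0, "pp2"] = 1.5
        path = tmp_path / "v.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="pp2"):
            read_variant_table(path)

    def test_ddg_identical_groups_nonsignificant(self):
        df = self._cohort()
        # all-ties oracle: constant ddG in both groups -> rank-sum p = 1
        df["ddg"] = 1.0
        out = ddg_compare(df, group_col="ss_change")
        tested = out[out.get("skipped", pd.Series(True, index=out.index)) == False]  # noqa: E712
        assert len(tested) >= 1
        assert np.allclose(tested["p_value"], 1.0)

    def test_ddg_small_stratum_skipped(self):
        df = self._cohort().head(8).copy()
        df["rsa"] = [0.05] * 7 + [0.95]
        df.loc[df.index[-1], "ss_change"] = True
        df.loc[df.index[:7], "ss_change"] = [True, False, False, False,
                                             False, False, False]
        out = ddg_compare(df, group_col="ss_change")
        top = out[out.rsa_bin == "[0.8,1)"].iloc[0]
        assert "p_value" not in out.columns or np.isnan(top.get("p_value", np.nan))

    def test_ddg_requires_column(self):
        with pytest.raises(ValueError, match="ddg"):
            ddg_compare(self._cohort().drop(columns=["ddg"]))
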