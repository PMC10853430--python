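"""Composition accounting, D/R/P set algebra, and Venn partitions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from domforge.chemodiversity import (
    VennPartition,
    build_venn_from_tables,
    compare_two,
    composition,
    composition_frame,
    round_half_up,
    venn_percentages,
)

C = "compound_class"


def _ann(keys, cls="lignin_cram", grp="CHO"):
    """Annotated frame from (C,H,O,N,S) keys, one class/group for all."""
    rows = [(k[0], k[1], k[2], k[3], k[4], cls, grp) for k in keys]
    df = pd.DataFrame(rows, columns=["C", "H", "O", "N", "S", C, "element_group"])
    for col in "CHONS":
        df[col] = df[col].astype("Int64")
    return df


def _key(i, cls_idx=0):
    # distinct formulas: vary H; cls_idx shifts C to keep classes apart
    return (20 + cls_idx, 20 + 2 * i, 8, 0, 0)


class TestRounding:
    def test_half_away_from_zero(self):
        assert round_half_up(0.125, 2) == 0.13
        assert round_half_up(-0.125, 2) == -0.13
        assert round_half_up(18.134999, 2) == 18.13


class TestComposition:
    def test_direct_arithmetic(self):
        df = pd.concat(
            [
                _ann([_key(i) for i in range(5)], "lignin_cram"),
                _ann([(21, 20 + 2 * i, 18, 0, 0) for i in range(3)], "tannins"),
                _ann([(22, 40 + 2 * i, 3, 0, 0) for i in range(2)], "lipids"),
            ],
            ignore_index=True,
        )
        comp = composition(df, "s")
        assert comp.n_formulas == 10
        assert comp.class_pct["lignin_cram"] == 50.0
        assert comp.class_pct["tannins"] == 30.0
        assert comp.class_pct["lipids"] == 20.0

    def test_duplicate_formula_counted_once(self):
        df = _ann([_key(1), _key(1), _key(2)])
        assert composition(df, "s").n_formulas == 2

    def test_empty_sample_warns_and_zeroes(self, caplog):
        df = _ann([])
        with caplog.at_level("WARNING"):
            comp = composition(df, "empty")
        assert comp.n_formulas == 0
        assert all(v == 0 for v in comp.class_counts.values())
        assert "empty" in caplog.text

    def test_percentages_sum_to_100(self, rng):
        keys = [(int(c), int(h), int(o), 0, 0)
                for c, h, o in zip(rng.integers(10, 40, 200),
                                   rng.integers(10, 60, 200),
                                   rng.integers(1, 20, 200))]
        classes = rng.choice(["lignin_cram", "tannins", "lipids", "unclassified"], 200)
        groups = rng.choice(["CHO", "CHON"], 200)
        df = _ann(keys)
        df[C] = classes
        df["element_group"] = groups
        comp = composition(df, "s")
        assert sum(comp.class_pct.values()) == pytest.approx(100, abs=0.05)
        assert sum(comp.group_pct.values()) == pytest.approx(100, abs=0.05)

    def test_row_order_invariance(self, rng):
        keys = [_key(i) for i in range(30)]
        df = _ann(keys)
        shuffled = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
        assert composition(df, "s") == composition(shuffled, "s")

    def test_mixture_recovery_at_n5000(self, rng):
        """Multinomial draw at N=5000 lands within ±1.5 points per class."""
        mix = {"tannins": 18.13, "aliphatic_proteins": 2.73, "lignin_cram": 79.14}
        names = list(mix)
        draws = rng.choice(names, size=5000, p=np.array(list(mix.values())) / 100)
        keys = [(20 + names.index(d), 20 + 2 * i, 8, 0, 0) for i, d in enumerate(draws)]
        df = _ann(keys)
        df[C] = draws
        comp = composition(df, "s")
        for name, want in mix.items():
            assert comp.class_pct[name] == pytest.approx(want, abs=1.5)

    def test_composition_frame_tidy(self):
        comp = composition(_ann([_key(0)]), "s1")
        tidy = composition_frame([comp])
        assert set(tidy["kind"]) == {"compound_class", "element_group"}
        assert len(tidy) == 12  # 8 classes + 4 groups


class TestCompareTwo:
    def test_hand_enumerable(self):
        a = _ann([_key(1), _key(2), _key(3)])
        b = _ann([_key(2), _key(3), _key(4), _key(5)])
        res = compare_two(a, b)
        assert (len(res.degraded), len(res.remaining), len(res.produced)) == (1, 2, 2)
        assert res.overall_pct == {"degraded": 20.0, "remaining": 40.0, "produced": 40.0}

    def test_identity(self):
        a = _ann([_key(i) for i in range(4)])
        res = compare_two(a, a.copy())
        assert res.overall_pct == {"degraded": 0.0, "remaining": 100.0, "produced": 0.0}

    def test_per_class_all_degraded(self):
        a = pd.concat(
            [_ann([_key(i) for i in range(3)], "lignin_cram"),
             _ann([(30, 30 + 2 * i, 27, 0, 0) for i in range(4)], "tannins")],
            ignore_index=True,
        )
        b = _ann([_key(i) for i in range(3)], "lignin_cram")
        res = compare_two(a, b)
        tannins = res.per_class.set_index("name").loc["tannins"]
        assert tannins["degraded_pct"] == 100.0
        assert tannins["total"] == 4

    def test_both_empty_raises(self):
        with pytest.raises(ValueError):
            compare_two(_ann([]), _ann([]))

    @given(
        st.sets(st.integers(0, 60), max_size=30),
        st.sets(st.integers(0, 60), max_size=30),
    )
    def test_set_algebra_properties(self, ia, ib):
        if not ia and not ib:
            return
        a, b = _ann([_key(i) for i in ia]), _ann([_key(i) for i in ib])
        res = compare_two(a, b)
        # disjoint, union identity
        assert not (res.degraded & res.remaining)
        assert not (res.degraded & res.produced)
        assert not (res.remaining & res.produced)
        assert len(res.degraded | res.remaining | res.produced) == len(ia | ib)
        # block sizes tie back to the inputs
        assert len(res.degraded) + len(res.remaining) == len(ia)
        assert len(res.remaining) + len(res.produced) == len(ib)
        # percentages close
        assert sum(res.overall_pct.values()) == pytest.approx(100, abs=0.1)
        # swap symmetry
        rev = compare_two(b, a)
        assert rev.degraded == res.produced
        assert rev.produced == res.degraded
        assert rev.remaining == res.remaining


class TestVenn:
    def test_printed_genus_counts(self):
        """The published two-condition genus Venn: 56/613/97 -> 7.31/80.03/12.66."""
        assert venn_percentages(VennPartition(56, 613, 97)) == (7.31, 80.03, 12.66)

    @pytest.mark.parametrize(
        "v, expected",
        [
            (VennPartition(0, 10, 0), (0.0, 100.0, 0.0)),
            (VennPartition(1, 1, 1), (33.33, 33.33, 33.33)),
        ],
    )
    def test_simple_partitions(self, v, expected):
        assert venn_percentages(v) == expected

    def test_empty_partition_raises(self):
        with pytest.raises(ValueError):
            venn_percentages(VennPartition(0, 0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            VennPartition(-1, 2, 3)

    def test_build_from_tables(self):
        a = pd.Series({"g1": 5.0, "g2": 0.0})
        b = pd.Series({"g2": 3.0, "g3": 1.0})
        v = build_venn_from_tables(a, b)
        assert (v.only_a, v.shared, v.only_b) == (1, 0, 2)

    def test_identical_tables(self):
        a = pd.Series({"g1": 5.0, "g2": 3.0})
        v = build_venn_from_tables(a, a)
        assert (v.only_a, v.only_b) == (0, 0)
        assert v.shared == 2

    def test_threshold(self):
        a = pd.Series({"g1": 5.0, "g2": 3.0})
        b = pd.Series({"g1": 0.0, "g2": 0.0})
        v = build_venn_from_tables(a, b, presence_threshold=4.0)
        assert (v.only_a, v.shared, v.only_b) == (1, 0, 0)

    def test_duplicate_taxa_rejected(self):
        a = pd.Series([1.0, 2.0], index=["g1", "g1"])
        with pytest.raises(ValueError):
            build_venn_from_tables(a, pd.Series({"g2": 1.0}))
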