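"""Unit and property tests for base/dinucleotide counting and the RIP indices."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ripscan import (
    RipIndices,
    RipThresholds,
    composite_index,
    count_bases,
    count_dinucleotides,
    gc_content,
    is_rip_positive,
    product_index,
    region_indices,
    substrate_index,
)

from conftest import rec, revcomp

seqs = st.text(alphabet="ACGT", min_size=2, max_size=50)
seqs_with_ambiguity = st.text(alphabet="ACGTN", min_size=2, max_size=50)


def brute_force_counts(s: str):
    """Independent position-by-position scan oracle."""
    bases = {b: 0 for b in "ACGT"}
    skipped = 0
    for c in s:
        if c in bases:
            bases[c] += 1
        else:
            skipped += 1
    pairs = {}
    skipped_pairs = 0
    for i in range(len(s) - 1):
        p = s[i:i + 2]
        if p[0] in "ACGT" and p[1] in "ACGT":
            pairs[p] = pairs.get(p, 0) + 1
        else:
            skipped_pairs += 1
    return bases, skipped, pairs, skipped_pairs


class TestCounting:
    def test_base_counts_examples(self):
        b = count_bases(rec("GGCC"))
        assert (b.a, b.c, b.g, b.t, b.skipped) == (0, 2, 2, 0, 0)
        b = count_bases(rec("ACGN"))
        assert (b.a, b.c, b.g, b.t, b.skipped) == (1, 1, 1, 0, 1)

    def test_interval_out_of_range_raises(self):
        r = rec("ACGT")
        with pytest.raises(ValueError):
            count_bases(r, 0, 5)
        with pytest.raises(ValueError):
            count_dinucleotides(r, 2, 2)

    def test_dinucleotide_examples(self):
        d = count_dinucleotides(rec("ATAT"))
        assert d.apt == 2 and d.tpa == 1
        assert d.total == 3 and d.skipped_pairs == 0
        d = count_dinucleotides(rec("CANTG"))
        assert d.cpa == 1 and d.tpg == 1 and d.skipped_pairs == 2

    def test_subinterval_counting(self):
        r = rec("AACGTT")
        d = count_dinucleotides(r, 1, 4)  # "ACG"
        assert d["AC"] == 1 and d["CG"] == 1 and d.total == 2
        b = count_bases(r, 1, 4)
        assert (b.a, b.c, b.g, b.t) == (1, 1, 1, 0)

    @given(seqs_with_ambiguity)
    def test_counts_match_brute_force_oracle(self, s):
        r = rec(s)
        bases, skipped, pairs, skipped_pairs = brute_force_counts(s)
        b = count_bases(r)
        assert (b.a, b.c, b.g, b.t, b.skipped) == (
            bases["A"], bases["C"], bases["G"], bases["T"], skipped)
        d = count_dinucleotides(r)
        assert d.skipped_pairs == skipped_pairs
        for p in ("AA", "AC", "AG", "AT", "CA", "CC", "CG", "CT",
                  "GA", "GC", "GG", "GT", "TA", "TC", "TG", "TT"):
            assert d[p] == pairs.get(p, 0)

    @given(seqs_with_ambiguity)
    def test_count_bookkeeping_invariants(self, s):
        r = rec(s)
        b = count_bases(r)
        assert b.total + b.skipped == len(s)
        d = count_dinucleotides(r)
        assert d.total + d.skipped_pairs == len(s) - 1


class TestIndices:
    def test_product_index(self):
        assert product_index(count_dinucleotides(rec("TATA"))) == 2.0
        d = count_dinucleotides(rec("TAGG"))  # TpA=1, ApT=0
        assert product_index(d) is None
        d = count_dinucleotides(rec("ATGAT"))  # TpA=0, ApT=2
        assert product_index(d) == 0.0

    def test_substrate_index(self):
        d = count_dinucleotides(rec("CATG"))  # CpA=1, TpG=1, ApC=0, GpT=0
        assert substrate_index(d) is None
        d = count_dinucleotides(rec("ACGTCATG"))
        assert substrate_index(d) == (d.cpa + d.tpg) / (d.apc + d.gpt)

    @pytest.mark.parametrize(
        "p,s,expected",
        [(1.67, 0.74, 0.93), (1.0, 1.0, 0.0), (None, 0.5, None), (0.5, None, None)],
    )
    def test_composite_index(self, p, s, expected):
        got = composite_index(p, s)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected)

    def test_gc_content(self):
        assert gc_content(count_bases(rec("GGCC"))) == 1.0
        assert gc_content(count_bases(rec("GCAT"))) == 0.5
        assert gc_content(count_bases(rec("NNNN"))) is None

    @given(seqs)
    def test_composite_equals_product_minus_substrate(self, s):
        idx = region_indices(rec(s))
        if idx.product is not None and idx.substrate is not None:
            assert idx.composite == pytest.approx(idx.product - idx.substrate)
        else:
            assert idx.composite is None

    @given(seqs_with_ambiguity)
    def test_strand_symmetry(self, s):
        """All indices are identical on a sequence and its reverse complement."""
        fwd = region_indices(rec(s))
        bwd = region_indices(rec(revcomp(s)))
        for name in ("product", "substrate", "composite", "gc"):
            f, b = getattr(fwd, name), getattr(bwd, name)
            if f is None:
                assert b is None
            else:
                assert b == pytest.approx(f)

    def test_iid_sequences_have_indices_near_one(self, rng):
        """Under an i.i.d. base model both index expectations are 1 regardless of GC."""
        for gc in (0.3, 0.5, 0.7):
            p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
            s = "".join(np.array(list("ACGT"))[rng.choice(4, size=400_000, p=p)])
            idx = region_indices(rec(s))
            assert idx.product == pytest.approx(1.0, abs=0.05)
            assert idx.substrate == pytest.approx(1.0, abs=0.05)
            assert idx.gc == pytest.approx(gc, abs=0.01)


class TestClassification:
    @pytest.mark.parametrize(
        "p,s,positive",
        [
            (1.35, 0.59, True),      # clearly RIP-affected
            (0.97, 0.72, False),     # product below cut-off
            (1.35, 0.80, False),     # substrate above cut-off
            (1.1, 0.75, True),       # boundary values are inclusive
            (None, 0.1, False),      # undefined index is never positive
            (1.5, None, False),
        ],
    )
    def test_is_rip_positive_default_thresholds(self, p, s, positive):
        idx = RipIndices(product=p, substrate=s, composite=composite_index(p, s), gc=0.3)
        assert is_rip_positive(idx, RipThresholds()) is positive

    def test_composite_must_strictly_exceed_cutoff(self):
        idx = RipIndices(product=1.2, substrate=0.7, composite=0.0, gc=0.3)
        th = RipThresholds(composite_min=0.5)
        assert not is_rip_positive(idx, th)

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            RipThresholds(window=1)
        with pytest.raises(ValueError):
            RipThresholds(step=2000, window=1000)
        with pytest.raises(ValueError):
            RipThresholds(lrar_min_span=500, window=1000)
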