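"""Clone taxonomy: linkage-pattern classes, breakpoints, DSB origin.

Includes a brute-force oracle that enumerates every 0-, 1- and 2-switch
parental mosaic consistent with the informative calls and classifies from
the minimal-switch explanation — an independent re-derivation of the
parsimony rule the classifier implements directly.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gtrec.calling import MarkerCall, RepeatMeasurement
from gtrec.classify import (
    ContractViolationError,
    InputMismatchError,
    classify_clone,
    classify_records,
    infer_dsb_origin,
    summarize_repeat_distribution,
)
from gtrec.simulate import CLASSES, simulate_clone


def make_calls(locus, pattern):
    """Build MarkerCall list from a per-marker string of P/M/a/m."""
    code = {"P": "P", "M": "M", "a": "ambiguous", "m": "missing"}
    return [
        MarkerCall(mid, code[p], None, (True, True))
        for mid, p in zip(locus.marker_ids, pattern)
    ]


def make_repeat(units):
    if units is None:
        return [RepeatMeasurement("motif1", None, "missing", None)]
    matches = {84: "paternal_count", 36: "maternal_count"}.get(units, "other")
    return [RepeatMeasurement("motif1", units, matches, 0)]


class TestClassifyExamples:
    def test_all_paternal_is_pd(self, locus):
        c = classify_clone(make_calls(locus, "PPPPPPPPP"), make_repeat(84), locus)
        assert c.clone_class == "PD" and c.n_switches == 0

    def test_crossover1_pattern(self, locus):
        c = classify_clone(make_calls(locus, "PMMMMMMMM"), make_repeat(36), locus)
        assert c.clone_class == "CO_I"
        (lo, hi), = c.breakpoint_intervals
        m1 = locus.motif_position("motif1")
        assert lo <= m1 < hi

    def test_crossover2_pattern(self, locus):
        c = classify_clone(make_calls(locus, "PPPPMMMMM"), make_repeat(84), locus)
        assert c.clone_class == "CO_II"

    def test_crossover1_plus_2_pattern(self, locus):
        c = classify_clone(make_calls(locus, "PMMMMPPPP"), make_repeat(36), locus)
        assert c.clone_class == "CO_I_II"
        assert len(c.breakpoint_intervals) == 2

    def test_uniparental_offsize_tract_is_intra_allelic(self, locus):
        c = classify_clone(make_calls(locus, "MMMMMMMMM"), make_repeat(30), locus)
        assert c.clone_class == "INTRA_ALLELIC"
        assert c.excluded

    def test_uniparental_other_parent_tract_is_intra_allelic(self, locus):
        c = classify_clone(make_calls(locus, "PPPPPPPPP"), make_repeat(36), locus)
        assert c.clone_class == "INTRA_ALLELIC"

    def test_switch_in_motif_free_region_is_ambiguous(self, locus):
        # single switch between the two SNPs just downstream of motif 1
        c = classify_clone(make_calls(locus, "PPMMMMMMM"), make_repeat(84), locus)
        assert c.clone_class == "AMBIGUOUS"

    def test_switch_across_motif3_is_ambiguous(self, locus):
        c = classify_clone(make_calls(locus, "PPPPPPPMM"), make_repeat(84), locus)
        assert c.clone_class == "AMBIGUOUS"

    def test_three_switches_ambiguous(self, locus):
        c = classify_clone(make_calls(locus, "PMPMPPPPP"), make_repeat(84), locus)
        assert c.clone_class == "AMBIGUOUS"

    def test_too_many_unusable_markers_ambiguous(self, locus):
        c = classify_clone(make_calls(locus, "PammaPPPP"), make_repeat(84), locus)
        assert c.clone_class == "AMBIGUOUS"

    def test_mismatched_marker_set_rejected(self, locus):
        calls = make_calls(locus, "PPPPPPPPP")[:-1]
        with pytest.raises(InputMismatchError):
            classify_clone(calls, make_repeat(84), locus)


class TestDSBOrigin:
    @pytest.mark.parametrize(
        "units,origin,basis",
        [
            (36, "dsb_paternal", "units_equal_maternal"),
            (84, "dsb_maternal", "units_equal_paternal"),
            (60, "indeterminate", "expanded"),
            (20, "indeterminate", "contracted"),
            (None, "indeterminate", "missing"),
        ],
    )
    def test_origin_from_unit_count(self, locus, units, origin, basis):
        c = classify_clone(make_calls(locus, "PMMMMMMMM"), make_repeat(units), locus)
        assert c.clone_class == "CO_I"
        d = infer_dsb_origin(c, locus)
        assert (d.origin, d.basis) == (origin, basis)

    def test_non_co1_clone_rejected(self, locus):
        c = classify_clone(make_calls(locus, "PPPPPPPPP"), make_repeat(84), locus)
        with pytest.raises(ContractViolationError):
            infer_dsb_origin(c, locus)


class TestTruthRecovery:
    def test_error_free_simulations_recover_all_classes(self, locus, clean_params):
        rng = np.random.default_rng(9)
        for cls in CLASSES:
            for _ in range(25):
                clone, truth = simulate_clone(cls, locus, clean_params, rng)
                classifications, dsb = classify_records([clone], locus)
                c = classifications[0]
                assert c.clone_class == cls
                for gap in truth.true_breakpoints:
                    assert any(lo <= gap <= hi for lo, hi in c.breakpoint_intervals)
                if cls == "CO_I":
                    assert dsb[clone.clone_id].origin == f"dsb_{truth.dsb_parent}"

    def test_reciprocal_products_mirror(self, locus, clean_params):
        rng = np.random.default_rng(10)
        for gap in locus.crossover2_gaps():
            a, _ = simulate_clone("CO_II", locus, clean_params, rng,
                                  orientation=("P", "M"), co2_gap=gap)
            b, _ = simulate_clone("CO_II", locus, clean_params, rng,
                                  orientation=("M", "P"), co2_gap=gap)
            ca = classify_records([a], locus)[0][0]
            cb = classify_records([b], locus)[0][0]
            assert ca.clone_class == cb.clone_class == "CO_II"
            assert ca.breakpoint_intervals == cb.breakpoint_intervals

    def test_co1_ii_intervals_in_candidate_regions(self, locus, clean_params):
        rng = np.random.default_rng(11)
        m1 = locus.motif_position("motif1")
        m2 = locus.motif_position("motif2")
        m3 = locus.motif_position("motif3")
        for _ in range(40):
            clone, _ = simulate_clone("CO_I_II", locus, clean_params, rng)
            c = classify_records([clone], locus)[0][0]
            assert c.clone_class == "CO_I_II"
            iv1, iv2 = c.breakpoint_intervals
            assert iv1[0] <= m1 < iv1[1]
            assert not (iv2[0] <= m1 < iv2[1]) and not (iv2[0] <= m3 < iv2[1])
            assert iv2[0] > m1 and iv2[1] <= m3 + 1


# ---------------------------------------------------------------------------
# Brute-force minimal-switch oracle
# ---------------------------------------------------------------------------

def oracle_classify(pattern, units, locus):
    """Enumerate all 0/1/2-switch parental mosaics over the marker sequence,
    keep those consistent with the informative calls, and classify from the
    minimal-switch explanation."""
    marker_pos = [locus.element_index[m] for m in locus.marker_ids]
    informative = [(i, p) for i, p in zip(marker_pos, pattern) if p in "PM"]
    if not informative or (len(pattern) - len(informative)) > -(-len(pattern) // 3):
        return "AMBIGUOUS"

    def consistent(assign_fn):
        return all(assign_fn(i) == p for i, p in informative)

    # 0 switches
    for parent in "PM":
        if consistent(lambda i, par=parent: par):
            m1 = locus.motifs[0]
            expected = m1.paternal_units if parent == "P" else m1.maternal_units
            if units is not None and units != expected:
                return "INTRA_ALLELIC"
            return "PD" if parent == "P" else "MD"

    n_elem = len(locus.elements)
    m1 = locus.motif_position("motif1")
    m2 = locus.motif_position("motif2")
    m3 = locus.motif_position("motif3")

    def covered(a, b):
        return set(range(a + 1, b))

    # 1 switch between bounding informative markers a < b
    for (a, pa), (b, pb) in itertools.combinations(informative, 2):
        if pa == pb:
            continue
        # all informative <= a must equal pa, all >= b equal pb, none between
        left_ok = all(p == pa for i, p in informative if i <= a)
        right_ok = all(p == pb for i, p in informative if i >= b)
        between = [x for x, _ in informative if a < x < b]
        if left_ok and right_ok and not between:
            cov = covered(a, b)
            if m1 in cov and m2 not in cov and m3 not in cov:
                return "CO_I"
            if m1 not in cov and m3 not in cov and (
                m2 in cov or (m2 < a + 1 and b <= m3)
            ):
                return "CO_II"
            return "AMBIGUOUS"

    # 2 switches: flank X, middle Y, flank X
    obs = [p for _, p in informative]
    runs = [k for k, _ in itertools.groupby(obs)]
    if len(runs) == 3 and runs[0] == runs[2]:
        idxs = [i for i, _ in informative]
        vals = obs
        first_switch = next(k for k in range(1, len(vals)) if vals[k] != vals[k - 1])
        last_switch = next(
            k for k in range(len(vals) - 1, 0, -1) if vals[k] != vals[k - 1]
        )
        iv1 = (idxs[first_switch - 1], idxs[first_switch])
        iv2 = (idxs[last_switch - 1], idxs[last_switch])
        c1 = covered(*iv1)
        c2 = covered(*iv2)
        ok1 = m1 in c1 and m2 not in c1 and m3 not in c1
        ok2 = m1 not in c2 and m3 not in c2 and (
            m2 in c2 or (m2 < iv2[0] + 1 and iv2[1] <= m3)
        )
        return "CO_I_II" if ok1 and ok2 else "AMBIGUOUS"
    return "AMBIGUOUS"


class TestOracleEquivalence:
    @settings(max_examples=400, deadline=None, derandomize=True)
    @given(
        pattern=st.lists(
            st.sampled_from("PMam"), min_size=9, max_size=9
        ).map("".join),
        units=st.sampled_from([84, 36, 30, 90, None]),
    )
    def test_classifier_agrees_with_enumeration(self, locus, pattern, units):
        got = classify_clone(make_calls(locus, pattern), make_repeat(units), locus)
        assert got.clone_class == oracle_classify(pattern, units, locus)

    def test_exhaustive_informative_patterns(self, locus):
        # every fully informative call pattern over the 9 markers
        for bits in itertools.product("PM", repeat=9):
            pattern = "".join(bits)
            got = classify_clone(
                make_calls(locus, pattern), make_repeat(84), locus
            )
            assert got.clone_class == oracle_classify(pattern, 84, locus)


class TestRepeatDistribution:
    def _co1(self, clone_id, units, sample):
        from gtrec.classify import CloneClassification

        return CloneClassification(
            clone_id, "CO_I",
            motif1_measurement=RepeatMeasurement("motif1", units, "other", 0),
            n_switches=1, sample=sample,
        )

    def test_printed_count_fixture_fraction(self, locus):
        cls = (
            [self._co1(f"a{i}", 36, "mitotic") for i in range(81)]
            + [self._co1(f"b{i}", 84, "mitotic") for i in range(17)]
            + [self._co1(f"c{i}", 50 + i % 5, "mitotic") for i in range(40)]
        )
        spec = summarize_repeat_distribution(cls, locus)["mitotic"]
        assert spec.n_measured == 138
        assert round(100 * spec.frac_at_paternal, 2) == 12.32
        assert round(100 * spec.frac_at_maternal, 2) == 58.70

    def test_fractions_sum_to_one(self, locus):
        cls = [self._co1(f"x{i}", u, "s") for i, u in enumerate([36, 84, 40, 36])]
        spec = summarize_repeat_distribution(cls, locus)["s"]
        assert spec.frac_at_paternal + spec.frac_at_maternal + spec.frac_other == \
            pytest.approx(1.0)

    def test_empty_input(self, locus):
        assert summarize_repeat_distribution([], locus) == {}

    def test_all_maternal_single_bin(self, locus):
        cls = [self._co1(f"x{i}", 36, "s") for i in range(5)]
        spec = summarize_repeat_distribution(cls, locus)["s"]
        assert spec.counts == {36: 5}
        assert spec.frac_at_maternal == 1.0
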