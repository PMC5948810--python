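"""Clone taxonomy: parental, crossover I / II / I+II, intra-allelic, ambiguous.

The classifier formalizes linkage-pattern reading as minimal-switch
parsimony over the ordered informative marker calls: the clone class is
the smallest number of parental switches consistent with the non-missing,
non-ambiguous calls, and each switch is localized to the half-open
element-frame interval between the two markers that bracket it.

Candidate regions (element frame):
  * crossover I — the switch interval contains motif 1 and no other motif;
  * crossover II — the interval lies between motifs 2 and 3 (it may cover
    motif 2, whose parental tracts are identical, but not motif 1 or 3);
  * crossover I+II — two switches, same flank parent on both sides, first
    interval a crossover-I site and second a crossover-II site (a short
    exchanged segment).

A uniparental clone whose motif-1 unit count contradicts its haplotype is
an intra-allelic (PCR template-switch) artifact; it is retained in outputs
but flagged for exclusion from recombination statistics.  Anything not
fitting the taxonomy — too many switches, too many unusable markers, or a
switch in a motif-free region — is AMBIGUOUS, never guessed.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

from .calling import MarkerCall, RepeatMeasurement
from .locus import LocusReference

CLONE_CLASSES = ("PD", "MD", "CO_I", "CO_II", "CO_I_II", "INTRA_ALLELIC", "AMBIGUOUS")
HR_CLASSES = ("CO_I", "CO_II", "CO_I_II")
EXCLUDED_CLASSES = ("INTRA_ALLELIC", "AMBIGUOUS")


class InputMismatchError(ValueError):
    """Marker calls do not match the locus marker set."""


class ContractViolationError(ValueError):
    pass


@dataclass
class CloneClassification:
    clone_id: str
    clone_class: str
    breakpoint_intervals: list = field(default_factory=list)  # [(lo, hi)] element frame
    motif1_measurement: RepeatMeasurement | None = None
    n_switches: int = 0
    sample: str | None = None
    individual: str | None = None

    @property
    def excluded(self) -> bool:
        return self.clone_class in EXCLUDED_CLASSES

    @property
    def is_hr(self) -> bool:
        return self.clone_class in HR_CLASSES


@dataclass
class DSBCall:
    clone_id: str
    origin: str  # "dsb_paternal" | "dsb_maternal" | "indeterminate"
    basis: str  # "units_equal_maternal" | "units_equal_paternal" | "contracted" | "expanded" | "missing"


def interval_contains_element(iv: tuple[int, int], pos: int) -> bool:
    return iv[0] <= pos < iv[1]


def interval_contains_gap(iv: tuple[int, int], gap: int) -> bool:
    """Gap ``g`` sits between elements g-1 and g; it is inside the marker
    interval [lo, hi) when lo <= g <= hi."""
    return iv[0] <= gap <= iv[1]


def _is_co1_interval(iv, locus: LocusReference) -> bool:
    m1, m2, m3 = (locus.motif_position(m.motif_id) for m in locus.motifs)
    return (
        interval_contains_element(iv, m1)
        and not interval_contains_element(iv, m2)
        and not interval_contains_element(iv, m3)
    )


def _is_co2_interval(iv, locus: LocusReference) -> bool:
    m1, m2, m3 = (locus.motif_position(m.motif_id) for m in locus.motifs)
    if interval_contains_element(iv, m1) or interval_contains_element(iv, m3):
        return False
    return interval_contains_element(iv, m2) or (m2 < iv[0] and iv[1] <= m3)


def classify_clone(
    calls: list[MarkerCall],
    repeats: list[RepeatMeasurement],
    locus: LocusReference,
    clone_id: str = "clone",
    sample: str | None = None,
    individual: str | None = None,
) -> CloneClassification:
    """Classify one clone from its ordered marker calls and repeat measurements."""
    if [c.marker_id for c in calls] != locus.marker_ids:
        raise InputMismatchError("marker calls do not match the locus marker set/order")

    motif1_id = locus.motifs[0].motif_id
    m1_meas = next((r for r in repeats if r.motif_id == motif1_id), None)

    informative = [
        (locus.element_index[c.marker_id], c.call) for c in calls if c.call in ("P", "M")
    ]
    n_unusable = len(calls) - len(informative)

    switches = []
    for (i, a), (j, b) in zip(informative, informative[1:]):
        if a != b:
            switches.append((i + 1, j))  # half-open element interval
    n_switches = len(switches)

    def result(cls, intervals=()):
        return CloneClassification(
            clone_id=clone_id,
            clone_class=cls,
            breakpoint_intervals=list(intervals),
            motif1_measurement=m1_meas,
            n_switches=n_switches,
            sample=sample,
            individual=individual,
        )

    if n_unusable > math.ceil(len(calls) / 3) or not informative:
        return result("AMBIGUOUS")

    if n_switches == 0:
        parent = informative[0][1]
        motif1 = locus.motifs[0]
        expected_units = motif1.paternal_units if parent == "P" else motif1.maternal_units
        if m1_meas is not None and m1_meas.observed_units is not None and \
                m1_meas.observed_units != expected_units:
            return result("INTRA_ALLELIC")
        return result("PD" if parent == "P" else "MD")

    if n_switches == 1:
        iv = switches[0]
        if _is_co1_interval(iv, locus):
            return result("CO_I", [iv])
        if _is_co2_interval(iv, locus):
            return result("CO_II", [iv])
        return result("AMBIGUOUS", [iv])

    if n_switches == 2:
        # alternation guarantees flank-X / middle-Y / flank-X
        if _is_co1_interval(switches[0], locus) and _is_co2_interval(switches[1], locus):
            return result("CO_I_II", switches)
        return result("AMBIGUOUS", switches)

    return result("AMBIGUOUS", switches)


def infer_dsb_origin(
    classification: CloneClassification, locus: LocusReference
) -> DSBCall:
    """Assign the double-strand break to a homolog for a crossover-I clone.

    An HR clone whose motif-1 count equals the maternal count arose from a
    break on the paternal homolog repaired off the maternal template, and
    symmetrically; counts matching neither parent leave the origin
    indeterminate (contracted below both counts, expanded otherwise).
    """
    if classification.clone_class != "CO_I":
        raise ContractViolationError(
            f"DSB origin is defined for CO_I clones, got {classification.clone_class}"
        )
    motif1 = locus.motifs[0]
    meas = classification.motif1_measurement
    if meas is None or meas.observed_units is None:
        return DSBCall(classification.clone_id, "indeterminate", "missing")
    u = meas.observed_units
    if u == motif1.maternal_units:
        return DSBCall(classification.clone_id, "dsb_paternal", "units_equal_maternal")
    if u == motif1.paternal_units:
        return DSBCall(classification.clone_id, "dsb_maternal", "units_equal_paternal")
    if u < min(motif1.paternal_units, motif1.maternal_units):
        return DSBCall(classification.clone_id, "indeterminate", "contracted")
    return DSBCall(classification.clone_id, "indeterminate", "expanded")


def classify_records(clones, locus: LocusReference):
    """End-to-end convenience: marker-call, measure and classify clone records.

    Returns ``(classifications, dsb_calls)`` where ``dsb_calls`` maps
    clone_id -> DSBCall for every crossover-I clone.
    """
    from .calling import call_clone

    classifications, dsb_calls = [], {}
    for clone in clones:
        calls, repeats = call_clone(clone, locus)
        c = classify_clone(
            calls, repeats, locus,
            clone_id=clone.clone_id,
            sample=clone.sample,
            individual=clone.individual,
        )
        classifications.append(c)
        if c.clone_class == "CO_I":
            dsb_calls[c.clone_id] = infer_dsb_origin(c, locus)
    return classifications, dsb_calls


@dataclass
class RepeatSpectrum:
    """Motif-1 unit-count distribution among the HR clones of one sample."""

    sample: str
    counts: Counter
    n_measured: int
    frac_at_paternal: float | None
    frac_at_maternal: float | None
    frac_other: float | None


def summarize_repeat_distribution(
    classifications: list[CloneClassification], locus: LocusReference
) -> dict[str, RepeatSpectrum]:
    """Histogram motif-1 unit counts among HR clones, split by sample origin.

    Fractions (at the paternal count, at the maternal count, elsewhere) are
    over non-missing measurements and sum to 1 per sample.
    """
    by_sample: dict[str, list[CloneClassification]] = {}
    for c in classifications:
        if not c.is_hr:
            continue
        by_sample.setdefault(c.sample or "all", []).append(c)

    motif1 = locus.motifs[0]
    out = {}
    for sample, group in by_sample.items():
        counts = Counter(
            c.motif1_measurement.observed_units
            for c in group
            if c.motif1_measurement is not None
            and c.motif1_measurement.observed_units is not None
        )
        n = sum(counts.values())
        if n:
            at_p = counts.get(motif1.paternal_units, 0) / n
            at_m = counts.get(motif1.maternal_units, 0) / n
            frac = (at_p, at_m, 1.0 - at_p - at_m)
        else:
            frac = (None, None, None)
        out[sample] = RepeatSpectrum(sample, counts, n, *frac)
    return out
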