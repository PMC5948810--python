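"""Aggregate clone classifications into recombination-frequency reports.

Intra-allelic artifact clones and ambiguous clones are excluded from both
the numerator and the denominator of every recombination fraction and
reported separately.  Uncertainty on proportions uses Wilson score
intervals, which behave sensibly at the small clone counts typical of
cloned-amplicon experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from statsmodels.stats.proportion import proportion_confint

from .classify import (
    CLONE_CLASSES,
    EXCLUDED_CLASSES,
    HR_CLASSES,
    CloneClassification,
)
from .locus import LocusReference

RETAINED_CLASSES = ("PD", "MD", "CO_I", "CO_II", "CO_I_II")


def wilson_interval(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    if n == 0:
        raise ValueError("empty denominator")
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    return float(lo), float(hi)


@dataclass
class FrequencyReport:
    """Per-sample clone-class bookkeeping and recombination fractions."""

    sample_id: str
    counts: dict
    n_retained: int
    n_excluded: int
    hr_fraction: float | None
    hr_ci: tuple[float, float] | None
    class_fractions: dict  # over retained clones
    flagged: bool = False  # True when no retained clones -> fractions undefined

    @property
    def n_total(self) -> int:
        return self.n_retained + self.n_excluded

    @property
    def hr_percent(self) -> float | None:
        return None if self.hr_fraction is None else round(100.0 * self.hr_fraction, 2)

    def class_percent(self, cls: str) -> float | None:
        f = self.class_fractions.get(cls)
        return None if f is None else round(100.0 * f, 2)


def estimate_frequencies(
    classifications: list[CloneClassification],
) -> dict[str, FrequencyReport]:
    """Per-sample class counts, HR fraction with Wilson 95% CI, exclusions.

    Samples are taken from each classification's ``sample`` field (clones
    with no sample tag pool under ``"all"``); samples are never pooled
    implicitly across tags.
    """
    by_sample: dict[str, list[CloneClassification]] = {}
    for c in classifications:
        by_sample.setdefault(c.sample or "all", []).append(c)
    return {s: _report_for(s, group) for s, group in sorted(by_sample.items())}


def _report_for(sample_id: str, group: list[CloneClassification]) -> FrequencyReport:
    counts = {cls: 0 for cls in CLONE_CLASSES}
    for c in group:
        counts[c.clone_class] += 1
    n_retained = sum(counts[c] for c in RETAINED_CLASSES)
    n_excluded = sum(counts[c] for c in EXCLUDED_CLASSES)
    if n_retained == 0:
        return FrequencyReport(
            sample_id, counts, 0, n_excluded,
            hr_fraction=None, hr_ci=None, class_fractions={}, flagged=True,
        )
    n_hr = sum(counts[c] for c in HR_CLASSES)
    return FrequencyReport(
        sample_id=sample_id,
        counts=counts,
        n_retained=n_retained,
        n_excluded=n_excluded,
        hr_fraction=n_hr / n_retained,
        hr_ci=wilson_interval(n_hr, n_retained),
        class_fractions={c: counts[c] / n_retained for c in RETAINED_CLASSES},
    )


# ---------------------------------------------------------------------------
# Half-tetrad genotyping of gynogenetic diploids
# ---------------------------------------------------------------------------

PATTERN_GRANDFATHER = "grandfather"
PATTERN_GRANDMOTHER = "grandmother"
PATTERN_CROSSOVER = "crossover"


@dataclass
class GynoGenotype:
    individual_id: str
    genotype: str | None  # "HOM_GF" | "HOM_GM" | "HET" | None when withheld
    patterns: tuple = ()
    n_clones: int = 0
    withheld: bool = False
    reason: str | None = None


def _pattern_of(c: CloneClassification) -> str | None:
    if c.clone_class == "PD":
        return PATTERN_GRANDFATHER
    if c.clone_class == "MD":
        return PATTERN_GRANDMOTHER
    if c.is_hr:
        return PATTERN_CROSSOVER
    return None  # excluded clones carry no haplotype evidence


def genotype_gynogenote(
    individual_id: str,
    classifications: list[CloneClassification],
    min_clones: int = 2,
) -> GynoGenotype:
    """Half-tetrad genotype of one gynogenetic diploid from its clones.

    One haplotype pattern among usable clones -> homozygous for that
    grandparental haplotype; two or more distinct patterns -> heterozygous,
    which directly evidences a meiotic crossover in the mother.  Fewer
    usable clones than ``min_clones`` withholds the genotype, as does the
    (real-data) corner case of a single all-crossover pattern, which the
    three-way genotype cannot express.
    """
    usable = [c for c in classifications if _pattern_of(c) is not None]
    patterns = tuple(sorted({_pattern_of(c) for c in usable}))
    if len(usable) < min_clones:
        return GynoGenotype(
            individual_id, None, patterns, len(usable),
            withheld=True, reason="insufficient clones",
        )
    if len(patterns) >= 2:
        return GynoGenotype(individual_id, "HET", patterns, len(usable))
    if patterns == (PATTERN_GRANDFATHER,):
        return GynoGenotype(individual_id, "HOM_GF", patterns, len(usable))
    if patterns == (PATTERN_GRANDMOTHER,):
        return GynoGenotype(individual_id, "HOM_GM", patterns, len(usable))
    return GynoGenotype(
        individual_id, None, patterns, len(usable),
        withheld=True, reason="single crossover pattern",
    )


def genotype_cohort(
    classifications: list[CloneClassification], min_clones: int = 2
) -> list[GynoGenotype]:
    """Group classifications by individual tag and genotype each."""
    by_ind: dict[str, list[CloneClassification]] = {}
    for c in classifications:
        key = c.individual or c.sample or "individual"
        by_ind.setdefault(key, []).append(c)
    return [
        genotype_gynogenote(ind, group, min_clones=min_clones)
        for ind, group in sorted(by_ind.items())
    ]


@dataclass
class MeioticHRReport:
    n_genotyped: int
    n_het: int
    n_hom_gf: int
    n_hom_gm: int
    het_fraction: float
    het_ci: tuple[float, float]
    n_withheld: int = 0

    @property
    def het_percent(self) -> float:
        return round(100.0 * self.het_fraction, 2)

    @property
    def hom_percent(self) -> float:
        return round(100.0 * (1.0 - self.het_fraction), 2)


def meiotic_hr_frequency(genotypes: list[GynoGenotype]) -> MeioticHRReport:
    """Meiotic HR frequency = heterozygote proportion among genotyped
    gynogenetic diploids (withheld individuals excluded), with Wilson CI."""
    usable = [g for g in genotypes if not g.withheld]
    if not usable:
        raise ValueError("no genotyped individuals")
    n = len(usable)
    n_het = sum(g.genotype == "HET" for g in usable)
    return MeioticHRReport(
        n_genotyped=n,
        n_het=n_het,
        n_hom_gf=sum(g.genotype == "HOM_GF" for g in usable),
        n_hom_gm=sum(g.genotype == "HOM_GM" for g in usable),
        het_fraction=n_het / n,
        het_ci=wilson_interval(n_het, n),
        n_withheld=len(genotypes) - n,
    )


# ---------------------------------------------------------------------------
# Repeat-length instability
# ---------------------------------------------------------------------------

@dataclass
class InstabilityReport:
    sample_id: str
    observed_counts: tuple
    novel_counts: tuple  # unit counts matching neither parental tract
    test_unique_counts: tuple | None = None  # absent from the control spectrum


def detect_novel_lengths(
    measurements_by_sample: dict,
    locus: LocusReference,
    control_sample: str | None = None,
) -> dict[str, InstabilityReport]:
    """Flag motif-1 unit counts absent from both parental tracts.

    ``measurements_by_sample`` maps sample -> list of RepeatMeasurement for
    motif 1.  When ``control_sample`` is given, each other sample also
    reports the lengths absent from the control's observed spectrum —
    the embryo-only novel bands of a heterozygote vs mixed-parent control.
    """
    motif1 = locus.motifs[0]
    parental = {motif1.paternal_units, motif1.maternal_units}
    spectra = {
        s: {m.observed_units for m in ms if m.observed_units is not None}
        for s, ms in measurements_by_sample.items()
    }
    control = spectra.get(control_sample, set()) if control_sample else None
    out = {}
    for s, counts in spectra.items():
        unique = None
        if control is not None and s != control_sample:
            unique = tuple(sorted(counts - control))
        out[s] = InstabilityReport(
            sample_id=s,
            observed_counts=tuple(sorted(counts)),
            novel_counts=tuple(sorted(counts - parental)),
            test_unique_counts=unique,
        )
    return out
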