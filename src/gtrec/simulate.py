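"""Synthetic clone generator with ground truth.

Emits cloned-amplicon sequences from a two-parent locus under known true
classes (parental, crossover I / II / I+II, intra-allelic artifact),
together with the PCR artifacts that real cloned products carry: repeat
slippage, single template-switch chimeras within a repeat tract, and
per-base substitution errors.  Every clone is paired with a TruthRecord so
the calling/classification/statistics stages can be tested end to end
without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .locus import MATERNAL, PATERNAL, LocusReference, RepeatMotif, e_id

CLASSES = ("PD", "MD", "CO_I", "CO_II", "CO_I_II", "INTRA_ALLELIC")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class ArtifactParams:
    """PCR/sequencing artifact model parameters (per clone).

    slippage_prob: probability the amplified motif-1 tract slips by a
        nonzero number of whole units (signed geometric step, symmetric).
    template_switch_prob: probability of a single within-tract
        template-switch chimera; the product keeps one parent's marker
        pattern but acquires an off-register repeat length — the mechanism
        behind intra-allelic artifact clones.
    seq_error_rate: per-base substitution probability, applied last.
    co1_dsb_paternal_prob: for simulated crossover-I clones, probability
        the double-strand break sits on the (long-tract) paternal homolog.
    """

    slippage_prob: float = 0.15
    slippage_geom_p: float = 0.5
    template_switch_prob: float = 0.1
    seq_error_rate: float = 0.001
    co1_dsb_paternal_prob: float = 0.8

    def __post_init__(self):
        for name in ("slippage_prob", "slippage_geom_p", "template_switch_prob",
                     "seq_error_rate", "co1_dsb_paternal_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0, 1]")

    @classmethod
    def clean(cls) -> "ArtifactParams":
        """Artifact-free parameters (for closure/identity tests)."""
        return cls(slippage_prob=0.0, template_switch_prob=0.0, seq_error_rate=0.0)


@dataclass
class CloneRecord:
    """One sequenced amplicon clone plus sample metadata."""

    clone_id: str
    seq: str
    sample: str | None = None
    individual: str | None = None


@dataclass
class TruthRecord:
    """Ground truth for a simulated clone."""

    clone_id: str
    true_class: str
    true_breakpoints: list = field(default_factory=list)  # gap indices, element frame
    true_motif1_units: int = 0
    dsb_parent: str = "none"  # "paternal" | "maternal" | "none"
    slipped: bool = False
    chimeric: bool = False
    sample: str | None = None


def _signed_geometric(rng, p: float) -> int:
    step = int(rng.geometric(p))
    return step if rng.random() < 0.5 else -step


def _slip_units(rng, units: int, params: ArtifactParams, forbidden=()) -> int:
    """A slipped unit count: nonzero whole-unit change, >= 1 unit, avoiding
    the counts in ``forbidden`` (used so forced artifacts stay off-parental)."""
    for _ in range(100):
        new = units + _signed_geometric(rng, params.slippage_geom_p)
        if new >= 1 and new != units and new not in forbidden:
            return new
    raise SimulationError("could not draw a slipped unit count")


def simulate_clone(
    true_class: str,
    locus: LocusReference,
    params: ArtifactParams,
    rng: np.random.Generator,
    *,
    clone_id: str = "clone",
    sample: str | None = None,
    orientation: tuple[str, str] | None = None,
    dsb_parent: str | None = None,
    motif1_units: int | None = None,
    co1_gap: int | None = None,
    co2_gap: int | None = None,
    uniparental_parent: str | None = None,
) -> tuple[CloneRecord, TruthRecord]:
    """Simulate one clone of the given true class.

    Keyword overrides pin the otherwise random choices: ``orientation`` is
    the (upstream, downstream) parent pair for crossover clones,
    ``dsb_parent`` the broken homolog for crossover-I clones (the emitted
    motif-1 tract carries the *template* parent's unit count),
    ``motif1_units`` an explicit tract length, ``co1_gap``/``co2_gap`` the
    breakpoint gaps (element frame), ``uniparental_parent`` the haplotype
    of PD/MD/intra-allelic clones.
    """
    if true_class not in CLASSES:
        raise SimulationError(f"unknown clone class {true_class!r}")

    m1 = locus.motifs[0]
    eids = [e_id(e) for e in locus.elements]
    co1_gaps = locus.crossover1_gaps()
    co2_gaps = locus.crossover2_gaps()
    m1_pos = locus.motif_position(m1.motif_id)

    breakpoints: list[int] = []
    truth_dsb = "none"
    units = None  # None -> innate count of the assigned parent

    if true_class in ("PD", "MD"):
        parent = PATERNAL if true_class == "PD" else MATERNAL
        assign = {eid: parent for eid in eids}
    elif true_class == "INTRA_ALLELIC":
        parent = uniparental_parent or (PATERNAL if rng.random() < 0.5 else MATERNAL)
        assign = {eid: parent for eid in eids}
        units = motif1_units if motif1_units is not None else _slip_units(
            rng, m1.units_of(parent), params,
            forbidden=(m1.paternal_units, m1.maternal_units),
        )
    elif true_class == "CO_I":
        up, down = orientation or ((PATERNAL, MATERNAL) if rng.random() < 0.5
                                   else (MATERNAL, PATERNAL))
        truth_dsb = dsb_parent or (
            "paternal" if rng.random() < params.co1_dsb_paternal_prob else "maternal"
        )
        template = MATERNAL if truth_dsb == "paternal" else PATERNAL
        # the repaired tract copies the template homolog's unit count; the
        # breakpoint gap follows: tract matching the downstream parent puts
        # the exchange upstream of motif 1, and vice versa
        gap = co1_gap if co1_gap is not None else (
            co1_gaps[0] if template == down else co1_gaps[1]
        )
        assign = {eid: (up if i < gap else down) for i, eid in enumerate(eids)}
        assign[m1.motif_id] = template
        units = motif1_units if motif1_units is not None else m1.units_of(template)
        breakpoints = [gap]
    elif true_class == "CO_II":
        up, down = orientation or ((PATERNAL, MATERNAL) if rng.random() < 0.5
                                   else (MATERNAL, PATERNAL))
        gap = co2_gap if co2_gap is not None else int(rng.choice(co2_gaps))
        assign = {eid: (up if i < gap else down) for i, eid in enumerate(eids)}
        breakpoints = [gap]
    elif true_class == "CO_I_II":
        flank, middle = orientation or ((PATERNAL, MATERNAL) if rng.random() < 0.5
                                        else (MATERNAL, PATERNAL))
        gap_i = co1_gap if co1_gap is not None else int(rng.choice(co1_gaps))
        gap_ii = co2_gap if co2_gap is not None else int(rng.choice(co2_gaps))
        assign = {
            eid: (middle if gap_i <= i < gap_ii else flank)
            for i, eid in enumerate(eids)
        }
        breakpoints = [gap_i, gap_ii]

    # innate count of whichever parent supplies motif 1
    if units is None:
        units = m1.units_of(assign[m1.motif_id])
        if motif1_units is not None:
            units = motif1_units

    slipped = chimeric = False
    if true_class != "INTRA_ALLELIC" and motif1_units is None:
        if rng.random() < params.template_switch_prob:
            # within-tract template switch: re-anneal at a random register of
            # a same-length template molecule
            u = int(rng.integers(1, max(units, 2)))
            v = int(rng.integers(1, max(units, 2)))
            if u != v:
                units = u + (units - v)
                chimeric = True
        if rng.random() < params.slippage_prob:
            units = _slip_units(rng, units, params)
            slipped = True

    seq = locus.render_haplotype(assign, motif_units={m1.motif_id: units})

    if params.seq_error_rate > 0:
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        n_err = rng.binomial(len(arr), params.seq_error_rate)
        if n_err:
            pos = rng.choice(len(arr), size=n_err, replace=False)
            bases = np.frombuffer(b"ACGT", dtype=np.uint8)
            for i in pos:
                alt = bases[bases != arr[i]]
                arr[i] = rng.choice(alt)
            seq = arr.tobytes().decode()

    clone = CloneRecord(clone_id=clone_id, seq=seq, sample=sample)
    truth = TruthRecord(
        clone_id=clone_id,
        true_class=true_class,
        true_breakpoints=breakpoints,
        true_motif1_units=units,
        dsb_parent=truth_dsb,
        slipped=slipped,
        chimeric=chimeric,
        sample=sample,
    )
    return clone, truth


def simulate_clone_set(
    composition: dict,
    locus: LocusReference,
    params: ArtifactParams,
    seed: int,
    sample: str | None = None,
) -> tuple[list[CloneRecord], list[TruthRecord]]:
    """Simulate exactly the requested per-class clone counts, shuffled.

    ``composition`` maps class name -> count (>= 0).  Reproducible for a
    fixed seed: identical seeds yield identical clone sets.
    """
    for cls, n in composition.items():
        if cls not in CLASSES:
            raise SimulationError(f"unknown clone class {cls!r}")
        if n < 0:
            raise SimulationError(f"negative count for {cls}")
    rng = np.random.default_rng(seed)
    order = [cls for cls in CLASSES for _ in range(composition.get(cls, 0))]
    rng.shuffle(order)
    clones, truths = [], []
    for i, cls in enumerate(order):
        c, t = simulate_clone(
            cls, locus, params, rng, clone_id=f"clone{i:05d}", sample=sample
        )
        clones.append(c)
        truths.append(t)
    return clones, truths


def simulate_embryo_series(
    per_division_hr_prob: float,
    division_counts: list[int],
    clones_per_sample: int,
    locus: LocusReference,
    params: ArtifactParams,
    seed: int,
) -> list[dict]:
    """Clone sets along an embryonic division series.

    A sampled lineage carries a recombinant allele with probability
    1 - (1 - p)^d after d divisions, so the expected recombinant fraction
    accumulates with cell divisions.  Recombinants are crossover-I clones;
    non-recombinants split evenly between the parental haplotypes.
    Returns one dict per entry of ``division_counts``: ``{"divisions",
    "clones", "truths"}``.
    """
    p = per_division_hr_prob
    if not 0.0 <= p <= 1.0:
        raise SimulationError(f"per-division HR probability {p} outside [0, 1]")
    if list(division_counts) != sorted(division_counts):
        raise SimulationError("division_counts must be nondecreasing")
    rng = np.random.default_rng(seed)
    out = []
    for d in division_counts:
        p_rec = 1.0 - (1.0 - p) ** d
        sample = f"d{d}"
        clones, truths = [], []
        for i in range(clones_per_sample):
            if rng.random() < p_rec:
                cls = "CO_I"
            else:
                cls = "PD" if rng.random() < 0.5 else "MD"
            c, t = simulate_clone(
                cls, locus, params, rng,
                clone_id=f"{sample}_clone{i:05d}", sample=sample,
            )
            clones.append(c)
            truths.append(t)
        out.append({"divisions": d, "clones": clones, "truths": truths})
    return out


def simulate_co1_repeat_panel(
    locus: LocusReference,
    params: ArtifactParams,
    seed: int,
    n_dsb_paternal: int,
    n_dsb_maternal: int,
    n_other: int,
    sample: str | None = None,
) -> tuple[list[CloneRecord], list[TruthRecord]]:
    """A crossover-I clone panel with pinned repeat-length composition.

    ``n_dsb_paternal`` clones carry the maternal motif-1 unit count (break
    on the paternal homolog), ``n_dsb_maternal`` the paternal count, and
    ``n_other`` a contracted/expanded count matching neither parent —
    the composition behind repeat-length DSB-origin spectra.
    """
    rng = np.random.default_rng(seed)
    m1 = locus.motifs[0]
    specs = (
        [("paternal", None)] * n_dsb_paternal
        + [("maternal", None)] * n_dsb_maternal
        + [(None, "other")] * n_other
    )
    rng.shuffle(specs)
    clones, truths = [], []
    for i, (dsb, other) in enumerate(specs):
        kw = {}
        if dsb is not None:
            kw["dsb_parent"] = dsb
        else:
            template = m1.units_of(PATERNAL if rng.random() < 0.5 else MATERNAL)
            kw["motif1_units"] = _slip_units(
                rng, template, params,
                forbidden=(m1.paternal_units, m1.maternal_units),
            )
        c, t = simulate_clone(
            "CO_I", locus, params, rng,
            clone_id=f"co1_{i:04d}", sample=sample, **kw,
        )
        clones.append(c)
        truths.append(t)
    return clones, truths


@dataclass
class GynoTruth:
    individual_id: str
    genotype: str  # "HET" | "HOM_GF" | "HOM_GM"


def simulate_gynogenote_cohort(
    meiotic_co_prob: float,
    n_individuals: int,
    clones_per_individual: int,
    locus: LocusReference,
    params: ArtifactParams,
    seed: int,
    genotypes: list[str] | None = None,
) -> tuple[list[CloneRecord], list[GynoTruth]]:
    """Simulate meio-gynogenetic diploid individuals (half-tetrad design).

    Each individual derives from a single egg whose second polar body was
    retained, so its two alleles are two chromatids of one homolog.  With
    probability ``meiotic_co_prob`` a crossover made those chromatids
    distinct (one grandparental, one recombinant) -> heterozygous;
    otherwise both match a single grandparent (equal odds).  Clones are
    drawn evenly from the individual's two template chromosomes.
    ``genotypes`` pins the per-individual truth (overrides the random
    draw), e.g. to rebuild a cohort with known heterozygote counts.
    """
    q = meiotic_co_prob
    if not 0.0 <= q <= 1.0:
        raise SimulationError(f"meiotic crossover probability {q} outside [0, 1]")
    rng = np.random.default_rng(seed)
    if genotypes is not None:
        if len(genotypes) != n_individuals:
            raise SimulationError("genotypes list length != n_individuals")
        bad = set(genotypes) - {"HET", "HOM_GF", "HOM_GM"}
        if bad:
            raise SimulationError(f"unknown genotypes {bad}")

    clones: list[CloneRecord] = []
    truths: list[GynoTruth] = []
    m1 = locus.motifs[0]
    eids = [e_id(e) for e in locus.elements]
    for j in range(n_individuals):
        ind = f"gyno{j:03d}"
        if genotypes is not None:
            gt = genotypes[j]
        elif rng.random() < q:
            gt = "HET"
        else:
            gt = "HOM_GF" if rng.random() < 0.5 else "HOM_GM"

        if gt == "HET":
            # retained chromatids: one non-recombinant grandparental, one
            # crossover-I recombinant sharing its upstream arm
            g = PATERNAL if rng.random() < 0.5 else MATERNAL
            other = MATERNAL if g == PATERNAL else PATERNAL
            alleles = [
                ("PD" if g == PATERNAL else "MD", {}),
                ("CO_I", {"orientation": (g, other),
                          "dsb_parent": "paternal" if g == PATERNAL else "maternal"}),
            ]
        else:
            g = PATERNAL if gt == "HOM_GF" else MATERNAL
            alleles = [("PD" if g == PATERNAL else "MD", {})] * 2

        for i in range(clones_per_individual):
            cls, kw = alleles[i % 2]
            c, t = simulate_clone(
                cls, locus, params, rng,
                clone_id=f"{ind}_clone{i:03d}", sample=ind, **kw,
            )
            c.individual = ind
            clones.append(c)
        truths.append(GynoTruth(individual_id=ind, genotype=gt))
    return clones, truths
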