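"""Two-parent locus model: diagnostic markers, GT repeat motifs, rendered haplotypes.

The locus is modelled as an alternating layout of *conserved* segments
(identical in both parents) and *diagnostic elements* (markers or repeat
motifs, which differ between the parents)::

    conserved[0] elem[0] conserved[1] elem[1] ... elem[n-1] conserved[n]

Every downstream stage locates elements through their *anchors*: the k-mer
of conserved sequence immediately left and right of the element.  Because
anchors live in conserved sequence they are present on both parental
haplotypes and on every recombinant, which makes marker extraction robust
to the large indel length differences between the parents.

Coordinates are 0-based half-open throughout.  Breakpoints are expressed in
the *element frame*: element ``i`` occupies integer position ``i`` and the
conserved gap preceding it is gap ``i`` (gap ``n`` follows the last
element).  Intervals in this frame are insensitive to parent-specific indel
lengths.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import yaml

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

SEGMENTS = (
    "upstream_of_motif1",
    "between_motif1_and_motif2",
    "between_motif2_and_motif3",
    "downstream_of_motif3",
)

PATERNAL = "P"
MATERNAL = "M"
PARENTS = (PATERNAL, MATERNAL)


class LocusError(ValueError):
    """Base class for locus specification problems."""


class AnchorNotUniqueError(LocusError):
    """An element's flanking anchor occurs more than once in a parental sequence."""


class LayoutError(LocusError):
    """Conserved/element layout is inconsistent (overlaps, short gaps...)."""


class InsufficientMarkersError(LocusError):
    """A segment required for crossover typing carries no diagnostic marker."""


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatMotif:
    """A dinucleotide tandem-repeat tract with parent-specific unit counts.

    ``interruptions`` maps parent -> list of ``(unit_offset, base)`` pairs;
    each replaces the first base of that unit with ``base`` (a
    length-preserving substitution, modelling an *imperfect* tract).
    ``orientation`` is relative to the reference strand: a ``reverse`` motif
    is laid down as the reverse complement of the unit tract.
    """

    motif_id: str
    unit: str
    orientation: str  # "forward" | "reverse"
    paternal_units: int
    maternal_units: int
    interruptions: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.unit) != 2 or any(b not in "ACGT" for b in self.unit):
            raise LocusError(f"{self.motif_id}: unit must be a 2-letter nucleotide string")
        if self.orientation not in ("forward", "reverse"):
            raise LocusError(f"{self.motif_id}: bad orientation {self.orientation!r}")
        if self.paternal_units < 1 or self.maternal_units < 1:
            raise LocusError(f"{self.motif_id}: unit counts must be >= 1")

    def units_of(self, parent: str) -> int:
        return self.paternal_units if parent == PATERNAL else self.maternal_units

    def render(self, parent: str, units: int | None = None) -> str:
        """Rendered tract on the reference strand for one parent.

        ``units`` overrides the parent's innate count (used by the simulator
        for slipped/chimeric tracts); interruption offsets beyond the tract
        are dropped.
        """
        n = self.units_of(parent) if units is None else units
        if n < 1:
            raise LocusError(f"{self.motif_id}: cannot render {n} units")
        tract = list(self.unit * n)
        for off, base in self.interruptions.get(parent, []):
            if 0 <= off < n:
                tract[off * 2] = base
        out = "".join(tract)
        return reverse_complement(out) if self.orientation == "reverse" else out


@dataclass(frozen=True)
class MarkerDef:
    """A diagnostic marker (SNP or indel) distinguishing the two parents."""

    marker_id: str
    kind: str  # "snp" | "indel"
    paternal_allele: str
    maternal_allele: str
    segment: str

    def __post_init__(self):
        if self.kind not in ("snp", "indel"):
            raise LocusError(f"{self.marker_id}: bad kind {self.kind!r}")
        if self.paternal_allele == self.maternal_allele:
            raise LocusError(f"{self.marker_id}: parental alleles must differ")
        if self.kind == "snp" and not (
            len(self.paternal_allele) == len(self.maternal_allele) == 1
        ):
            raise LocusError(f"{self.marker_id}: SNP alleles must have length 1")
        if self.segment not in SEGMENTS:
            raise LocusError(f"{self.marker_id}: unknown segment {self.segment!r}")

    def allele_of(self, parent: str) -> str:
        return self.paternal_allele if parent == PATERNAL else self.maternal_allele


@dataclass
class LocusReference:
    """Validated two-parent locus: sequences, elements, anchors, coordinates.

    ``elements`` is the 5'->3' ordered list of MarkerDef / RepeatMotif
    objects; ``conserved`` the interleaved conserved segments
    (``len(conserved) == len(elements) + 1``).  ``anchors[element_id]`` is
    the ``(left_kmer, right_kmer)`` pair, ``coords[(element_id, parent)]``
    the half-open interval of the element in that parent's sequence.
    """

    locus_id: str
    elements: list
    conserved: list
    anchor_k: int
    paternal_seq: str = field(init=False)
    maternal_seq: str = field(init=False)
    anchors: dict = field(init=False)
    coords: dict = field(init=False)
    element_index: dict = field(init=False)

    def __post_init__(self):
        if len(self.conserved) != len(self.elements) + 1:
            raise LayoutError(
                f"need {len(self.elements) + 1} conserved segments, got {len(self.conserved)}"
            )
        for i, seg in enumerate(self.conserved):
            if i > 0 and len(seg) < self.anchor_k:
                # interior gaps must be able to donate both flanking anchors
                raise LayoutError(f"conserved segment {i} shorter than anchor k={self.anchor_k}")
        if len(self.conserved[0]) < self.anchor_k:
            raise LayoutError(f"leading conserved segment shorter than anchor k={self.anchor_k}")
        self.element_index = {e_id(e): i for i, e in enumerate(self.elements)}
        if len(self.element_index) != len(self.elements):
            raise LayoutError("duplicate element ids")
        self.anchors = {}
        for i, e in enumerate(self.elements):
            left = self.conserved[i][-self.anchor_k:]
            right = self.conserved[i + 1][: self.anchor_k]
            self.anchors[e_id(e)] = (left, right)
        self.paternal_seq, p_coords = self._render(PATERNAL)
        self.maternal_seq, m_coords = self._render(MATERNAL)
        self.coords = {}
        for eid, iv in p_coords.items():
            self.coords[(eid, PATERNAL)] = iv
        for eid, iv in m_coords.items():
            self.coords[(eid, MATERNAL)] = iv
        self._validate()

    # -- rendering ---------------------------------------------------------

    def _render(self, parent: str):
        parts = [self.conserved[0]]
        coords = {}
        pos = len(self.conserved[0])
        for i, e in enumerate(self.elements):
            piece = (
                e.render(parent) if isinstance(e, RepeatMotif) else e.allele_of(parent)
            )
            coords[e_id(e)] = (pos, pos + len(piece))
            parts.append(piece)
            pos += len(piece)
            parts.append(self.conserved[i + 1])
            pos += len(self.conserved[i + 1])
        return "".join(parts), coords

    def render_haplotype(self, parent_by_element: dict, motif_units: dict | None = None) -> str:
        """Render a (possibly recombinant) haplotype.

        ``parent_by_element`` maps element_id -> "P" / "M"; ``motif_units``
        optionally overrides a motif's unit count (slippage, chimeras).
        """
        motif_units = motif_units or {}
        parts = [self.conserved[0]]
        for i, e in enumerate(self.elements):
            parent = parent_by_element[e_id(e)]
            if isinstance(e, RepeatMotif):
                parts.append(e.render(parent, units=motif_units.get(e.motif_id)))
            else:
                parts.append(e.allele_of(parent))
            parts.append(self.conserved[i + 1])
        return "".join(parts)

    # -- validation --------------------------------------------------------

    def _validate(self):
        for eid, (left, right) in self.anchors.items():
            for parent, seq in ((PATERNAL, self.paternal_seq), (MATERNAL, self.maternal_seq)):
                for name, kmer in (("left", left), ("right", right)):
                    if seq.count(kmer) != 1:
                        raise AnchorNotUniqueError(
                            f"{eid}: anchor_{name} occurs {seq.count(kmer)}x in {parent}"
                        )
        for parent, seq in ((PATERNAL, self.paternal_seq), (MATERNAL, self.maternal_seq)):
            prev_end = 0
            for e in self.elements:
                s, t = self.coords[(e_id(e), parent)]
                if s < prev_end:
                    raise LayoutError(f"overlapping intervals at {e_id(e)} ({parent})")
                prev_end = t
        present = {m.segment for m in self.markers}
        missing = [s for s in SEGMENTS if s not in present]
        if missing:
            raise InsufficientMarkersError(
                f"no diagnostic marker in segment(s): {', '.join(missing)}"
            )

    # -- structure accessors -----------------------------------------------

    @property
    def markers(self) -> list:
        return [e for e in self.elements if isinstance(e, MarkerDef)]

    @property
    def motifs(self) -> list:
        return [e for e in self.elements if isinstance(e, RepeatMotif)]

    @property
    def marker_ids(self) -> list:
        return [m.marker_id for m in self.markers]

    def motif_position(self, motif_id: str) -> int:
        return self.element_index[motif_id]

    @property
    def motif1(self) -> RepeatMotif:
        return self.motifs[0]

    def n_gaps(self) -> int:
        return len(self.elements) + 1

    def crossover1_gaps(self) -> list:
        """Conserved gaps flanking motif 1 (candidate crossover-I sites)."""
        m1 = self.motif_position(self.motifs[0].motif_id)
        return [m1, m1 + 1]

    def crossover2_gaps(self) -> list:
        """Gaps between motif 2 and the last marker before motif 3.

        A breakpoint in any of these gaps is localized by flanking markers
        to an interval free of motif 1 and motif 3 (candidate crossover-II
        sites); the gap immediately before motif 3 is excluded because its
        marker interval would also span motif 3.
        """
        m2 = self.motif_position(self.motifs[1].motif_id)
        m3 = self.motif_position(self.motifs[2].motif_id)
        marker_pos = [self.element_index[m.marker_id] for m in self.markers]
        last_mid = max(p for p in marker_pos if m2 < p < m3)
        return list(range(m2 + 1, last_mid + 1))


def e_id(element) -> str:
    return element.motif_id if isinstance(element, RepeatMotif) else element.marker_id


# ---------------------------------------------------------------------------
# Spec document <-> LocusReference
# ---------------------------------------------------------------------------

def load_locus_spec(doc: dict) -> LocusReference:
    """Build and validate a LocusReference from a structured spec document.

    The document holds ``locus_id``, ``anchor_k``, the ``conserved``
    segment list and the ordered ``elements`` list (dicts with
    ``type: marker|motif``).  Deterministic for a fixed document; raises
    ``LocusError`` subclasses on invalid input.
    """
    elements = []
    for entry in doc["elements"]:
        kind = entry["type"]
        if kind == "motif":
            interruptions = {
                p: [tuple(x) for x in v]
                for p, v in (entry.get("interruptions") or {}).items()
            }
            elements.append(
                RepeatMotif(
                    motif_id=entry["id"],
                    unit=entry["unit"],
                    orientation=entry.get("orientation", "forward"),
                    paternal_units=int(entry["paternal_units"]),
                    maternal_units=int(entry["maternal_units"]),
                    interruptions=interruptions,
                )
            )
        elif kind == "marker":
            elements.append(
                MarkerDef(
                    marker_id=entry["id"],
                    kind=entry["kind"],
                    paternal_allele=entry.get("paternal", ""),
                    maternal_allele=entry.get("maternal", ""),
                    segment=entry["segment"],
                )
            )
        else:
            raise LocusError(f"unknown element type {kind!r}")
    return LocusReference(
        locus_id=doc.get("locus_id", "locus"),
        elements=elements,
        conserved=list(doc["conserved"]),
        anchor_k=int(doc.get("anchor_k", 20)),
    )


def serialize_locus(locus: LocusReference) -> dict:
    """Inverse of load_locus_spec: round-trips sequences and coordinates."""
    out = {
        "locus_id": locus.locus_id,
        "anchor_k": locus.anchor_k,
        "conserved": list(locus.conserved),
        "elements": [],
    }
    for e in locus.elements:
        if isinstance(e, RepeatMotif):
            out["elements"].append(
                {
                    "type": "motif",
                    "id": e.motif_id,
                    "unit": e.unit,
                    "orientation": e.orientation,
                    "paternal_units": e.paternal_units,
                    "maternal_units": e.maternal_units,
                    "interruptions": {p: [list(x) for x in v] for p, v in e.interruptions.items()},
                }
            )
        else:
            out["elements"].append(
                {
                    "type": "marker",
                    "id": e.marker_id,
                    "kind": e.kind,
                    "paternal": e.paternal_allele,
                    "maternal": e.maternal_allele,
                    "segment": e.segment,
                }
            )
    return out


def locus_spec_hash(doc: dict) -> str:
    return hashlib.sha256(yaml.safe_dump(doc, sort_keys=True).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Default emulation spec
# ---------------------------------------------------------------------------

_DEFAULT_SPEC_SEED = 1137  # fixed: the default locus is a constant of the package


def _random_conserved(rng, length: int) -> str:
    # reject GT/AC dinucleotide runs >= 3 units so conserved sequence cannot
    # extend a repeat tract or mimic one
    while True:
        seq = "".join(rng.choice(list("ACGT"), size=length))
        if "GTGTGT" not in seq and "ACACAC" not in seq:
            return seq


def default_locus_spec(
    motif1_paternal_units: int = 84,
    motif1_maternal_units: int = 36,
    motif2_units: int = 12,
    motif3_units: int = 10,
    anchor_k: int = 20,
) -> dict:
    """The default goldfish *ntl*-promoter-like locus specification.

    A ~2.6 kb two-parent locus: a 39-bp indel upstream of an imperfect
    (GT)n motif 1 (84 paternal / 36 maternal units, i.e. ~168 vs ~72 nt),
    two SNPs plus a 3-bp indel between motifs 1 and 2, a reverse-oriented
    (GT)n motif 2, three SNPs between motifs 2 and 3, a short (GT)n motif
    3, and two markers downstream.  Insertion alleles sit on the paternal
    haplotype by default.  Conserved segments are fixed pseudo-random
    sequence (constant seed), so the default locus is fully deterministic.
    """
    rng = np.random.default_rng(_DEFAULT_SPEC_SEED)
    elements = [
        {"type": "marker", "id": "indel39", "kind": "indel",
         "segment": "upstream_of_motif1",
         "paternal": _random_conserved(rng, 39), "maternal": ""},
        {"type": "motif", "id": "motif1", "unit": "GT", "orientation": "forward",
         "paternal_units": motif1_paternal_units, "maternal_units": motif1_maternal_units,
         "interruptions": {"P": [[motif1_paternal_units // 2, "A"]],
                           "M": [[motif1_maternal_units // 2, "A"]]}},
        {"type": "marker", "id": "snp1", "kind": "snp",
         "segment": "between_motif1_and_motif2", "paternal": "A", "maternal": "G"},
        {"type": "marker", "id": "snp2", "kind": "snp",
         "segment": "between_motif1_and_motif2", "paternal": "T", "maternal": "C"},
        {"type": "marker", "id": "indel3", "kind": "indel",
         "segment": "between_motif1_and_motif2", "paternal": "CTT", "maternal": ""},
        {"type": "motif", "id": "motif2", "unit": "GT", "orientation": "reverse",
         "paternal_units": motif2_units, "maternal_units": motif2_units,
         "interruptions": {}},
        {"type": "marker", "id": "snpA", "kind": "snp",
         "segment": "between_motif2_and_motif3", "paternal": "G", "maternal": "T"},
        {"type": "marker", "id": "snpB", "kind": "snp",
         "segment": "between_motif2_and_motif3", "paternal": "C", "maternal": "A"},
        {"type": "marker", "id": "snpC", "kind": "snp",
         "segment": "between_motif2_and_motif3", "paternal": "A", "maternal": "C"},
        {"type": "motif", "id": "motif3", "unit": "GT", "orientation": "forward",
         "paternal_units": motif3_units, "maternal_units": motif3_units,
         "interruptions": {}},
        {"type": "marker", "id": "snpD", "kind": "snp",
         "segment": "downstream_of_motif3", "paternal": "T", "maternal": "G"},
        {"type": "marker", "id": "indelD", "kind": "indel",
         "segment": "downstream_of_motif3",
         "paternal": "", "maternal": _random_conserved(rng, 8)},
    ]
    n_gaps = len(elements) + 1
    # gap sizing targets ~2.6 kb total paternal length
    gap_lengths = [250] + [170] * (n_gaps - 2) + [250]
    conserved = [_random_conserved(rng, L) for L in gap_lengths]
    return {
        "locus_id": "ntl_promoter_emulation",
        "anchor_k": anchor_k,
        "conserved": conserved,
        "elements": elements,
    }


def default_locus(**kwargs) -> LocusReference:
    return load_locus_spec(default_locus_spec(**kwargs))
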