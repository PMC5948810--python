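"""Anchor-based marker calling and repeat-length measurement.

Each diagnostic element is located in a clone through its two conserved
flanking anchors.  Location is attempted in three stages, cheapest first:

1. exact k-mer search (``str.find``);
2. fuzzy anchor alignment (edlib infix mode, <= 2 edits, unique best hit) —
   absorbs sequencing errors inside the anchor;
3. coordinate transfer through a global clone-vs-parent alignment
   (``align_to_parent``), for clones whose anchor region is too damaged
   for a direct hit.

The substring enclosed by the anchors is then compared to the two parental
alleles (markers) or converted to a whole-unit repeat count (motifs).
Failures surface as ``missing``/``ambiguous`` calls, never exceptions.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
from Bio import Align

from .locus import (
    MATERNAL,
    PATERNAL,
    LocusReference,
    MarkerDef,
    RepeatMotif,
    reverse_complement,
)
from .simulate import CloneRecord

FUZZY_MAX_EDITS = 2

_ALPHABET = set("ACGTN")


@dataclass
class MarkerCall:
    marker_id: str
    call: str  # "P" | "M" | "ambiguous" | "missing"
    observed_allele: str | None
    anchor_found: tuple[bool, bool]


@dataclass
class RepeatMeasurement:
    motif_id: str
    observed_units: int | None
    matches: str  # "paternal_count" | "maternal_count" | "other" | "missing"
    delta_vs_nearest_parent: int | None


class AlignmentInputError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Pairwise alignment (global, affine gaps, deterministic)
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -6.0
    aligner.extend_gap_score = -0.2
    return aligner


_ALIGNER = _make_aligner()


def align_to_parent(clone_seq: str, parent_seq: str) -> Align.Alignment:
    """Global affine-gap alignment of a clone against one parental reference.

    Target coordinates are the parent's, query coordinates the clone's.
    Among co-optimal alignments the first enumerated one is returned, which
    for this scoring scheme places gaps leftmost — the output is
    deterministic for fixed inputs.
    """
    for name, s in (("clone", clone_seq), ("parent", parent_seq)):
        if not s:
            raise AlignmentInputError(f"{name} sequence is empty")
        if set(s) - _ALPHABET:
            raise AlignmentInputError(f"{name} sequence contains non-ACGTN characters")
    return _ALIGNER.align(parent_seq, clone_seq)[0]


def alignment_identity(alignment: Align.Alignment) -> float:
    """Fraction of target positions aligned to an identical query base.

    Low values flag degenerate inputs (truncated clones, wrong locus);
    downstream marker calls on such clones surface as ``missing``.
    """
    counts = alignment.counts()
    aligned = counts.identities + counts.mismatches
    total = alignment.shape[1]
    return counts.identities / total if total else 0.0


def map_parent_interval(
    alignment: Align.Alignment, start: int, end: int
) -> tuple[int, int] | None:
    """Map a parent (target) interval onto clone (query) coordinates.

    Returns the query span covering every aligned position of the target
    interval, or None if the interval is entirely deleted from the clone.
    """
    blocks = alignment.aligned  # shape (2, n_blocks, 2): target rows, query rows
    t_blocks, q_blocks = blocks[0], blocks[1]
    qs = qe = None
    for (ts, te), (qbs, _qbe) in zip(t_blocks, q_blocks):
        if te <= start:
            continue
        if ts >= end:
            break
        s, e = max(ts, start), min(te, end)
        if qs is None:
            qs = int(qbs + (s - ts))
        qe = int(qbs + (e - ts))
    if qs is None or qe is None:
        return None
    return qs, qe


# ---------------------------------------------------------------------------
# Anchor location
# ---------------------------------------------------------------------------

def _find_exact(seq: str, kmer: str) -> tuple[int, int] | None:
    i = seq.find(kmer)
    if i < 0:
        return None
    return i, i + len(kmer)


def _find_fuzzy(seq: str, kmer: str, max_edits: int = FUZZY_MAX_EDITS) -> tuple[int, int] | None:
    res = edlib.align(kmer, seq, mode="HW", task="locations", k=max_edits)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    locs = res["locations"]
    starts = {s for s, _ in locs}
    if len(starts) > 1:
        # several distinct best placements: ambiguous, refuse to guess
        return None
    s, e = locs[0]
    return s, e + 1  # edlib end is inclusive


class _CloneContext:
    """Per-clone anchor location with cached parent alignments as last resort.

    Cloned inserts can be sequenced in either direction, so the context
    first picks the clone orientation: whichever strand carries more exact
    anchor hits is scanned (ties keep the forward strand).
    """

    def __init__(self, clone_seq: str, locus: LocusReference):
        self.locus = locus
        anchors = [k for pair in locus.anchors.values() for k in pair]
        rc = reverse_complement(clone_seq)
        fwd_hits = sum(k in clone_seq for k in anchors)
        rc_hits = sum(k in rc for k in anchors)
        self.seq = rc if rc_hits > fwd_hits else clone_seq
        self._alignments: dict[str, Align.Alignment | None] = {}

    def _alignment(self, parent: str) -> Align.Alignment | None:
        if parent not in self._alignments:
            ref = self.locus.paternal_seq if parent == PATERNAL else self.locus.maternal_seq
            try:
                self._alignments[parent] = align_to_parent(self.seq, ref)
            except AlignmentInputError:
                self._alignments[parent] = None
        return self._alignments[parent]

    def locate_anchor(self, kmer: str) -> tuple[int, int] | None:
        hit = _find_exact(self.seq, kmer)
        if hit is None:
            hit = _find_fuzzy(self.seq, kmer)
        if hit is None:
            hit = self._locate_via_alignment(kmer)
        return hit

    def _locate_via_alignment(self, kmer: str) -> tuple[int, int] | None:
        # anchors are conserved: their parent coordinates are well defined;
        # map through whichever parent aligns better
        best = None
        for parent in (PATERNAL, MATERNAL):
            ref = self.locus.paternal_seq if parent == PATERNAL else self.locus.maternal_seq
            p = ref.find(kmer)
            if p < 0:
                continue
            aln = self._alignment(parent)
            if aln is None:
                continue
            if best is None or aln.score > best[0]:
                best = (aln.score, aln, p)
        if best is None:
            return None
        _, aln, p = best
        hit = map_parent_interval(aln, p, p + len(kmer))
        if hit is None or hit[1] <= hit[0]:
            return None
        return hit


# ---------------------------------------------------------------------------
# Calls and measurements
# ---------------------------------------------------------------------------

def _enclosed(ctx: _CloneContext, left: str, right: str):
    lhit = ctx.locate_anchor(left)
    rhit = ctx.locate_anchor(right)
    found = (lhit is not None, rhit is not None)
    if lhit is None or rhit is None or rhit[0] < lhit[1]:
        return None, found
    return ctx.seq[lhit[1]: rhit[0]], found


def _matches_allele(observed: str, allele: str, kind: str) -> bool:
    if kind == "snp":
        return observed == allele
    # indel alleles: same length, <= 1 substitution (sequencing-error slack)
    if len(observed) != len(allele):
        return False
    return sum(a != b for a, b in zip(observed, allele)) <= 1


def call_marker(ctx: _CloneContext, marker: MarkerDef, locus: LocusReference) -> MarkerCall:
    left, right = locus.anchors[marker.marker_id]
    observed, found = _enclosed(ctx, left, right)
    if observed is None:
        return MarkerCall(marker.marker_id, "missing", None, found)
    hit_p = _matches_allele(observed, marker.paternal_allele, marker.kind)
    hit_m = _matches_allele(observed, marker.maternal_allele, marker.kind)
    if hit_p and not hit_m:
        call = "P"
    elif hit_m and not hit_p:
        call = "M"
    else:
        call = "ambiguous"
    return MarkerCall(marker.marker_id, call, observed, found)


def call_markers(clone: CloneRecord | str, locus: LocusReference) -> list[MarkerCall]:
    """One MarkerCall per locus marker, in 5'->3' locus order."""
    seq = clone.seq if isinstance(clone, CloneRecord) else clone
    ctx = _CloneContext(seq, locus)
    return [call_marker(ctx, m, locus) for m in locus.markers]


def measure_repeat(
    clone: CloneRecord | str, motif: RepeatMotif, locus: LocusReference
) -> RepeatMeasurement:
    """Whole-unit repeat count of one motif, measured on the motif's strand.

    Reverse-oriented motifs are measured on the reverse complement of the
    enclosed substring; a trailing odd nucleotide is not counted; the
    length-preserving interruptions configured in the locus do not change
    the count.
    """
    seq = clone.seq if isinstance(clone, CloneRecord) else clone
    ctx = _CloneContext(seq, locus)
    return _measure_repeat_ctx(ctx, motif, locus)


def _measure_repeat_ctx(
    ctx: _CloneContext, motif: RepeatMotif, locus: LocusReference
) -> RepeatMeasurement:
    left, right = locus.anchors[motif.motif_id]
    observed, _found = _enclosed(ctx, left, right)
    if observed is None:
        return RepeatMeasurement(motif.motif_id, None, "missing", None)
    tract = reverse_complement(observed) if motif.orientation == "reverse" else observed
    units = len(tract) // len(motif.unit)
    if units == motif.paternal_units and units == motif.maternal_units:
        matches = "paternal_count"  # counts coincide; paternal label by convention
    elif units == motif.paternal_units:
        matches = "paternal_count"
    elif units == motif.maternal_units:
        matches = "maternal_count"
    else:
        matches = "other"
    nearest = min(
        (motif.paternal_units, motif.maternal_units),
        key=lambda c: (abs(units - c), c),
    )
    return RepeatMeasurement(motif.motif_id, units, matches, units - nearest)


def call_clone(
    clone: CloneRecord | str, locus: LocusReference
) -> tuple[list[MarkerCall], list[RepeatMeasurement]]:
    """Marker calls plus repeat measurements for one clone (shared anchor
    location context, so the clone is scanned once)."""
    seq = clone.seq if isinstance(clone, CloneRecord) else clone
    ctx = _CloneContext(seq, locus)
    calls = [call_marker(ctx, m, locus) for m in locus.markers]
    repeats = [_measure_repeat_ctx(ctx, mo, locus) for mo in locus.motifs]
    return calls, repeats
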