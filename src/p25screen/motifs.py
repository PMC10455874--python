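"""p25alpha-domain motif scanning and TPPP-like architecture typing.

The p25alpha domain is diagnosed here by two degenerate protein motifs: the
Rossmann-like ``GXGXGXXGR`` nonamer at the conserved C-terminus, and the
``L(F)xxxFxxF(Y)xxF`` signature at the very start of the domain.  Domain
*completeness* (full domain, C-terminally incomplete, C-terminus absent,
C-terminal fragment only) is measured by aligning the candidate to a reference
consensus and reading off which parts of the reference are covered.  Motif
counts + coverage class + an externally supplied DCX-domain flag then decide
the five-way TPPP-like type:

============  =============================================================
long          one Rossmann motif, full domain (animal-type TPPP)
fungal_type   two Rossmann motifs (full domain plus an extra C-tail copy)
short         no Rossmann, C-terminal part incomplete
truncated     no Rossmann, entire C-terminus missing, N-terminal motif there
apicortin     C-terminal fragment of the domain fused to a DCX domain
============  =============================================================

DCX presence is an input annotation (id -> bool), not computed here.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from Bio import Align

from .sequence_io import (
    Alphabet,
    AlphabetError,
    NUCLEOTIDE_CHARS,
    SequenceRecord,
    six_frame_translate,
)

__all__ = [
    "MotifPattern",
    "MotifHit",
    "ReferenceDomain",
    "CoverageClass",
    "DomainArchitecture",
    "TpppType",
    "ROSSMANN",
    "NTERM",
    "DEFAULT_REFERENCE",
    "AlignScoring",
    "scan_motif",
    "align_to_reference",
    "covered_fraction",
    "coverage_class",
    "classify_architecture",
    "scan_protein",
    "scan_nucleotide",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate motif: one residue-set per position; ``None`` = any.

    ``X`` (and ``*``) in a scanned sequence match only ``None`` positions.
    """

    name: str
    positions: tuple[frozenset[str] | None, ...]

    def __post_init__(self) -> None:
        for pos in self.positions:
            if pos is not None and (not pos or not pos <= AMINO_ACIDS):
                raise ValueError(f"pattern {self.name!r}: bad position {pos!r}")

    def __len__(self) -> int:
        return len(self.positions)


def _pat(name: str, spec: str) -> MotifPattern:
    """Compact pattern syntax: 'G.G.G..GR' with [LF] for alternatives."""
    positions: list[frozenset[str] | None] = []
    i = 0
    while i < len(spec):
        c = spec[i]
        if c == ".":
            positions.append(None)
            i += 1
        elif c == "[":
            j = spec.index("]", i)
            positions.append(frozenset(spec[i + 1 : j]))
            i = j + 1
        else:
            positions.append(frozenset(c))
            i += 1
    return MotifPattern(name, tuple(positions))


#: Rossmann-like motif GXGXGXXGR at the conserved C-terminus of the domain.
ROSSMANN = _pat("rossmann", "G.G.G..GR")
#: N-terminal signature L(F)xxxFxxF(Y)xxF; parenthesised letters alternate.
NTERM = _pat("nterm", "[LF]...F..[FY]..F")


@dataclass(frozen=True)
class MotifHit:
    pattern_name: str
    start: int  # 1-based
    end: int  # 1-based inclusive
    matched: str
    source_id: str = ""
    frame: int | None = None

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.matched):
            raise ValueError("hit span does not match matched string length")


@dataclass(frozen=True)
class ReferenceDomain:
    """A reference p25alpha consensus against which coverage is measured."""

    consensus: str
    expected_length: int = 160

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError("empty reference consensus")
        if self.expected_length < 30:
            raise ValueError("expected_length must be >= 30")

    def __len__(self) -> int:
        return len(self.consensus)


# Synthetic stand-in consensus (no real p25alpha sequence is bundled): the
# N-terminal signature occupies positions 1-11, the Rossmann nonamer 146-154,
# and the filler alphabet excludes G/R/F/Y/L so neither motif can fire twice.
_SYNTHETIC_CONSENSUS = (
    "LAEHFSKYDGFPSMHMVTVEHWSVTIVKMNNWPQIEQPSHMMHSPPHTIQMWQSWQASMH"
    "VAMKQDMDPTQNHMNKAVHTWMPEQNEKDDPKEVDANITSIPQEIPKDHSWDEIDAQHHM"
    "TDEIPITWWTWESKWKQETPNIDHIGAGAGKAGRDDANHD"
)

DEFAULT_REFERENCE = ReferenceDomain(consensus=_SYNTHETIC_CONSENSUS)


class CoverageClass(str, enum.Enum):
    full = "full"
    cterm_partial = "cterm_partial"
    cterm_missing = "cterm_missing"
    cterm_only = "cterm_only"
    none = "none"


class TpppType(str, enum.Enum):
    long = "long"
    short = "short"
    truncated = "truncated"
    fungal_type = "fungal_type"
    apicortin = "apicortin"
    ambiguous = "ambiguous"
    none = "none"


@dataclass(frozen=True)
class DomainArchitecture:
    has_nterm_motif: bool
    n_rossmann: int
    coverage_class: CoverageClass
    has_dcx: bool = False
    source_id: str = ""
    frame: int | None = None

    def __post_init__(self) -> None:
        if self.n_rossmann < 0:
            raise ValueError("n_rossmann must be >= 0")


def _check_protein(seq: str, reject_nucleotide_like: bool = True) -> str:
    seq = seq.upper()
    extra = set(seq) - AMINO_ACIDS - {"X", "*"}
    if extra:
        raise AlphabetError(f"not a protein sequence, offending: {sorted(extra)}")
    # most amino-acid letters double as IUPAC nucleotide codes, so "looks
    # nucleotide" can only be a heuristic: a long sequence over ACGTUN alone
    # is essentially never a real protein.
    if reject_nucleotide_like and len(seq) >= 6 and set(seq) <= set("ACGTUN"):
        raise AlphabetError("sequence looks nucleotide, expected protein")
    return seq


def scan_motif(
    seq: str,
    pattern: MotifPattern,
    max_mismatch: int = 0,
    source_id: str = "",
    check_alphabet: bool = True,
) -> list[MotifHit]:
    """All (possibly overlapping) occurrences of ``pattern`` in ``seq``.

    Hits are returned in ascending start order, 1-based inclusive coordinates.
    ``max_mismatch`` (default 0) allows that many violated fixed positions,
    for sensitivity studies; the published motifs are treated as exact.
    """
    seq = _check_protein(seq, reject_nucleotide_like=check_alphabet)
    k = len(pattern)
    hits = []
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        mism = 0
        for c, pos in zip(window, pattern.positions):
            if pos is not None and c not in pos:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            hits.append(
                MotifHit(
                    pattern_name=pattern.name,
                    start=i + 1,
                    end=i + k,
                    matched=window,
                    source_id=source_id,
                )
            )
    return hits


@dataclass(frozen=True)
class AlignScoring:
    """Linear (affine-free) scoring for reference-coverage alignment."""

    match: float = 2.0
    mismatch: float = -1.0
    gap: float = -2.0
    #: minimum score a trimmed segment must reach to be reported; filters the
    #: low-scoring stretches a global alignment necessarily drags along when
    #: unrelated flanks face unrelated parts of the reference.
    min_segment_score: float = 12.0


def _ruzzo_tompa(scores: list[float]) -> list[tuple[int, int, float]]:
    """All maximal positive-scoring subsequences of ``scores``.

    Returns (start, end_exclusive, score) triples in left-to-right order.
    """
    segs: list[list[float]] = []  # [start, end, Lcum, Rcum]
    cum = 0.0
    for i, s in enumerate(scores):
        if s <= 0:
            cum += s
            continue
        cand = [float(i), float(i + 1), cum, cum + s]
        cum += s
        while True:
            j = None
            for k in range(len(segs) - 1, -1, -1):
                if segs[k][2] < cand[2]:
                    j = k
                    break
            if j is None or segs[j][3] >= cand[3]:
                if j is None:
                    segs = [cand]
                else:
                    segs = segs[: j + 1] + [cand]
                break
            cand = [segs[j][0], cand[1], segs[j][2], cand[3]]
            segs = segs[:j]
    return [(int(a), int(b), r - l) for a, b, l, r in segs]


def align_to_reference(
    seq: str,
    ref: ReferenceDomain = DEFAULT_REFERENCE,
    scoring: AlignScoring = AlignScoring(),
) -> list[tuple[int, int]]:
    """Reference intervals covered by ``seq``.

    The sequence is aligned to the reference consensus with linear gap
    scoring in local (Smith-Waterman) mode — the domain may sit anywhere
    inside a longer translated frame, and unrelated flanks must not drag the
    alignment.  Within the aligned columns, maximal positive-scoring
    stretches of reference positions (insertions in the sequence charge
    their gap penalty) are extracted and those reaching
    ``min_segment_score`` are returned as 1-based inclusive
    ``(ref_start, ref_end)`` intervals.

    A sequence with no region scoring positive against the reference yields
    an empty list.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap
    aligner.extend_gap_score = scoring.gap
    alns = aligner.align(ref.consensus, seq)
    if len(alns) == 0 or alns.score <= 0:
        return []
    aln = alns[0]
    t_blocks, q_blocks = aln.aligned
    # per-reference-position column scores; insertions in seq charge their gap
    # penalty onto the following reference position so trimming sees them.
    items: list[tuple[int, float]] = []  # (ref_pos0, score)
    prev_t_end = None
    prev_q_end = None
    for (t0, t1), (q0, q1) in zip(t_blocks, q_blocks):
        pending = 0.0
        if prev_q_end is not None and q0 > prev_q_end and prev_t_end == t0:
            pending = scoring.gap * (q0 - prev_q_end)
        for k in range(t1 - t0):
            a, b = ref.consensus[t0 + k], seq[q0 + k]
            s = scoring.match if a == b else scoring.mismatch
            items.append((t0 + k, s + (pending if k == 0 else 0.0)))
        prev_t_end, prev_q_end = t1, q1
    segments: list[tuple[int, int]] = []
    # split at reference-position discontinuities, trim within each chunk
    chunk: list[tuple[int, float]] = []
    for item in items + [(-2, 0.0)]:
        if chunk and item[0] != chunk[-1][0] + 1:
            scores = [s for _, s in chunk]
            for a, b, sc in _ruzzo_tompa(scores):
                if sc >= scoring.min_segment_score:
                    segments.append((int(chunk[a][0]) + 1, int(chunk[b - 1][0]) + 1))
            chunk = []
        if item[0] >= 0:
            chunk.append(item)
    return segments


def covered_fraction(segments: list[tuple[int, int]], length: int) -> float:
    covered = set()
    for a, b in segments:
        covered.update(range(max(1, a), min(length, b) + 1))
    return len(covered) / length


def coverage_class(
    segments: list[tuple[int, int]],
    ref: ReferenceDomain = DEFAULT_REFERENCE,
    tail_fraction: float = 0.25,
) -> CoverageClass:
    """Classify which part of the reference domain is present.

    The C-terminal *tail* is the last ``tail_fraction`` of the reference.
    Decision list, first match wins: ``full`` at >= 90% total coverage;
    ``none`` below 20%; ``cterm_only`` when coverage starts at (or within a
    small slack of) the tail boundary; ``cterm_missing`` when coverage ends
    clearly before the tail boundary; ``cterm_partial`` otherwise (coverage
    reaches the tail region but the domain is incomplete).  The slack
    (5% of the reference, minimum 2 residues) absorbs alignment jitter of a
    few columns at the domain edges.
    """
    length = len(ref)
    covered = set()
    for a, b in segments:
        covered.update(range(max(1, a), min(length, b) + 1))
    frac = len(covered) / length
    if frac >= 0.9:
        return CoverageClass.full
    if frac < 0.2:
        return CoverageClass.none
    boundary = math.floor(length * (1.0 - tail_fraction))
    slack = max(2, round(0.05 * length))
    if min(covered) >= boundary - slack:
        return CoverageClass.cterm_only
    if max(covered) < boundary - slack:
        return CoverageClass.cterm_missing
    return CoverageClass.cterm_partial


def classify_architecture(arch: DomainArchitecture) -> TpppType:
    """Five-way TPPP-like type call from motif and coverage evidence.

    A decision list, first rule wins; evidence combinations matching no rule
    are reported ``ambiguous`` rather than forced into a type.
    """
    cc = arch.coverage_class
    if arch.has_dcx and cc is CoverageClass.cterm_only:
        return TpppType.apicortin
    if arch.n_rossmann >= 2:
        return TpppType.fungal_type
    if arch.n_rossmann == 1 and cc is CoverageClass.full:
        return TpppType.long
    if arch.n_rossmann == 0 and cc is CoverageClass.cterm_partial:
        return TpppType.short
    if arch.n_rossmann == 0 and arch.has_nterm_motif and cc is CoverageClass.cterm_missing:
        return TpppType.truncated
    if cc is CoverageClass.none and arch.n_rossmann == 0 and not arch.has_nterm_motif:
        return TpppType.none
    return TpppType.ambiguous


@dataclass(frozen=True)
class ScanResult:
    architecture: DomainArchitecture
    tppp_type: TpppType
    hits: tuple[MotifHit, ...]
    segments: tuple[tuple[int, int], ...]


def scan_protein(
    seq: str,
    source_id: str = "",
    ref: ReferenceDomain = DEFAULT_REFERENCE,
    scoring: AlignScoring = AlignScoring(),
    has_dcx: bool = False,
    max_mismatch: int = 0,
    frame: int | None = None,
) -> ScanResult:
    """Scan one protein sequence and type its architecture."""
    check = frame is None  # translated frames are protein by construction
    ross = scan_motif(seq, ROSSMANN, max_mismatch, source_id, check_alphabet=check)
    nterm = scan_motif(seq, NTERM, max_mismatch, source_id, check_alphabet=check)
    segments = align_to_reference(seq, ref, scoring)
    cc = coverage_class(segments, ref)
    hits = tuple(
        MotifHit(h.pattern_name, h.start, h.end, h.matched, source_id, frame)
        for h in ross + nterm
    )
    arch = DomainArchitecture(
        has_nterm_motif=bool(nterm),
        n_rossmann=len(ross),
        coverage_class=cc,
        has_dcx=has_dcx,
        source_id=source_id,
        frame=frame,
    )
    return ScanResult(arch, classify_architecture(arch), hits, tuple(segments))


def scan_nucleotide(
    rec: SequenceRecord,
    ref: ReferenceDomain = DEFAULT_REFERENCE,
    scoring: AlignScoring = AlignScoring(),
    has_dcx: bool = False,
    max_mismatch: int = 0,
) -> ScanResult:
    """Six-frame scan of a nucleotide record.

    Every frame is translated and scanned; the frame with the highest total
    evidence (motif hit count plus covered reference fraction) wins, ties
    broken by lowest ``|frame|`` with positive strand first.  The winning
    frame is recorded on the architecture and its hits.
    """
    if rec.alphabet is not Alphabet.nucleotide:
        raise AlphabetError(f"record {rec.id!r} is not nucleotide")
    best: ScanResult | None = None
    best_key: tuple = ()
    for ft in six_frame_translate(rec):
        if not ft.peptide:
            continue
        res = scan_protein(
            ft.peptide, rec.id, ref, scoring, has_dcx, max_mismatch, frame=ft.frame
        )
        evidence = len(res.hits) + covered_fraction(list(res.segments), len(ref))
        key = (-evidence, abs(ft.frame), 0 if ft.frame > 0 else 1)
        if best is None or key < best_key:
            best, best_key = res, key
    if best is None:
        arch = DomainArchitecture(False, 0, CoverageClass.none, has_dcx, rec.id, None)
        return ScanResult(arch, classify_architecture(arch), (), ())
    return best
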