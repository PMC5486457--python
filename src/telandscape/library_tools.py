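"""Repeat-library redundancy removal and element intactness screening.

Two jobs live here.

*Redundancy removal.*  Combined repeat libraries (database consensus plus
de novo models) contain the same family many times over.  The 80-80 rule
treats two sequences as one family when they can be aligned over more than
80% of their length with more than 80% identity; single-linkage clustering
of that relation partitions the library into families, each represented by
its longest member.  "Their length" is read as the shorter sequence's
length, so fragments are absorbed into their parent family — the behavior
redundancy removal needs (configurable to "longer" or "both").

*Intactness screening.*  Candidate LINEs are ranked on a ladder — intact
reverse transcriptase (RT), ORF1, long ORF2 (> 600 aa), and "full"
elements carrying both ORF1 and long ORF2; candidate ERVs are screened for
the retroviral ENV (> 480 aa), GAG (> 500 aa) and POL (> 800 aa) domains,
and called "full ERV" only when all three are present.  Domain presence is
established by local protein alignment of ORF translations against
user-supplied reference domain sequences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, NamedTuple, Optional, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .rm_io import reverse_complement

__all__ = [
    "PairSimilarity",
    "pair_similarity",
    "Family",
    "FamilyClustering",
    "cluster_80_80",
    "Orf",
    "find_orfs",
    "DomainHit",
    "ScreenResult",
    "screen_line",
    "screen_erv",
    "summarize_screen",
    "LINE_CATEGORIES",
    "ERV_CATEGORIES",
    "ERV_DOMAIN_THRESHOLDS",
]

_VALID_NT = set("ACGTN")

# Category ladders, most complete first.
LINE_CATEGORIES = ("full_LINE", "ORF2_only", "ORF1_only", "intact_RT_only", "defective")
ERV_CATEGORIES = ("full_ERV", "partial_ERV", "defective")

#: Minimum matched span (aa, strict >) for each retroviral domain.
ERV_DOMAIN_THRESHOLDS = {"ENV": 480, "GAG": 500, "POL": 800}


def _check_nucleotide(seq: str, name: str = "sequence") -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID_NT
    if bad:
        raise ValueError(
            f"{name} contains non-nucleotide characters: {sorted(bad)!r}"
        )
    if not seq:
        raise ValueError(f"{name} is empty")
    return seq


def _nt_aligner(match: float, mismatch: float, gap_open: float, gap_extend: float):
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _alignment_stats(alignment) -> tuple[int, int, tuple[int, int], tuple[int, int]]:
    """(matches, columns, target span, query span) of one local alignment.

    Columns count every alignment column, gap columns included.
    """
    blocks_t, blocks_q = alignment.aligned
    target = alignment.target
    query = alignment.query
    matches = 0
    columns = 0
    prev_t_end = prev_q_end = None
    for (ts, te), (qs, qe) in zip(blocks_t, blocks_q):
        if prev_t_end is not None:
            columns += (ts - prev_t_end) + (qs - prev_q_end)
        for a, b in zip(target[ts:te], query[qs:qe]):
            matches += a == b
        columns += te - ts
        prev_t_end, prev_q_end = te, qe
    t_span = (int(blocks_t[0][0]), int(blocks_t[-1][1]))
    q_span = (int(blocks_q[0][0]), int(blocks_q[-1][1]))
    return matches, columns, t_span, q_span


class PairSimilarity(NamedTuple):
    """Identity and (shorter-sequence) coverage of the best local alignment."""

    identity: float
    coverage: float
    score: float
    strand: str  # strand of b relative to a in the best alignment


def pair_similarity(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
    both_strands: bool = True,
    coverage_of: str = "shorter",
) -> PairSimilarity:
    """Local-alignment identity and coverage of a nucleotide pair.

    Identity is matches / aligned columns (gap columns included); coverage
    is the aligned span of the shorter sequence over its length (switchable
    to the longer sequence or both via ``coverage_of``).  The computation
    is symmetric in (a, b) and, with ``both_strands``, invariant to
    reverse-complementing either sequence.
    """
    a = _check_nucleotide(a, "a")
    b = _check_nucleotide(b, "b")
    # Canonical orientation/order: makes the statistic exactly symmetric.
    lo, hi = sorted((a, b), key=lambda s: (len(s), s))
    candidates = [hi]
    if both_strands:
        candidates.append(reverse_complement(hi))
    aligner = _nt_aligner(match, mismatch, gap_open, gap_extend)
    best: Optional[PairSimilarity] = None
    for strand, target in zip("+-", candidates):
        alignments = aligner.align(target, lo)
        if len(alignments) == 0 or alignments.score <= 0:
            stats = PairSimilarity(0.0, 0.0, 0.0, strand)
        else:
            aln = alignments[0]
            matches, columns, t_span, q_span = _alignment_stats(aln)
            identity = matches / columns if columns else 0.0
            short_len, long_len = len(lo), len(hi)
            cov_short = (q_span[1] - q_span[0]) / short_len
            cov_long = (t_span[1] - t_span[0]) / long_len
            coverage = {
                "shorter": cov_short,
                "longer": cov_long,
                "both": min(cov_short, cov_long),
            }[coverage_of]
            stats = PairSimilarity(identity, coverage, float(alignments.score), strand)
        if best is None or stats.score > best.score:
            best = stats
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# 80-80 clustering


@dataclass(frozen=True)
class Family:
    members: tuple[str, ...]
    representative: str


@dataclass
class FamilyClustering:
    """A partition of a library into families with designated representatives."""

    families: list[Family]

    def family_of(self) -> dict[str, str]:
        """Member identifier -> representative identifier."""
        return {m: f.representative for f in self.families for m in f.members}

    def as_sets(self) -> set[frozenset[str]]:
        return {frozenset(f.members) for f in self.families}

    @property
    def representatives(self) -> list[str]:
        return [f.representative for f in self.families]

    def non_redundant(self, library: dict[str, str]) -> dict[str, str]:
        """The library reduced to one representative per family."""
        return {r: library[r] for r in self.representatives}

    def to_tsv(self, stream: IO[str]) -> None:
        stream.write("member\trepresentative\n")
        for fam in self.families:
            for m in fam.members:
                stream.write(f"{m}\t{fam.representative}\n")


def _representative(members: Sequence[str], library: dict[str, str]) -> str:
    # Longest member; ties broken by lexicographically smallest identifier.
    return sorted(members, key=lambda m: (-len(library[m]), m))[0]


def cluster_80_80(
    library: dict[str, str],
    min_identity: float = 0.80,
    min_coverage: float = 0.80,
    coverage_of: str = "shorter",
    **align_kwargs,
) -> FamilyClustering:
    """Partition a library under the 80-80 rule by single linkage.

    Two sequences are directly linked when their best local alignment has
    identity strictly above ``min_identity`` AND coverage strictly above
    ``min_coverage``; families are the connected components of that graph.
    Deterministic and independent of input order.
    """
    if not library:
        raise ValueError("library is empty")
    ids = sorted(library)
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if find(a) == find(b):
                continue
            sim = pair_similarity(
                library[a], library[b], coverage_of=coverage_of, **align_kwargs
            )
            if sim.identity > min_identity and sim.coverage > min_coverage:
                union(a, b)

    groups: dict[str, list[str]] = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    families = [
        Family(tuple(sorted(members)), _representative(members, library))
        for members in groups.values()
    ]
    families.sort(key=lambda f: f.representative)
    return FamilyClustering(families)


# ---------------------------------------------------------------------------
# ORF finding


class Orf(NamedTuple):
    """An open reading frame: ATG-to-stop span in one of the six frames.

    ``start``/``end`` are 1-based inclusive positions on the input
    sequence (forward coordinates regardless of strand) and include the
    stop codon; ``length_aa`` excludes the stop.
    """

    frame: int  # 0, 1, 2: offset within the strand's reading direction
    strand: str
    start: int
    end: int
    length_aa: int
    protein: str


def find_orfs(nt: str, min_length_aa: int = 1, require_atg: bool = True) -> list[Orf]:
    """All ORFs in the six frames, longest first.

    With ``require_atg`` (the default) an ORF runs from the first ATG
    after the previous stop to the next stop codon; without it, from the
    first full codon after the previous stop (stop-to-stop mode).  ORFs
    lacking a terminating stop are not reported.
    """
    nt = _check_nucleotide(nt, "nt")
    if len(nt) < 3:
        raise ValueError("sequence shorter than one codon")
    L = len(nt)
    orfs: list[Orf] = []
    for strand in "+-":
        s = nt if strand == "+" else reverse_complement(nt)
        for frame in range(3):
            usable = (L - frame) // 3 * 3
            if usable < 3:
                continue
            prot = str(Seq(s[frame : frame + usable]).translate())
            start_aa: Optional[int] = None
            for i, aa in enumerate(prot):
                if aa == "*":
                    if start_aa is not None:
                        nt_start = frame + 3 * start_aa  # 0-based on s
                        nt_end = frame + 3 * (i + 1)  # exclusive, incl. stop
                        if strand == "+":
                            pos = (nt_start + 1, nt_end)
                        else:
                            pos = (L - nt_end + 1, L - nt_start)
                        length_aa = i - start_aa
                        if length_aa >= min_length_aa:
                            orfs.append(
                                Orf(
                                    frame,
                                    strand,
                                    pos[0],
                                    pos[1],
                                    length_aa,
                                    prot[start_aa:i],
                                )
                            )
                        start_aa = None
                elif start_aa is None and (aa == "M" or not require_atg):
                    start_aa = i
    orfs.sort(key=lambda o: (-o.length_aa, o.strand, o.frame, o.start))
    return orfs


# ---------------------------------------------------------------------------
# Protein alignment and screening


def _protein_aligner():
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


class DomainHit(NamedTuple):
    """Best local protein alignment of an ORF translation to a reference."""

    ref_id: str
    identity: float
    aligned_columns: int
    query_span_aa: int  # matched span on the element's ORF translation
    ref_coverage: float  # matched span on the reference / reference length
    score: float


_PROT_SANITIZE = re.compile(r"[^ACDEFGHIKLMNPQRSTVWYX]")


def _align_protein(query: str, ref_id: str, ref: str, aligner) -> Optional[DomainHit]:
    query = _PROT_SANITIZE.sub("X", query.upper())
    ref = _PROT_SANITIZE.sub("X", ref.upper())
    if not query or not ref:
        return None
    alignments = aligner.align(ref, query)
    if len(alignments) == 0 or alignments.score <= 0:
        return None
    matches, columns, t_span, q_span = _alignment_stats(alignments[0])
    return DomainHit(
        ref_id=ref_id,
        identity=matches / columns if columns else 0.0,
        aligned_columns=columns,
        query_span_aa=q_span[1] - q_span[0],
        ref_coverage=(t_span[1] - t_span[0]) / len(ref),
        score=float(alignments.score),
    )


def _best_hit(query: str, refs: dict[str, str], aligner) -> Optional[DomainHit]:
    best: Optional[DomainHit] = None
    for ref_id, ref in refs.items():
        hit = _align_protein(query, ref_id, ref, aligner)
        if hit and (best is None or hit.score > best.score):
            best = hit
    return best


@dataclass
class ScreenResult:
    """Category assignment for one candidate element.

    For LINE mode, ``orf2_length_aa`` is the length of the longest
    RT-bearing ORF (0 when none) and ``erv_domains`` is empty; for ERV
    mode the flags are unused and ``erv_domains`` maps each detected
    domain label to its matched span in aa.
    """

    element_id: str
    category: str
    has_intact_RT: bool = False
    has_ORF1: bool = False
    orf2_length_aa: int = 0
    erv_domains: dict[str, int] = field(default_factory=dict)
    clade: Optional[str] = None


def screen_line(
    element: str,
    rt_refs: dict[str, str],
    element_id: str = "element",
    min_identity: float = 0.25,
    min_overlap_aa: int = 200,
    orf2_min_aa: int = 600,
    orf1_min_aa: int = 100,
    intact_rt_ref_coverage: float = 0.90,
    clade: Optional[str] = None,
) -> ScreenResult:
    """Screen a candidate LINE for the intactness ladder.

    ORF2 is the longest ORF whose translation aligns to a reverse-
    transcriptase reference (identity >= ``min_identity`` over at least
    ``min_overlap_aa`` aligned aa).  ORF1 is any other ORF of at least
    ``orf1_min_aa`` aa upstream of ORF2 on the same strand.  The RT is
    called intact when a single ORF's alignment covers at least
    ``intact_rt_ref_coverage`` of a reference — i.e. the RT span is
    uninterrupted by stops or frameshifts.  "Full" elements need ORF1 and
    an ORF2 strictly longer than ``orf2_min_aa`` (600 aa by default).
    """
    if not rt_refs:
        raise ValueError("RT reference set is empty")
    element = _check_nucleotide(element, element_id)
    aligner = _protein_aligner()
    orfs = find_orfs(element)
    rt_hits: list[tuple[Orf, DomainHit]] = []
    for orf in orfs:
        hit = _best_hit(orf.protein, rt_refs, aligner)
        if hit and hit.identity >= min_identity and hit.aligned_columns >= min_overlap_aa:
            rt_hits.append((orf, hit))

    has_intact_rt = any(h.ref_coverage >= intact_rt_ref_coverage for _, h in rt_hits)
    orf2: Optional[Orf] = None
    if rt_hits:
        orf2 = max(rt_hits, key=lambda oh: oh[0].length_aa)[0]
    orf2_len = orf2.length_aa if orf2 else 0

    has_orf1 = False
    if orf2 is not None:
        for orf in orfs:
            if orf is orf2 or orf.strand != orf2.strand:
                continue
            if orf.length_aa < orf1_min_aa:
                continue
            upstream = (
                orf.end < orf2.start if orf2.strand == "+" else orf.start > orf2.end
            )
            if upstream:
                has_orf1 = True
                break

    if has_orf1 and orf2_len > orf2_min_aa:
        category = "full_LINE"
    elif orf2_len > orf2_min_aa:
        category = "ORF2_only"
    elif has_orf1:
        category = "ORF1_only"
    elif has_intact_rt:
        category = "intact_RT_only"
    else:
        category = "defective"
    return ScreenResult(
        element_id=element_id,
        category=category,
        has_intact_RT=has_intact_rt,
        has_ORF1=has_orf1,
        orf2_length_aa=orf2_len,
        clade=clade,
    )


def _domain_label(ref_id: str) -> str:
    tokens = re.split(r"[^A-Za-z0-9]+", ref_id.upper())
    labels = [t for t in tokens if t in ERV_DOMAIN_THRESHOLDS]
    if len(set(labels)) != 1:
        raise ValueError(
            f"reference {ref_id!r} must carry exactly one of "
            f"{sorted(ERV_DOMAIN_THRESHOLDS)} in its identifier"
        )
    return labels[0]


def screen_erv(
    element: str,
    domain_refs: dict[str, str],
    element_id: str = "element",
    min_identity: float = 0.25,
    thresholds: Optional[dict[str, int]] = None,
    clade: Optional[str] = None,
) -> ScreenResult:
    """Screen a candidate ERV for the ENV/GAG/POL domains.

    A domain is present when some ORF translation aligns to a reference
    carrying that label and the matched span on the element strictly
    exceeds the domain's threshold (ENV > 480 aa, GAG > 500 aa,
    POL > 800 aa).  All three present: ``full_ERV``; at least one:
    ``partial_ERV``; none: ``defective``.
    """
    if not domain_refs:
        raise ValueError("domain reference set is empty")
    thresholds = dict(ERV_DOMAIN_THRESHOLDS if thresholds is None else thresholds)
    by_label: dict[str, dict[str, str]] = {}
    for ref_id, ref in domain_refs.items():
        by_label.setdefault(_domain_label(ref_id), {})[ref_id] = ref
    element = _check_nucleotide(element, element_id)
    aligner = _protein_aligner()
    orfs = find_orfs(element)

    found: dict[str, int] = {}
    for label, refs in by_label.items():
        best_span = 0
        for orf in orfs:
            hit = _best_hit(orf.protein, refs, aligner)
            if hit and hit.identity >= min_identity:
                best_span = max(best_span, hit.query_span_aa)
        if best_span > thresholds[label]:
            found[label] = best_span

    if set(found) == set(ERV_DOMAIN_THRESHOLDS):
        category = "full_ERV"
    elif found:
        category = "partial_ERV"
    else:
        category = "defective"
    return ScreenResult(
        element_id=element_id, category=category, erv_domains=found, clade=clade
    )


def summarize_screen(
    results: Sequence[ScreenResult], mode: str = "line"
) -> pd.DataFrame:
    """Count table of screening categories, one row per clade.

    Categories partition the input, so each row sums to the number of
    elements screened from that clade.
    """
    categories = LINE_CATEGORIES if mode == "line" else ERV_CATEGORIES
    clades = sorted({r.clade or "all" for r in results}) or ["all"]
    table = pd.DataFrame(0, index=clades, columns=list(categories) + ["total"])
    for r in results:
        clade = r.clade or "all"
        if r.category not in categories:
            raise ValueError(f"unexpected category {r.category!r} for mode {mode!r}")
        table.loc[clade, r.category] += 1
        table.loc[clade, "total"] += 1
    table.index.name = "clade"
    return table
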