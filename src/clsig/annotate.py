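"""V/J germline assignment, somatic-mutation quantification and junction extraction.

Each consensus sequence is aligned against every germline V (and J) segment
with an overlap (free-end-gap) affine alignment; the best-scoring gene wins,
with ties broken by lexicographically smallest gene name. V mutation percent is
computed over the aligned germline V positions up to and including the
conserved 2nd-CYS codon (104): mismatches plus internal indel events (one event
per gap run), divided by aligned germline positions. The junction runs from
codon 104 (mapped through the V alignment) to the J-TRP/PHE codon 118 (mapped
through the J alignment), inclusive. A rearrangement is productive when the
junction length is a multiple of three, both anchors are present (C at 104,
W/F at 118) and the V-frame translation through the junction contains no stop.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align
from Bio.Seq import Seq

from .reference import (
    AnalysisParameters,
    CellFraction,
    GermlineSegment,
    SegmentKind,
)

__all__ = [
    "Rearrangement",
    "AnnotationFailure",
    "FailureReason",
    "MutationStatus",
    "make_aligner",
    "call_v_gene",
    "call_j_gene",
    "call_d_gene",
    "extract_junction",
    "mutation_status",
    "annotate_sequence",
    "annotate_all",
    "write_airr_tsv",
    "read_airr_tsv",
    "ISOTYPE_MOTIFS",
]

# Synthetic constant-region prefix motifs used for isotype tagging in simulated
# amplicons. Exact-prefix matched against the sequence tail; configurable.
ISOTYPE_MOTIFS: dict[str, str] = {
    "IGHM": "CATCCCCGACCAGCCC",
    "IGHD": "CACCCACCAAGGCTCC",
    "IGHG": "CCTCCACCAAGGGCCC",
    "IGHA": "CATCCCCGACCAGCCA",
}


class MutationStatus(str, enum.Enum):
    M = "M"  # mutated, >= threshold
    U = "U"  # unmutated, < threshold


class FailureReason(str, enum.Enum):
    NO_V = "NO_V"
    NO_J = "NO_J"
    NO_JUNCTION = "NO_JUNCTION"


@dataclass(frozen=True)
class AnnotationFailure:
    sequence_id: str
    reason: FailureReason


@dataclass(frozen=True)
class Rearrangement:
    """One annotated IGH rearrangement with cell-fraction metadata.

    Coordinate fields follow the AIRR convention (``v_sequence_start`` etc. are
    0-based half-open here internally; exported TSV uses 1-based closed).
    """

    sequence_id: str
    sequence: str
    v_call: str
    j_call: str
    junction_aa: str
    v_mutation_pct: float
    productive: bool
    fraction: CellFraction
    read_count: int = 1
    d_call: str | None = None
    isotype: str | None = None
    # alignment bookkeeping (needed for chimera construction)
    v_sequence_start: int | None = None
    v_sequence_end: int | None = None
    v_germline_start: int | None = None
    v_germline_end: int | None = None
    junction_start: int | None = None
    junction_end: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.v_mutation_pct <= 100.0:
            raise ValueError("v_mutation_pct outside [0, 100]")

    @property
    def v_identity_pct(self) -> float:
        return 100.0 - self.v_mutation_pct

    @property
    def cdr3_aa(self) -> str:
        return self.junction_aa[1:-1]

    @property
    def cdr3_length(self) -> int:
        return len(self.cdr3_aa)

    def status(self, params: AnalysisParameters | None = None) -> MutationStatus:
        return mutation_status(self.v_mutation_pct, params or AnalysisParameters())


def mutation_status(
    v_mutation_pct: float, params: AnalysisParameters
) -> MutationStatus:
    """Mutated (M) at or above the threshold (default 2%), unmutated (U) below."""
    if not 0.0 <= v_mutation_pct <= 100.0:
        raise ValueError("v_mutation_pct outside [0, 100]")
    return (
        MutationStatus.M
        if v_mutation_pct >= params.mutation_threshold_pct
        else MutationStatus.U
    )


def make_aligner(params: AnalysisParameters) -> Align.PairwiseAligner:
    """Overlap aligner: free end gaps on both sequences, affine internal gaps."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match_score
    aligner.mismatch_score = params.mismatch_score
    aligner.open_gap_score = params.gap_open_score
    aligner.extend_gap_score = params.gap_extend_score
    # free end gaps on both target (germline) and query (read)
    aligner.open_end_insertion_score = 0.0
    aligner.extend_end_insertion_score = 0.0
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    return aligner


@dataclass(frozen=True)
class SegmentAlignment:
    """Best germline-segment alignment of one read."""

    gene_name: str
    score: float
    # aligned blocks: ((germ_start, germ_end), (read_start, read_end)) pairs
    blocks: tuple[tuple[tuple[int, int], tuple[int, int]], ...]
    germ_len: int
    mismatches: int
    indel_events: int
    aligned_germ_positions: int

    @property
    def germ_span(self) -> tuple[int, int]:
        return self.blocks[0][0][0], self.blocks[-1][0][1]

    @property
    def read_span(self) -> tuple[int, int]:
        return self.blocks[0][1][0], self.blocks[-1][1][1]

    @property
    def coverage_pct(self) -> float:
        s, e = self.germ_span
        return 100.0 * (e - s) / self.germ_len

    def map_germ_to_read(self, germ_pos: int) -> int | None:
        """Read coordinate aligned to a 0-based germline coordinate (None if gapped)."""
        for (gs, ge), (rs, re) in self.blocks:
            if gs <= germ_pos < ge:
                return rs + (germ_pos - gs)
        return None


def _align_segment(
    aligner: Align.PairwiseAligner,
    germ: GermlineSegment,
    read: str,
    mutation_cap: int | None = None,
) -> SegmentAlignment:
    aln = aligner.align(germ.sequence, read)[0]
    blocks = tuple(
        ((int(t0), int(t1)), (int(q0), int(q1)))
        for (t0, t1), (q0, q1) in zip(aln.aligned[0], aln.aligned[1])
    )
    cap = mutation_cap if mutation_cap is not None else len(germ.sequence)
    mismatches = 0
    aligned_pos = 0
    for (gs, ge), (rs, _) in blocks:
        for i in range(gs, ge):
            if i >= cap:
                break
            aligned_pos += 1
            if germ.sequence[i] != read[rs + (i - gs)]:
                mismatches += 1
    # internal indel events: one per gap run between consecutive aligned blocks
    indels = 0
    for k in range(1, len(blocks)):
        (pg, pr), (cg, cr) = blocks[k - 1], blocks[k]
        if pg[1] < cap:  # only events inside the counted V region
            indels += int(cg[0] > pg[1]) + int(cr[0] > pr[1])
    return SegmentAlignment(
        gene_name=germ.gene_name,
        score=float(aln.score),
        blocks=blocks,
        germ_len=len(germ.sequence),
        mismatches=mismatches,
        indel_events=indels,
        aligned_germ_positions=aligned_pos,
    )


def _best_segment(
    sequence: str,
    germline: Sequence[GermlineSegment],
    aligner: Align.PairwiseAligner,
) -> GermlineSegment:
    """Best-scoring germline segment; score ties broken by smallest gene name."""
    best: tuple[float, str] | None = None
    best_seg: GermlineSegment | None = None
    for seg in sorted(germline, key=lambda s: s.gene_name):
        score = aligner.score(seg.sequence, sequence)
        key = (score, seg.gene_name)
        if best is None or score > best[0]:
            best, best_seg = key, seg
    assert best_seg is not None
    return best_seg


def call_v_gene(
    sequence: str,
    germline: Sequence[GermlineSegment],
    params: AnalysisParameters | None = None,
) -> tuple[str, SegmentAlignment, float] | AnnotationFailure:
    """Best V gene, its alignment, and the V mutation percent.

    Mutation percent = 100 x (mismatches + indel events) / aligned germline
    positions, counted over the aligned V region through codon 104.
    """
    params = params or AnalysisParameters()
    vs = [g for g in germline if g.segment_kind is SegmentKind.V]
    if not vs:
        raise ValueError("no V segments in germline")
    aligner = make_aligner(params)
    seg = _best_segment(sequence, vs, aligner)
    cap = seg.anchor_ungapped_nt() + 3  # through codon 104 inclusive
    aln = _align_segment(aligner, seg, sequence, mutation_cap=cap)
    if aln.coverage_pct < params.min_v_coverage_pct:
        return AnnotationFailure("", FailureReason.NO_V)
    if aln.aligned_germ_positions == 0:
        return AnnotationFailure("", FailureReason.NO_V)
    mut_pct = 100.0 * (aln.mismatches + aln.indel_events) / aln.aligned_germ_positions
    return seg.gene_name, aln, min(mut_pct, 100.0)


def call_j_gene(
    sequence: str,
    germline: Sequence[GermlineSegment],
    params: AnalysisParameters | None = None,
    search_from: int = 0,
) -> tuple[str, SegmentAlignment] | AnnotationFailure:
    """Best J gene and its alignment over the read region after ``search_from``."""
    params = params or AnalysisParameters()
    js = [g for g in germline if g.segment_kind is SegmentKind.J]
    if not js:
        raise ValueError("no J segments in germline")
    region = sequence[search_from:]
    if not region:
        return AnnotationFailure("", FailureReason.NO_J)
    aligner = make_aligner(params)
    seg = _best_segment(region, js, aligner)
    aln = _align_segment(aligner, seg, region)
    if search_from:
        aln = SegmentAlignment(
            gene_name=aln.gene_name,
            score=aln.score,
            blocks=tuple(
                ((gs, ge), (rs + search_from, re + search_from))
                for (gs, ge), (rs, re) in aln.blocks
            ),
            germ_len=aln.germ_len,
            mismatches=aln.mismatches,
            indel_events=aln.indel_events,
            aligned_germ_positions=aln.aligned_germ_positions,
        )
    # require the anchor codon to be covered and at least a minimal overlap
    if aln.aligned_germ_positions < 9:
        return AnnotationFailure("", FailureReason.NO_J)
    return seg.gene_name, aln


def call_d_gene(
    junction_nt: str, germline: Sequence[GermlineSegment], min_len: int = 5
) -> str | None:
    """Optional D call: longest exact germline-D substring (>= min_len) in the junction."""
    best: tuple[int, str] | None = None
    for seg in sorted(
        (g for g in germline if g.segment_kind is SegmentKind.D),
        key=lambda s: s.gene_name,
    ):
        d = seg.sequence
        hit = 0
        for L in range(len(d), min_len - 1, -1):
            if hit:
                break
            for s in range(0, len(d) - L + 1):
                if d[s : s + L] in junction_nt:
                    hit = L
                    break
        if hit >= min_len and (best is None or hit > best[0]):
            best = (hit, seg.gene_name)
    return best[1] if best else None


def extract_junction(
    sequence: str,
    v_seg: GermlineSegment,
    v_aln: SegmentAlignment,
    j_seg: GermlineSegment,
    j_aln: SegmentAlignment,
) -> tuple[str, str, bool, int, int] | AnnotationFailure:
    """Junction amino acids, CDR3, productivity and junction read coordinates.

    The junction spans the codon aligned to the V anchor (2nd-CYS, codon 104)
    through the codon aligned to the J anchor (J-TRP/PHE), inclusive.
    """
    v_anchor_read = v_aln.map_germ_to_read(v_seg.anchor_ungapped_nt())
    j_anchor_read = j_aln.map_germ_to_read(j_seg.anchor_ungapped_nt())
    if v_anchor_read is None or j_anchor_read is None:
        return AnnotationFailure("", FailureReason.NO_JUNCTION)
    jstart, jend = v_anchor_read, j_anchor_read + 3
    if jend <= jstart or jend > len(sequence):
        return AnnotationFailure("", FailureReason.NO_JUNCTION)
    junction_nt = sequence[jstart:jend]
    in_frame = len(junction_nt) % 3 == 0
    if not in_frame:
        # translate what we can for reporting; productivity is false
        junction_aa = str(Seq(junction_nt[: 3 * (len(junction_nt) // 3)]).translate())
    else:
        junction_aa = str(Seq(junction_nt).translate())
    anchors_ok = bool(
        junction_aa and junction_aa[0] == "C" and junction_aa[-1] in "WF"
    )
    # V-frame translation from the start of the aligned V region through the
    # junction end: no stop codon anywhere for a productive rearrangement
    v_read_start = v_aln.read_span[0]
    frame_start = v_read_start + ((jstart - v_read_start) % 3)
    vframe = sequence[frame_start : frame_start + 3 * ((jend - frame_start) // 3)]
    no_stop = "*" not in str(Seq(vframe).translate())
    productive = in_frame and anchors_ok and no_stop
    return junction_aa, junction_aa[1:-1], productive, jstart, jend


def _detect_isotype(sequence: str) -> str | None:
    tail = sequence[-60:]
    for iso, motif in ISOTYPE_MOTIFS.items():
        if motif in tail:
            return iso
    return None


def annotate_sequence(
    sequence_id: str,
    sequence: str,
    germline: Sequence[GermlineSegment],
    fraction: CellFraction,
    read_count: int = 1,
    params: AnalysisParameters | None = None,
) -> Rearrangement | AnnotationFailure:
    """Full annotation of one consensus sequence against a germline set."""
    params = params or AnalysisParameters()
    sequence = sequence.upper()
    v_res = call_v_gene(sequence, germline, params)
    if isinstance(v_res, AnnotationFailure):
        return AnnotationFailure(sequence_id, v_res.reason)
    v_call, v_aln, v_mut = v_res
    v_seg = next(g for g in germline if g.gene_name == v_call)
    anchor_read = v_aln.map_germ_to_read(v_seg.anchor_ungapped_nt())
    search_from = (anchor_read + 3) if anchor_read is not None else v_aln.read_span[1]
    j_res = call_j_gene(sequence, germline, params, search_from=search_from)
    if isinstance(j_res, AnnotationFailure):
        return AnnotationFailure(sequence_id, j_res.reason)
    j_call, j_aln = j_res
    j_seg = next(g for g in germline if g.gene_name == j_call)
    junc = extract_junction(sequence, v_seg, v_aln, j_seg, j_aln)
    if isinstance(junc, AnnotationFailure):
        return AnnotationFailure(sequence_id, junc.reason)
    junction_aa, _, productive, jstart, jend = junc
    d_call = call_d_gene(sequence[jstart:jend], germline)
    return Rearrangement(
        sequence_id=sequence_id,
        sequence=sequence,
        v_call=v_call,
        j_call=j_call,
        d_call=d_call,
        junction_aa=junction_aa,
        v_mutation_pct=v_mut,
        productive=productive,
        fraction=fraction,
        read_count=read_count,
        isotype=_detect_isotype(sequence),
        v_sequence_start=v_aln.read_span[0],
        v_sequence_end=v_aln.read_span[1],
        v_germline_start=v_aln.germ_span[0],
        v_germline_end=v_aln.germ_span[1],
        junction_start=jstart,
        junction_end=jend,
    )


def annotate_all(
    consensuses,
    germline: Sequence[GermlineSegment],
    params: AnalysisParameters | None = None,
) -> tuple[list[Rearrangement], list[AnnotationFailure]]:
    """Annotate consensus sequences; returns (annotated, failures)."""
    params = params or AnalysisParameters()
    ok: list[Rearrangement] = []
    bad: list[AnnotationFailure] = []
    for i, c in enumerate(consensuses):
        res = annotate_sequence(
            sequence_id=f"{c.umi}",
            sequence=c.sequence,
            germline=germline,
            fraction=c.fraction,
            read_count=c.read_count,
            params=params,
        )
        (ok if isinstance(res, Rearrangement) else bad).append(res)
    return ok, bad


AIRR_COLUMNS = [
    "sequence_id",
    "sequence",
    "v_call",
    "d_call",
    "j_call",
    "junction_aa",
    "cdr3_aa",
    "v_identity",
    "productive",
    "duplicate_count",
    "isotype",
    "donor_id",
    "cd5",
    "light_chain",
    "b_subset",
]


def write_airr_tsv(rearrangements: Iterable[Rearrangement], path: str | Path) -> None:
    """AIRR Rearrangement TSV (standard columns plus cell-fraction metadata)."""
    rows = []
    for r in rearrangements:
        d, cd5, lc, bs = r.fraction.key()
        rows.append(
            {
                "sequence_id": r.sequence_id,
                "sequence": r.sequence,
                "v_call": r.v_call,
                "d_call": r.d_call or "",
                "j_call": r.j_call,
                "junction_aa": r.junction_aa,
                "cdr3_aa": r.cdr3_aa,
                "v_identity": round(r.v_identity_pct / 100.0, 6),
                "productive": "T" if r.productive else "F",
                "duplicate_count": r.read_count,
                "isotype": r.isotype or "",
                "donor_id": d,
                "cd5": cd5,
                "light_chain": lc,
                "b_subset": bs,
            }
        )
    pd.DataFrame(rows, columns=AIRR_COLUMNS).to_csv(path, sep="\t", index=False)


def read_airr_tsv(path: str | Path) -> pd.DataFrame:
    """Read an AIRR Rearrangement TSV produced by this package (or compatible).

    Returns a DataFrame with at least v_call, j_call, cdr3_aa, v_identity,
    productive, duplicate_count and the four cell-fraction columns; adds
    derived columns v_mutation_pct and mut_status.
    """
    df = pd.read_csv(path, sep="\t", dtype={"donor_id": str})
    needed = {"sequence_id", "v_call", "j_call", "productive", "donor_id"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"AIRR TSV missing columns: {sorted(missing)}")
    if "cdr3_aa" not in df.columns:
        df["cdr3_aa"] = df["junction_aa"].str[1:-1]
    df["productive"] = df["productive"].astype(str).str.upper().isin(["T", "TRUE", "1"])
    if "v_mutation_pct" not in df.columns:
        df["v_mutation_pct"] = 100.0 * (1.0 - df["v_identity"].astype(float))
    if "duplicate_count" not in df.columns:
        df["duplicate_count"] = 1
    return df
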