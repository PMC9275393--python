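"""UMI grouping and consensus building.

A sequenced molecule is identified by its unique molecular identifier (UMI)
within one sorted cell fraction. Reads sharing a (UMI, fraction) key are
collapsed to a per-position plurality consensus; a consensus passes the quality
filter only if it derives from at least ``min_reads_per_umi`` raw reads and
contains no ambiguous base. Positional ties are never silently resolved: they
emit N, and the no-N rule then rejects the group.
"""

from __future__ import annotations

import enum
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .reference import AnalysisParameters, CellFraction

__all__ = [
    "RawRead",
    "ConsensusSequence",
    "Rejection",
    "RejectionReason",
    "group_by_umi",
    "build_consensus",
    "consensus_pass",
    "read_fastq_with_umi",
    "read_samplesheet",
    "write_consensus_fasta",
    "write_rejection_log",
]

UMI_MIN_LEN = 14
UMI_MAX_LEN = 16


@dataclass(frozen=True)
class RawRead:
    """One raw amplicon read carrying its UMI and sort-fraction metadata."""

    read_id: str
    umi: str
    sequence: str
    fraction: CellFraction
    qualities: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not (UMI_MIN_LEN <= len(self.umi) <= UMI_MAX_LEN):
            raise ValueError(
                f"read {self.read_id}: UMI length {len(self.umi)} outside "
                f"[{UMI_MIN_LEN}, {UMI_MAX_LEN}]"
            )
        if not self.sequence:
            raise ValueError(f"read {self.read_id}: empty sequence")


@dataclass(frozen=True)
class ConsensusSequence:
    """Quality-passing consensus of one UMI group (>=2 reads, no N)."""

    umi: str
    sequence: str
    read_count: int
    fraction: CellFraction

    def __post_init__(self) -> None:
        if "N" in self.sequence:
            raise ValueError("consensus must not contain N")
        if self.read_count < 2:
            raise ValueError("consensus requires at least two reads")


class RejectionReason(str, enum.Enum):
    TOO_FEW_READS = "TOO_FEW_READS"
    AMBIGUOUS_POSITION = "AMBIGUOUS_POSITION"
    N_IN_CONSENSUS = "N_IN_CONSENSUS"


@dataclass(frozen=True)
class Rejection:
    umi: str
    fraction: CellFraction
    reason: RejectionReason
    read_count: int


GroupKey = tuple[str, tuple[str, str, str, str]]


def group_by_umi(reads: Iterable[RawRead]) -> dict[GroupKey, list[RawRead]]:
    """Partition reads by (UMI, fraction); UMIs are never merged across fractions."""
    groups: dict[GroupKey, list[RawRead]] = defaultdict(list)
    for r in reads:
        groups[(r.umi, r.fraction.key())].append(r)
    return dict(groups)


def build_consensus(
    group: Sequence[RawRead], params: AnalysisParameters | None = None
) -> ConsensusSequence | Rejection:
    """Plurality consensus of one UMI group, or a structured rejection.

    Reads whose length deviates from the group's modal length by more than
    ``params.length_outlier_frac`` are dropped before voting (guards against
    truncated/chimeric reads). Votes are per position over reads of the modal
    length window; any tie yields N and the group is rejected.
    """
    params = params or AnalysisParameters()
    if not group:
        raise ValueError("empty UMI group")
    umi = group[0].umi
    frac = group[0].fraction
    if any(r.umi != umi or r.fraction != frac for r in group):
        raise ValueError("all reads in a group must share UMI and fraction")

    lengths = Counter(len(r.sequence) for r in group)
    modal_len = max(lengths, key=lambda L: (lengths[L], L))
    tol = params.length_outlier_frac * modal_len
    voters = [r for r in group if abs(len(r.sequence) - modal_len) <= tol]

    if len(voters) < params.min_reads_per_umi:
        return Rejection(umi, frac, RejectionReason.TOO_FEW_READS, len(group))

    consensus = []
    ambiguous = False
    for pos in range(modal_len):
        votes = Counter(
            r.sequence[pos] for r in voters if pos < len(r.sequence)
        )
        best = votes.most_common()
        if len(best) > 1 and best[0][1] == best[1][1]:
            consensus.append("N")
            ambiguous = True
        else:
            consensus.append(best[0][0])
    seq = "".join(consensus)
    if ambiguous:
        return Rejection(umi, frac, RejectionReason.AMBIGUOUS_POSITION, len(group))
    if "N" in seq:  # N carried over from a unanimous N in the raw reads
        return Rejection(umi, frac, RejectionReason.N_IN_CONSENSUS, len(group))
    return ConsensusSequence(umi=umi, sequence=seq, read_count=len(voters), fraction=frac)


def consensus_pass(
    reads: Iterable[RawRead], params: AnalysisParameters | None = None
) -> tuple[list[ConsensusSequence], list[Rejection]]:
    """Group reads by UMI and build all consensuses; conservation holds:
    len(kept) + len(rejected) == number of UMI groups."""
    params = params or AnalysisParameters()
    kept: list[ConsensusSequence] = []
    rejected: list[Rejection] = []
    for grp in group_by_umi(reads).values():
        res = build_consensus(grp, params)
        if isinstance(res, ConsensusSequence):
            kept.append(res)
        else:
            rejected.append(res)
    return kept, rejected


def read_samplesheet(path: str | Path) -> dict[str, CellFraction]:
    """Samplesheet TSV: columns file, donor_id, cd5, light_chain, b_subset."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"file", "donor_id", "cd5", "light_chain", "b_subset"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"samplesheet missing columns: {sorted(missing)}")
    return {
        row["file"]: CellFraction(
            donor_id=row["donor_id"],
            cd5=row["cd5"],
            light_chain=row["light_chain"],
            b_subset=row["b_subset"],
        )
        for _, row in df.iterrows()
    }


def read_fastq_with_umi(
    path: str | Path,
    fraction: CellFraction,
    umi_location: str = "header",
) -> list[RawRead]:
    """Read a FASTQ whose UMI is in a ``UMI=<seq>`` header tag or a fixed prefix.

    ``umi_location``: ``"header"`` or ``"prefix:<k>"`` (first k bases are the UMI
    and are stripped from the sequence).
    """
    reads: list[RawRead] = []
    prefix_k: int | None = None
    if umi_location.startswith("prefix:"):
        prefix_k = int(umi_location.split(":", 1)[1])
    elif umi_location != "header":
        raise ValueError(f"unknown umi_location {umi_location!r}")
    for rec in SeqIO.parse(str(path), "fastq"):
        seq = str(rec.seq).upper()
        if prefix_k is not None:
            umi, seq = seq[:prefix_k], seq[prefix_k:]
        else:
            umi = ""
            for token in rec.description.split():
                if token.startswith("UMI="):
                    umi = token[4:]
                    break
            if not umi:
                raise ValueError(f"{path}: read {rec.id} lacks a UMI= header tag")
        quals = tuple(rec.letter_annotations.get("phred_quality", ()))
        reads.append(
            RawRead(
                read_id=rec.id,
                umi=umi,
                sequence=seq,
                fraction=fraction,
                qualities=quals or None,
            )
        )
    return reads


def write_consensus_fasta(
    consensuses: Iterable[ConsensusSequence], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for c in consensuses:
            d, cd5, lc, bs = c.fraction.key()
            fh.write(
                f">{c.umi}|reads={c.read_count}|donor={d}|cd5={cd5}|lc={lc}|bsub={bs}\n"
            )
            fh.write(c.sequence + "\n")


def write_rejection_log(rejections: Iterable[Rejection], path: str | Path) -> None:
    rows = [
        {
            "umi": r.umi,
            "donor_id": r.fraction.donor_id,
            "reason": r.reason.value,
            "read_count": r.read_count,
        }
        for r in rejections
    ]
    pd.DataFrame(rows, columns=["umi", "donor_id", "reason", "read_count"]).to_csv(
        path, sep="\t", index=False
    )
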