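"""Germline reference model, IGHV clan table, cell-fraction metadata and analysis parameters.

The germline reference is a set of named IGHV/IGHD/IGHJ segments. V segments are
stored both IMGT-gapped (``.`` for gaps, so the conserved 2nd-CYS sits at codon
104 of the gapped frame) and ungapped. IGHV families are grouped into the three
phylogenetic clans (I: IGHV1/5/7, II: IGHV2/4/6, III: IGHV3), which is one of
the core features used for stereotyped-subset assignment.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from importlib import resources as _ilres
from pathlib import Path
from typing import Iterable, Mapping

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentKind",
    "Clan",
    "CD5Status",
    "LightChain",
    "BSubset",
    "Confidence",
    "CellFraction",
    "GermlineSegment",
    "ClanTable",
    "AnalysisParameters",
    "ReferenceError",
    "GermlineParseError",
    "read_germline_fasta",
    "write_germline_fasta",
    "clan_of",
    "family_of",
    "gene_of",
    "default_clan_table",
    "toy_germline_path",
]

V_ANCHOR_CODON = 104  # conserved 2nd-CYS, IMGT numbering
J_ANCHOR_CODON = 118  # conserved J-TRP/J-PHE, IMGT numbering


class ReferenceError(ValueError):
    """A gene/family cannot be resolved against the reference resources."""


class GermlineParseError(ValueError):
    """Malformed germline FASTA input."""


class SegmentKind(str, enum.Enum):
    V = "V"
    D = "D"
    J = "J"


class Clan(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"


class CD5Status(str, enum.Enum):
    POS = "POS"
    NEG = "NEG"


class LightChain(str, enum.Enum):
    KAPPA = "KAPPA"
    LAMBDA = "LAMBDA"


class BSubset(str, enum.Enum):
    TR = "TR"   # transitional
    N = "N"     # naive
    MZ = "MZ"   # marginal-zone-like
    MO = "MO"   # IgM-only memory
    SM = "SM"   # switched memory
    DN = "DN"   # double negative


class Confidence(enum.IntEnum):
    """Ordinal confidence scale for stereotyped-subset assignment."""

    NONE = 0
    BORDERLINE = 1
    AVERAGE = 2
    GOOD = 3
    EXCELLENT = 4

    @classmethod
    def from_string(cls, s: str) -> "Confidence":
        return cls[s.strip().upper()]


@dataclass(frozen=True)
class CellFraction:
    """One sorted cell fraction: donor x CD5 x light chain x B-cell subset."""

    donor_id: str
    cd5: CD5Status
    light_chain: LightChain
    b_subset: BSubset

    def __post_init__(self) -> None:
        if not self.donor_id:
            raise ValueError("donor_id must be a nonempty string")
        # accept plain strings for convenience
        object.__setattr__(self, "cd5", CD5Status(self.cd5))
        object.__setattr__(self, "light_chain", LightChain(self.light_chain))
        object.__setattr__(self, "b_subset", BSubset(self.b_subset))

    def key(self) -> tuple[str, str, str, str]:
        return (self.donor_id, self.cd5.value, self.light_chain.value, self.b_subset.value)


_GENE_RE = re.compile(r"^(IGH[VDJ])(\d+)")


def family_of(gene_name: str) -> str:
    """IMGT family prefix of a gene name, e.g. ``IGHV1-69`` -> ``IGHV1``."""
    m = _GENE_RE.match(gene_name)
    if not m:
        raise ReferenceError(f"cannot parse IMGT gene name: {gene_name!r}")
    return m.group(1) + m.group(2)


def gene_of(call: str) -> str:
    """Gene-level name of a V/D/J call: allele suffix (``*01``) stripped."""
    return call.split("*", 1)[0].strip()


@dataclass(frozen=True)
class ClanTable:
    """Total mapping of IGHV family -> phylogenetic clan."""

    mapping: Mapping[str, Clan]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "mapping", {str(k): Clan(v) for k, v in dict(self.mapping).items()}
        )

    def clan_of_family(self, family: str) -> Clan:
        try:
            return self.mapping[family]
        except KeyError:
            raise ReferenceError(f"IGHV family {family!r} absent from clan table") from None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClanTable":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(mapping=data["clans"])


def clan_of(gene_name: str, table: ClanTable) -> Clan:
    """Clan of an IGHV gene (allele suffixes tolerated)."""
    return table.clan_of_family(family_of(gene_of(gene_name)))


def default_clan_table() -> ClanTable:
    """Standard clan assignment: families 1/5/7 -> I, 2/4/6 -> II, 3 -> III."""
    return ClanTable.from_yaml(_resource_path("clans.yaml"))


def _resource_path(name: str) -> Path:
    return Path(str(_ilres.files("clsig").joinpath("resources", name)))


def toy_germline_path() -> Path:
    """Bundled synthetic toy germline FASTA (IMGT-style names, synthetic sequences)."""
    return _resource_path("germline_toy_synthetic.fasta")


@dataclass(frozen=True)
class GermlineSegment:
    """One named germline segment with clan and anchor annotation.

    ``gapped_sequence`` is IMGT-gapped for V segments (``.`` for gaps) and equal
    to ``sequence`` otherwise. ``anchor_codon`` is the 1-based codon index of
    the conserved 2nd-CYS (V, gapped frame) or J-TRP/J-PHE (J, segment frame).
    """

    gene_name: str
    segment_kind: SegmentKind
    sequence: str
    gapped_sequence: str
    anchor_codon: int | None = None
    clan: Clan | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "segment_kind", SegmentKind(self.segment_kind))
        if self.gapped_sequence.replace(".", "") != self.sequence:
            raise GermlineParseError(
                f"{self.gene_name}: gapped sequence does not strip to ungapped sequence"
            )
        if set(self.sequence) - set("ACGT"):
            raise GermlineParseError(f"{self.gene_name}: non-ACGT characters in sequence")

    @property
    def family(self) -> str:
        return family_of(self.gene_name)

    def anchor_ungapped_nt(self) -> int:
        """0-based nt offset of the anchor codon start in the ungapped sequence."""
        if self.anchor_codon is None:
            raise ValueError(f"{self.gene_name} has no anchor")
        if self.segment_kind is SegmentKind.V:
            gapped_start = 3 * (self.anchor_codon - 1)
            return gapped_start - self.gapped_sequence[:gapped_start].count(".")
        return 3 * (self.anchor_codon - 1)


def _translate_gapped_codon(gapped: str, codon_1based: int) -> str:
    """Amino acid at a 1-based codon of a gapped sequence ('' if gapped there)."""
    codon = gapped[3 * (codon_1based - 1): 3 * codon_1based]
    if len(codon) < 3 or "." in codon:
        return ""
    return str(Seq(codon).translate())


def _locate_v_anchor(gapped: str) -> int | None:
    """V anchor: the conserved Cys at IMGT codon 104 of the gapped frame."""
    if _translate_gapped_codon(gapped, V_ANCHOR_CODON) == "C":
        return V_ANCHOR_CODON
    return None


def _locate_j_anchor(seq: str) -> int | None:
    """J anchor: first W/F that starts the FR4 (W/F-G-x-G) motif, in the segment frame.

    Returns the 1-based codon index within the J segment, or None.
    """
    n_codons = len(seq) // 3
    aa = str(Seq(seq[: 3 * n_codons]).translate())
    for i, res in enumerate(aa):
        if res in "WF" and i + 3 < len(aa) and aa[i + 1] == "G" and aa[i + 3] == "G":
            return i + 1
    return None


def read_germline_fasta(
    path: str | Path, clan_table: ClanTable
) -> list[GermlineSegment]:
    """Parse a germline FASTA with headers ``><gene_name>|<segment_kind>``.

    V records must be IMGT-gapped (dots as gaps) with the conserved Cys at codon
    104; every V family must resolve in the clan table.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    segments: list[GermlineSegment] = []
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        logger.warning("germline FASTA %s contains no records", path)
        return segments
    for rec in records:
        parts = rec.id.split("|")
        if len(parts) < 2 or parts[1] not in ("V", "D", "J"):
            raise GermlineParseError(
                f"{path}: header {rec.id!r} is not '<gene_name>|<V/D/J>'"
            )
        gene, kind = parts[0], SegmentKind(parts[1])
        gapped = str(rec.seq).upper()
        ungapped = gapped.replace(".", "")
        anchor: int | None = None
        clan: Clan | None = None
        if kind is SegmentKind.V:
            clan = clan_of(gene, clan_table)  # raises ReferenceError if unknown
            anchor = _locate_v_anchor(gapped)
            if anchor is None:
                raise GermlineParseError(
                    f"{gene}: no conserved Cys at IMGT codon {V_ANCHOR_CODON}"
                )
        elif kind is SegmentKind.J:
            anchor = _locate_j_anchor(ungapped)
            if anchor is None:
                raise GermlineParseError(f"{gene}: no J-TRP/PHE (W/F-G-x-G) anchor found")
            gapped = ungapped
        else:
            gapped = ungapped
        segments.append(
            GermlineSegment(
                gene_name=gene,
                segment_kind=kind,
                sequence=ungapped,
                gapped_sequence=gapped,
                anchor_codon=anchor,
                clan=clan,
            )
        )
    return segments


def write_germline_fasta(segments: Iterable[GermlineSegment], path: str | Path) -> None:
    """Inverse of :func:`read_germline_fasta` (round-trip safe)."""
    recs = [
        SeqRecord(
            Seq(s.gapped_sequence),
            id=f"{s.gene_name}|{s.segment_kind.value}",
            description="",
        )
        for s in segments
    ]
    SeqIO.write(recs, str(path), "fasta")


_CONFIDENCE_ORDER = "confidence drawn from NONE<BORDERLINE<AVERAGE<GOOD<EXCELLENT"


@dataclass(frozen=True)
class AnalysisParameters:
    """Global thresholds of the analysis.

    mutation_threshold_pct
        V-gene mutation percent separating unmutated (U, below) from mutated
        (M, at or above). Default 2.0.
    min_reads_per_umi
        Minimum raw reads per UMI group for a consensus to pass. Default 2.
    identity_threshold_pct / similarity_threshold_pct
        CDR3 amino-acid identity / physicochemical similarity gates for
        stereotyped-subset membership. Defaults 50.0 / 70.0.
    min_clsig_for_frequency
        Minimum stereotyped clonotypes in a stratum for its frequency to be
        informative. Default 2.
    min_donors_for_test
        Minimum complete donor pairs for a paired test. Default 3.
    min_confidence
        Minimum assignment confidence to call a clonotype CLS-IG. Default AVERAGE.
    """

    mutation_threshold_pct: float = 2.0
    min_reads_per_umi: int = 2
    identity_threshold_pct: float = 50.0
    similarity_threshold_pct: float = 70.0
    min_clsig_for_frequency: int = 2
    min_donors_for_test: int = 3
    min_confidence: Confidence = Confidence.AVERAGE
    # alignment scoring (exposed for reproducibility)
    match_score: float = 1.0
    mismatch_score: float = -1.0
    gap_open_score: float = -4.0
    gap_extend_score: float = -1.0
    min_v_coverage_pct: float = 50.0
    length_outlier_frac: float = 0.10

    def __post_init__(self) -> None:
        if isinstance(self.min_confidence, str):
            object.__setattr__(
                self, "min_confidence", Confidence.from_string(self.min_confidence)
            )
        for name in (
            "mutation_threshold_pct",
            "min_reads_per_umi",
            "identity_threshold_pct",
            "similarity_threshold_pct",
            "min_clsig_for_frequency",
            "min_donors_for_test",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisParameters":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data.get("parameters", data))
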