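"""Stereotyped-subset assignment, reverse-status chimeras, and typicality.

A CLL stereotyped subset is defined by core features (IGHV clan, IGHV
mutational status, CDR3 length) plus a set of reference CDR3s and an anchored
motif. A clonotype is assigned when, against some eligible subset, its CDR3
reaches >=50% amino-acid identity and >=70% physicochemical similarity to a
reference CDR3 and carries the subset motif at its stated offset. Assignments
are graded on an ordinal confidence scale and reported only at "average" or
higher (configurable); assigned clonotypes are the CLS-IG of the analysis.

The reverse-chimera construction (rCLS-IG) swaps the V region of a
rearrangement for one of the opposite mutational status, leaving the junction
amino acids untouched, to probe whether stereotypy assignment depends on the
mutational status core feature.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotate import (
    AnnotationFailure,
    Rearrangement,
    annotate_sequence,
    call_v_gene,
    mutation_status,
    MutationStatus,
)
from .clonotype import Clonotype
from .reference import (
    AnalysisParameters,
    Clan,
    ClanTable,
    Confidence,
    GermlineSegment,
    LightChain,
    ReferenceError,
    clan_of,
    gene_of,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RESIDUE_CLASSES",
    "ResidueClassTable",
    "MotifPattern",
    "SubsetDefinition",
    "SubsetAssignment",
    "CoreMutStatus",
    "Typicality",
    "load_subset_definitions",
    "synthetic_subsets_path",
    "major_subsets_path",
    "prefilter_core",
    "cdr3_identity_pct",
    "cdr3_similarity_pct",
    "pattern_matches",
    "grade_confidence",
    "assign_subset",
    "assign_frame",
    "classify_typicality",
    "make_reverse_chimera",
    "rclsig_scan",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# Default six-class physicochemical scheme (total and disjoint over the 20
# standard residues); identity implies shared class, so similarity >= identity.
RESIDUE_CLASSES: dict[str, frozenset[str]] = {
    "aliphatic": frozenset("AILMV"),
    "aromatic": frozenset("FWY"),
    "polar": frozenset("NQST"),
    "positive": frozenset("HKR"),
    "negative": frozenset("DE"),
    "special": frozenset("CGP"),
}


@dataclass(frozen=True)
class ResidueClassTable:
    """Total, disjoint mapping residue -> physicochemical class."""

    classes: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(RESIDUE_CLASSES)
    )

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, members in self.classes.items():
            if seen & members:
                raise ValueError(f"class {name} overlaps another class")
            seen |= members
        if seen != set(AA_ALPHABET):
            raise ValueError("classes must cover exactly the 20 standard residues")

    def class_of(self, residue: str) -> str:
        for name, members in self.classes.items():
            if residue in members:
                return name
        raise KeyError(f"unknown residue {residue!r}")

    def same_class(self, a: str, b: str) -> bool:
        return self.class_of(a) == self.class_of(b)

    def lut(self) -> np.ndarray:
        """uint8 lookup table over ASCII codes: residue -> class index (255 unknown)."""
        table = np.full(128, 255, dtype=np.uint8)
        for idx, (_, members) in enumerate(sorted(self.classes.items())):
            for r in members:
                table[ord(r)] = idx
        return table

    def members_of(self, name: str) -> frozenset[str]:
        return self.classes[name]


class CoreMutStatus(str, enum.Enum):
    U = "U"
    M = "M"
    EITHER = "EITHER"

    def matches(self, status: MutationStatus) -> bool:
        return self is CoreMutStatus.EITHER or self.value == status.value


class Typicality(str, enum.Enum):
    TYPICAL = "TYPICAL"
    NON_TYPICAL = "NON_TYPICAL"
    NA = "NA"


@dataclass(frozen=True)
class MotifPattern:
    """Anchored per-position motif within the CDR3.

    Each element is a residue-class name, a literal residue, or ``x`` (any);
    the motif is matched at ``offset`` (0-based) within the CDR3.
    """

    offset: int
    motif: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.offset < 0 or not self.motif:
            raise ValueError("pattern needs offset >= 0 and a nonempty motif")
        object.__setattr__(self, "motif", tuple(self.motif))


def pattern_matches(
    cdr3: str, pattern: MotifPattern, classes: ResidueClassTable
) -> bool:
    """True iff every motif position is satisfied at the pattern's offset."""
    if pattern.offset + len(pattern.motif) > len(cdr3):
        return False
    for i, elem in enumerate(pattern.motif):
        res = cdr3[pattern.offset + i]
        if elem in ("x", "X", "any"):
            continue
        if elem in classes.classes:
            if res not in classes.members_of(elem):
                return False
        elif res != elem:
            return False
    return True


@dataclass(frozen=True)
class SubsetDefinition:
    """Core features and reference CDR3s of one CLL stereotyped subset."""

    subset_id: str
    clan: Clan
    core_mut_status: CoreMutStatus
    cdr3_length: int
    reference_cdr3s: tuple[str, ...]
    pattern: MotifPattern
    typical_v_genes: frozenset[str]
    cll_reference_freq: float
    predominant_v_gene: str | None = None
    light_chain_bias: LightChain | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "clan", Clan(self.clan))
        object.__setattr__(self, "core_mut_status", CoreMutStatus(self.core_mut_status))
        object.__setattr__(self, "reference_cdr3s", tuple(self.reference_cdr3s))
        object.__setattr__(self, "typical_v_genes", frozenset(self.typical_v_genes))
        if not self.reference_cdr3s:
            raise ValueError(f"{self.subset_id}: needs at least one reference CDR3")
        for ref in self.reference_cdr3s:
            if len(ref) != self.cdr3_length:
                raise ValueError(
                    f"{self.subset_id}: reference CDR3 {ref} length != {self.cdr3_length}"
                )
        if not 0.0 <= self.cll_reference_freq <= 1.0:
            raise ValueError(f"{self.subset_id}: cll_reference_freq outside [0,1]")
        if (
            self.predominant_v_gene is not None
            and self.predominant_v_gene not in self.typical_v_genes
        ):
            raise ValueError(
                f"{self.subset_id}: predominant gene not among typical genes"
            )
        if self.pattern.offset + len(self.pattern.motif) > self.cdr3_length:
            raise ValueError(f"{self.subset_id}: pattern exceeds CDR3 length")

    def validate_against(self, clans: ClanTable) -> None:
        for g in self.typical_v_genes:
            if clan_of(g, clans) is not self.clan:
                raise ReferenceError(
                    f"{self.subset_id}: typical gene {g} outside clan {self.clan.value}"
                )


def load_subset_definitions(
    path: str | Path, clans: ClanTable | None = None
) -> list[SubsetDefinition]:
    """Load subset definitions from the versioned YAML resource format."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    defs: list[SubsetDefinition] = []
    for entry in data["subsets"]:
        pat = entry["pattern"]
        d = SubsetDefinition(
            subset_id=str(entry["subset_id"]),
            clan=entry["clan"],
            core_mut_status=entry["core_mut_status"],
            cdr3_length=int(entry["cdr3_length"]),
            reference_cdr3s=tuple(entry["reference_cdr3s"]),
            pattern=MotifPattern(offset=int(pat["offset"]), motif=tuple(pat["motif"])),
            typical_v_genes=frozenset(entry["typical_v_genes"]),
            predominant_v_gene=entry.get("predominant_v_gene"),
            cll_reference_freq=float(entry["cll_reference_freq"]),
            light_chain_bias=(
                LightChain(entry["light_chain_bias"])
                if entry.get("light_chain_bias") not in (None, "NONE")
                else None
            ),
        )
        if clans is not None:
            d.validate_against(clans)
        defs.append(d)
    ids = [d.subset_id for d in defs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subset ids in definition file")
    return defs


def synthetic_subsets_path() -> Path:
    from .reference import _resource_path

    return _resource_path("subsets_synthetic.yaml")


def major_subsets_path() -> Path:
    """Best-effort curated major-subset resource (synthetic CDR3 exemplars)."""
    from .reference import _resource_path

    return _resource_path("subsets_major_approx.yaml")


@dataclass(frozen=True)
class SubsetAssignment:
    """Outcome of stereotyped-subset assignment for one clonotype."""

    clonotype_id: str
    subset_id: str | None
    confidence: Confidence
    best_identity_pct: float | None = None
    best_similarity_pct: float | None = None
    pattern_matched: bool = False
    typicality: Typicality = Typicality.NA
    ambiguous: bool = False

    @property
    def assigned(self) -> bool:
        return self.subset_id is not None


# ---------------------------------------------------------------------------
# elementary comparisons


def cdr3_identity_pct(a: str, b: str) -> float:
    """Percent of positions with identical residues (equal lengths required)."""
    if len(a) != len(b):
        raise ValueError("CDR3 identity requires equal lengths")
    if not a:
        return 0.0
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


def cdr3_similarity_pct(
    a: str, b: str, classes: ResidueClassTable | None = None
) -> float:
    """Percent of positions whose residues share a physicochemical class."""
    if len(a) != len(b):
        raise ValueError("CDR3 similarity requires equal lengths")
    classes = classes or ResidueClassTable()
    if not a:
        return 0.0
    return (
        100.0
        * sum(classes.class_of(x) == classes.class_of(y) for x, y in zip(a, b))
        / len(a)
    )


def _clonotype_features(
    clonotype, params: AnalysisParameters
) -> tuple[str, str, MutationStatus, str]:
    """(clonotype_id, v_gene, mutation status, cdr3) from a Clonotype or record."""
    if isinstance(clonotype, Clonotype):
        rep = clonotype.representative
        return (
            clonotype.clonotype_id,
            clonotype.v_gene,
            rep.status(params),
            clonotype.cdr3_aa,
        )
    # duck-typed record (e.g. pandas row / namespace)
    return (
        str(clonotype.clonotype_id),
        gene_of(str(clonotype.v_gene)),
        mutation_status(float(clonotype.v_mutation_pct), params),
        str(clonotype.cdr3_aa),
    )


def prefilter_core(
    clonotype,
    d: SubsetDefinition,
    clans: ClanTable,
    params: AnalysisParameters | None = None,
) -> bool:
    """Core-feature prefilter: same IGHV clan, compatible mutational status,
    identical CDR3 length."""
    params = params or AnalysisParameters()
    _, v_gene, status, cdr3 = _clonotype_features(clonotype, params)
    try:
        clan = clan_of(v_gene, clans)
    except ReferenceError:
        return False
    return (
        clan is d.clan
        and d.core_mut_status.matches(status)
        and len(cdr3) == d.cdr3_length
    )


def grade_confidence(
    identity_pct: float,
    similarity_pct: float,
    params: AnalysisParameters,
    margin: float = 5.0,
) -> Confidence:
    """Ordinal confidence for a candidate that met the identity/similarity/pattern
    gates: EXCELLENT at >=90% identity, GOOD at >=70%, AVERAGE when both scores
    clear their thresholds by at least ``margin`` points, else BORDERLINE."""
    if identity_pct >= 90.0:
        return Confidence.EXCELLENT
    if identity_pct >= 70.0:
        return Confidence.GOOD
    if (
        identity_pct >= params.identity_threshold_pct + margin
        and similarity_pct >= params.similarity_threshold_pct + margin
    ):
        return Confidence.AVERAGE
    return Confidence.BORDERLINE


def assign_subset(
    clonotype,
    definitions: Sequence[SubsetDefinition],
    clans: ClanTable,
    classes: ResidueClassTable | None = None,
    params: AnalysisParameters | None = None,
) -> SubsetAssignment:
    """Assign one clonotype to at most one stereotyped subset.

    For each definition passing the core prefilter, the best reference CDR3 is
    found by (identity, similarity); the clonotype is a candidate for the
    subset when identity >= 50%, similarity >= 70% and the anchored motif
    matches. The best subset by (identity, similarity) wins; exact ties across
    subsets yield no assignment (flagged ambiguous). The assignment is reported
    only at confidence >= params.min_confidence.
    """
    params = params or AnalysisParameters()
    classes = classes or ResidueClassTable()
    cid, v_gene, status, cdr3 = _clonotype_features(clonotype, params)

    best: tuple[float, float] | None = None
    best_def: SubsetDefinition | None = None
    ambiguous = False
    for d in definitions:
        if not prefilter_core(clonotype, d, clans, params):
            continue
        scores = [
            (cdr3_identity_pct(cdr3, ref), cdr3_similarity_pct(cdr3, ref, classes))
            for ref in d.reference_cdr3s
        ]
        ident, sim = max(scores)
        if (
            ident < params.identity_threshold_pct
            or sim < params.similarity_threshold_pct
            or not pattern_matches(cdr3, d.pattern, classes)
        ):
            continue
        if best is None or (ident, sim) > best:
            best, best_def, ambiguous = (ident, sim), d, False
        elif (ident, sim) == best and d.subset_id != best_def.subset_id:
            ambiguous = True
    if best is None:
        return SubsetAssignment(cid, None, Confidence.NONE)
    ident, sim = best
    conf = grade_confidence(ident, sim, params)
    if ambiguous:
        logger.info("clonotype %s: AMBIGUOUS tie across subsets", cid)
        return SubsetAssignment(
            cid, None, conf, ident, sim, pattern_matched=True, ambiguous=True
        )
    if conf < params.min_confidence:
        return SubsetAssignment(cid, None, conf, ident, sim, pattern_matched=True)
    typ = (
        Typicality.TYPICAL
        if v_gene in best_def.typical_v_genes
        else Typicality.NON_TYPICAL
    )
    return SubsetAssignment(
        cid,
        best_def.subset_id,
        conf,
        ident,
        sim,
        pattern_matched=True,
        typicality=typ,
    )


def classify_typicality(
    assignment: SubsetAssignment, clonotype, d: SubsetDefinition,
    clans: ClanTable | None = None,
) -> Typicality:
    """TYPICAL iff the clonotype's IGHV gene occurs among the subset's CLL
    counterparts; NON_TYPICAL for a different gene of the same clan."""
    if assignment.subset_id != d.subset_id:
        return Typicality.NA
    params = AnalysisParameters()
    _, v_gene, _, _ = _clonotype_features(clonotype, params)
    if clans is not None and clan_of(v_gene, clans) is not d.clan:
        raise ValueError(
            f"{v_gene} is outside clan {d.clan.value}; prefilter should prevent this"
        )
    return (
        Typicality.TYPICAL if v_gene in d.typical_v_genes else Typicality.NON_TYPICAL
    )


# ---------------------------------------------------------------------------
# vectorized assignment over clonotype frames


def _cdr3_matrix(cdr3s: pd.Series) -> np.ndarray:
    """(n, L) uint8 matrix of equal-length CDR3 strings."""
    arr = np.array(cdr3s.tolist(), dtype=bytes)
    return arr.view(np.uint8).reshape(len(cdr3s), -1)


def assign_frame(
    df: pd.DataFrame,
    definitions: Sequence[SubsetDefinition],
    clans: ClanTable,
    classes: ResidueClassTable | None = None,
    params: AnalysisParameters | None = None,
) -> pd.DataFrame:
    """Vectorized :func:`assign_subset` over a clonotype frame.

    Expects columns clonotype_id, v_gene, cdr3_aa, v_mutation_pct. Returns the
    frame with subset_id, confidence, best_identity_pct, best_similarity_pct,
    pattern_matched, ambiguous, typicality and is_clsig columns appended.
    Produces results identical to the per-clonotype path.
    """
    params = params or AnalysisParameters()
    classes = classes or ResidueClassTable()
    n = len(df)
    out = df.reset_index(drop=True).copy()
    if n == 0:
        for col in (
            "subset_id",
            "confidence",
            "best_identity_pct",
            "best_similarity_pct",
            "pattern_matched",
            "ambiguous",
            "typicality",
            "is_clsig",
        ):
            out[col] = pd.Series(dtype=object)
        return out

    fam2clan = {fam: clan.value for fam, clan in clans.mapping.items()}
    families = out["v_gene"].str.extract(r"^(IGH[VDJ]\d+)", expand=False)
    clan_col = families.map(fam2clan)
    status_col = np.where(
        out["v_mutation_pct"].to_numpy(dtype=float)
        >= params.mutation_threshold_pct,
        "M",
        "U",
    )
    lengths = out["cdr3_aa"].str.len().to_numpy()

    class_lut = classes.lut()
    best_id = np.full(n, np.nan)
    best_sim = np.full(n, np.nan)
    best_subset = np.full(n, -1, dtype=int)
    tie = np.zeros(n, dtype=bool)
    any_candidate = np.zeros(n, dtype=bool)

    for di, d in enumerate(definitions):
        mask = (clan_col == d.clan.value).to_numpy(dtype=bool) & (
            lengths == d.cdr3_length
        )
        if d.core_mut_status is not CoreMutStatus.EITHER:
            mask &= status_col == d.core_mut_status.value
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        mat = _cdr3_matrix(out["cdr3_aa"].iloc[idx])
        cls_mat = class_lut[mat]
        ident = np.zeros(idx.size)
        sim = np.zeros(idx.size)
        best_pair = None
        for ref in d.reference_cdr3s:
            ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
            ref_cls = class_lut[ref_arr]
            r_id = 100.0 * (mat == ref_arr).mean(axis=1)
            r_sim = 100.0 * (cls_mat == ref_cls).mean(axis=1)
            better = (r_id > ident) | ((r_id == ident) & (r_sim > sim))
            if best_pair is None:
                ident, sim = r_id, r_sim
                best_pair = True
            else:
                ident = np.where(better, r_id, ident)
                sim = np.where(better, r_sim, sim)
        # anchored motif
        pat_ok = np.ones(idx.size, dtype=bool)
        for i, elem in enumerate(d.pattern.motif):
            col = mat[:, d.pattern.offset + i]
            if elem in ("x", "X", "any"):
                continue
            if elem in classes.classes:
                allowed = np.zeros(128, dtype=bool)
                for r in classes.members_of(elem):
                    allowed[ord(r)] = True
                pat_ok &= allowed[col]
            else:
                pat_ok &= col == ord(elem)
        cand = (
            (ident >= params.identity_threshold_pct)
            & (sim >= params.similarity_threshold_pct)
            & pat_ok
        )
        cidx = idx[cand]
        if cidx.size == 0:
            continue
        c_id, c_sim = ident[cand], sim[cand]
        any_candidate[cidx] = True
        cur_id, cur_sim = best_id[cidx], best_sim[cidx]
        is_new = np.isnan(cur_id)
        better = is_new | (c_id > cur_id) | ((c_id == cur_id) & (c_sim > cur_sim))
        equal = ~is_new & (c_id == cur_id) & (c_sim == cur_sim)
        upd = cidx[better]
        best_id[upd] = c_id[better]
        best_sim[upd] = c_sim[better]
        best_subset[upd] = di
        tie[upd] = False
        tie[cidx[equal]] = True

    conf = np.empty(n, dtype=object)
    conf[:] = Confidence.NONE
    subset_ids = np.full(n, None, dtype=object)
    typicality = np.full(n, Typicality.NA.value, dtype=object)
    has = any_candidate
    for i in np.flatnonzero(has):
        c = grade_confidence(best_id[i], best_sim[i], params)
        conf[i] = c
        if tie[i] or c < params.min_confidence:
            continue
        d = definitions[best_subset[i]]
        subset_ids[i] = d.subset_id
        typicality[i] = (
            Typicality.TYPICAL.value
            if out["v_gene"].iat[i] in d.typical_v_genes
            else Typicality.NON_TYPICAL.value
        )

    out["subset_id"] = subset_ids
    out["confidence"] = [c.name for c in conf]
    out["best_identity_pct"] = best_id
    out["best_similarity_pct"] = best_sim
    out["pattern_matched"] = has
    out["ambiguous"] = tie
    out["typicality"] = typicality
    out["is_clsig"] = pd.notna(pd.Series(subset_ids))
    return out


def assignment_frame(assignments: Sequence[SubsetAssignment]) -> pd.DataFrame:
    rows = [
        {
            "clonotype_id": a.clonotype_id,
            "subset_id": a.subset_id,
            "confidence": a.confidence.name,
            "best_identity_pct": a.best_identity_pct,
            "best_similarity_pct": a.best_similarity_pct,
            "pattern_matched": a.pattern_matched,
            "ambiguous": a.ambiguous,
            "typicality": a.typicality.value,
            "is_clsig": a.assigned,
        }
        for a in assignments
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reverse-status chimeras


def make_reverse_chimera(
    r: Rearrangement,
    germline: Sequence[GermlineSegment],
    rng: np.random.Generator,
    target_mut_pct: float = 4.0,
    params: AnalysisParameters | None = None,
) -> Rearrangement:
    """In-silico chimera with the V region swapped to the opposite mutational status.

    M input: the read segment aligned to the V gene (through codon 104) is
    replaced by the unmutated germline, giving a U chimera with ~0% mutation.
    U input: random substitutions are placed at germline-matching V positions
    (sparing the 104 anchor codon and avoiding stop codons) until the mutation
    percent reaches ``target_mut_pct``, giving an M chimera. The junction amino
    acids are preserved bit-identically; the chimera is re-annotated.
    """
    params = params or AnalysisParameters()
    if target_mut_pct < params.mutation_threshold_pct:
        raise ValueError(
            f"target_mut_pct {target_mut_pct} below mutation threshold "
            f"{params.mutation_threshold_pct}"
        )
    if not r.productive:
        raise ValueError("chimera construction requires a productive rearrangement")
    v_res = call_v_gene(r.sequence, germline, params)
    if isinstance(v_res, AnnotationFailure):
        raise ValueError("cannot realign V region for chimera construction")
    v_call, v_aln, v_mut = v_res
    v_seg = next(g for g in germline if g.gene_name == v_call)
    status = r.status(params)
    rs, re_ = v_aln.read_span
    gs, ge = v_aln.germ_span
    anchor_nt = v_seg.anchor_ungapped_nt()

    if status is MutationStatus.M:
        # swap in the unmutated germline through codon 104 (inclusive)
        germ_piece = v_seg.sequence[gs : min(ge, anchor_nt + 3)]
        anchor_read = v_aln.map_germ_to_read(anchor_nt)
        if anchor_read is None:
            raise ValueError("V anchor not covered; cannot build chimera")
        new_seq = r.sequence[:rs] + germ_piece + r.sequence[anchor_read + 3 :]
    else:
        # mutate germline-matching positions to reach the target, sparing the
        # anchor codon; resample any substitution creating a stop codon
        seq = list(r.sequence)
        anchor_read = v_aln.map_germ_to_read(anchor_nt)
        if anchor_read is None:
            raise ValueError("V anchor not covered; cannot build chimera")
        matches = []
        for (g0, g1), (r0, _) in v_aln.blocks:
            for i in range(g0, min(g1, anchor_nt)):
                rp = r0 + (i - g0)
                if r.sequence[rp] == v_seg.sequence[i]:
                    matches.append(rp)
        need = math.ceil(
            (target_mut_pct - v_mut) / 100.0 * v_aln.aligned_germ_positions
        )
        if need > len(matches):
            raise ValueError("not enough substitutable positions to reach target")
        frame0 = rs  # germline V is in frame from its aligned start
        placed = 0
        pool = list(rng.permutation(np.array(matches)))
        while placed < need and pool:
            pos = int(pool.pop())
            original = seq[pos]
            choices = [b for b in "ACGT" if b != original]
            rng.shuffle(choices)
            for b in choices:
                seq[pos] = b
                cstart = frame0 + 3 * ((pos - frame0) // 3)
                codon = "".join(seq[cstart : cstart + 3])
                if codon not in ("TAA", "TAG", "TGA"):
                    placed += 1
                    break
                seq[pos] = original
        if placed < need:
            raise ValueError("could not place enough stop-free substitutions")
        new_seq = "".join(seq)

    chimera = annotate_sequence(
        sequence_id=r.sequence_id + "_r",
        sequence=new_seq,
        germline=germline,
        fraction=r.fraction,
        read_count=r.read_count,
        params=params,
    )
    if isinstance(chimera, AnnotationFailure):
        raise ValueError(f"chimera re-annotation failed: {chimera.reason.value}")
    return chimera


def rclsig_scan(
    clonotypes: Sequence[Clonotype],
    germline: Sequence[GermlineSegment],
    definitions: Sequence[SubsetDefinition],
    clans: ClanTable,
    rng: np.random.Generator,
    classes: ResidueClassTable | None = None,
    params: AnalysisParameters | None = None,
    target_mut_pct: float = 4.0,
) -> pd.DataFrame:
    """Paired native/reversed stereotypy eligibility per clonotype.

    Each clonotype representative is assigned natively, then its reverse-status
    chimera is assigned; the chimera of a clonotype assigned to a
    status-restricted subset fails that subset's core feature by construction.
    """
    params = params or AnalysisParameters()
    classes = classes or ResidueClassTable()
    rows = []
    for c in clonotypes:
        rep = c.representative
        native = assign_subset(c, definitions, clans, classes, params)
        chimera = make_reverse_chimera(rep, germline, rng, target_mut_pct, params)
        chim_rec = type("Rec", (), {})()
        chim_rec.clonotype_id = c.clonotype_id + "_r"
        chim_rec.v_gene = gene_of(chimera.v_call)
        chim_rec.v_mutation_pct = chimera.v_mutation_pct
        chim_rec.cdr3_aa = chimera.cdr3_aa
        reversed_ = assign_subset(chim_rec, definitions, clans, classes, params)
        rows.append(
            {
                "clonotype_id": c.clonotype_id,
                "donor_id": c.donor_id,
                "native_status": rep.status(params).value,
                "reversed_status": chimera.status(params).value,
                "native_subset": native.subset_id,
                "reversed_subset": reversed_.subset_id,
                "native_assigned": native.assigned,
                "reversed_assigned": reversed_.assigned,
                "cdr3_preserved": chimera.cdr3_aa == rep.cdr3_aa,
            }
        )
    return pd.DataFrame(rows)
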