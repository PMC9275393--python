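"""Seeded synthetic B-cell repertoire cohorts with stereotype spike-ins.

Two entry points at different granularities, fed by one splittable generator:

* sequence level — V(D)J nucleotide rearrangements with controlled somatic
  mutation, emitted as UMI-tagged FASTQ reads with sequencing error, for
  exercising the preprocess and annotate stages against ground truth;
* table level — annotated rearrangement frames at desk-scale cohort size
  (donors x 24 sorted fractions), equivalent to annotating error-free reads,
  for exercising clonotyping, subset assignment and the statistics layer.

The stratum plan mirrors the structure of healthy-donor repertoires: TR and N
cells almost exclusively unmutated, memory subsets predominantly mutated, the
CD5+ fraction shifted toward unmutated rearrangements, and CLL-like
stereotyped spike-ins at frequencies in the 0.005%-0.1% range.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import ISOTYPE_MOTIFS
from .reference import (
    AnalysisParameters,
    BSubset,
    CD5Status,
    CellFraction,
    GermlineSegment,
    LightChain,
    SegmentKind,
    read_germline_fasta,
    toy_germline_path,
    default_clan_table,
)
from .stereotypy import (
    AA_ALPHABET,
    ResidueClassTable,
    SubsetDefinition,
    CoreMutStatus,
)

__all__ = [
    "SpikePlan",
    "SimulationConfig",
    "TruthRecord",
    "DEFAULT_U_FRACTIONS",
    "DEFAULT_B_SUBSET_WEIGHTS",
    "toy_germline",
    "simulate_rearrangement",
    "spike_stereotype",
    "spike_cdr3_variant",
    "emit_reads",
    "simulate_cohort_frame",
    "all_fractions",
]

STOP_CODONS = ("TAA", "TAG", "TGA")

# Unmutated fraction by B-cell subset (CD5-unshifted baseline): transitional
# and naive B cells carry almost exclusively unmutated rearrangements, the
# marginal-zone-like compartment is mixed, memory compartments are mutated.
DEFAULT_U_FRACTIONS: dict[str, float] = {
    "TR": 0.97,
    "N": 0.95,
    "MZ": 0.50,
    "MO": 0.12,
    "SM": 0.08,
    "DN": 0.15,
}

# Relative B-subset composition of each CD5 compartment: the CD5+ compartment
# is dominated by naive/transitional cells while memory subsets are scarce
# there, which is what skews the bulk CD5+ repertoire toward unmutated
# rearrangements. Used when a simulation requests realistic compartment sizes.
DEFAULT_B_SUBSET_WEIGHTS: dict[str, dict[str, float]] = {
    "POS": {"TR": 0.12, "N": 0.55, "MZ": 0.18, "MO": 0.05, "SM": 0.06, "DN": 0.04},
    "NEG": {"TR": 0.06, "N": 0.40, "MZ": 0.20, "MO": 0.10, "SM": 0.18, "DN": 0.06},
}


@dataclass(frozen=True)
class SpikePlan:
    """One stereotyped spike-in: subset, target frequency, generation rule.

    ``freq`` is the per-molecule spike probability; with ``rate_basis="status"``
    it applies within molecules of the subset's core mutational status, with
    ``"all"`` to every molecule of the stratum (the spiked molecule's status is
    then drawn to match the core). ``n_subs`` gives the inclusive range of
    class-preserving CDR3 substitutions per spike; at least one substitution by
    default so distinct molecules remain distinct clonotypes.
    """

    subset_id: str
    freq: float
    rate_basis: Literal["status", "all"] = "status"
    n_subs: tuple[int, int] = (1, 2)
    typical_only: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.freq <= 1.0:
            raise ValueError("spike frequency must lie in [0, 1]")
        lo, hi = self.n_subs
        if not (0 <= lo <= hi):
            raise ValueError("invalid substitution range")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a synthetic cohort."""

    seed: int
    n_donors: int = 9
    molecules_per_fraction: int = 2000
    u_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_U_FRACTIONS)
    )
    cd5_shift: float = 0.15  # CD5+ U-fraction raised, CD5- lowered, by this much
    shm_u_range: tuple[float, float] = (0.0, 2.0)  # percent, unmutated
    shm_m_range: tuple[float, float] = (2.0, 10.0)  # percent, mutated
    spikes: tuple[SpikePlan, ...] = ()
    read_count_poisson_mean: float = 2.0  # reads per molecule = 1 + Poisson(mean)
    error_rate: float = 0.002  # per-base substitution probability
    umi_lengths: tuple[int, ...] = (14, 15, 16)
    cdr3_length_mean: float = 15.0
    cdr3_length_sd: float = 3.0
    cdr3_length_range: tuple[int, int] = (8, 24)
    # optional cd5 -> b_subset -> relative weight; None = equal-sized fractions
    b_subset_weights: Mapping[str, Mapping[str, float]] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "spikes", tuple(self.spikes))
        for v in self.u_fractions.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("U-fractions must lie in [0, 1]")

    def u_fraction(self, b_subset: str, cd5: str) -> float:
        base = self.u_fractions[b_subset]
        shift = self.cd5_shift if cd5 == "POS" else -self.cd5_shift
        return float(np.clip(base + shift, 0.0, 1.0))

    def molecules_for(self, b_subset: str, cd5: str) -> int:
        """Molecules in one sorted fraction; weighted plans redistribute the
        per-CD5-compartment total (6 x molecules_per_fraction) over B-subsets."""
        if self.b_subset_weights is None:
            return self.molecules_per_fraction
        w = self.b_subset_weights[cd5]
        total = self.molecules_per_fraction * 6
        return int(round(total * w[b_subset] / sum(w.values())))


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated molecule (joins 1:1 to emitted molecules)."""

    molecule_id: str
    v_call: str
    d_call: str | None
    j_call: str
    junction_aa: str
    n_mutations: int
    v_mutation_pct: float
    fraction: CellFraction
    spike_subset: str | None = None

    @property
    def cdr3_aa(self) -> str:
        return self.junction_aa[1:-1]


def toy_germline() -> list[GermlineSegment]:
    """The bundled synthetic toy germline set (parsed fresh on each call)."""
    return read_germline_fasta(toy_germline_path(), default_clan_table())


def all_fractions(n_donors: int) -> list[CellFraction]:
    """The 24 sorted fractions (CD5 x light chain x 6 B-subsets) per donor."""
    out = []
    for d in range(1, n_donors + 1):
        for cd5 in CD5Status:
            for lc in LightChain:
                for bs in BSubset:
                    out.append(
                        CellFraction(
                            donor_id=f"D{d:02d}",
                            cd5=cd5,
                            light_chain=lc,
                            b_subset=bs,
                        )
                    )
    return out


# ---------------------------------------------------------------------------
# sequence-level simulation

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)

_CODONS_BY_AA: dict[str, list[str]] = {}


def _codons_by_aa() -> dict[str, list[str]]:
    if not _CODONS_BY_AA:
        from Bio.Seq import Seq

        for a in "ACGT":
            for b in "ACGT":
                for c in "ACGT":
                    codon = a + b + c
                    aa = str(Seq(codon).translate())
                    _CODONS_BY_AA.setdefault(aa, []).append(codon)
    return _CODONS_BY_AA


def _reverse_translate(aa: str, rng: np.random.Generator) -> str:
    table = _codons_by_aa()
    return "".join(table[res][rng.integers(0, len(table[res]))] for res in aa)


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _translate(nt: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(nt).translate())


def _shm_count(status: str, target_pct: float, L: int) -> int:
    """Substitution count for a target percent, clamped so that the realized
    100*k/L stays on the correct side of the 2% U/M threshold."""
    k = int(round(target_pct / 100.0 * L))
    threshold_k = int(np.ceil(0.02 * L))  # smallest k with 100k/L >= 2
    if status == "U":
        return min(k, max(threshold_k - 1, 0))
    return max(k, threshold_k)


def _apply_shm(
    v_seq: str,
    k: int,
    rng: np.random.Generator,
    frame0: int = 0,
) -> tuple[str, int]:
    """Place exactly k stop-free substitutions in a V sequence, sparing the
    trailing anchor codon. Returns (mutated sequence, count)."""
    L = len(v_seq)
    if k == 0:
        return v_seq, 0
    seq = list(v_seq)
    eligible = list(range(frame0, L - 3))  # spare the 2nd-CYS codon at the tail
    rng.shuffle(eligible)
    placed = 0
    for pos in eligible:
        if placed == k:
            break
        original = seq[pos]
        choices = [b for b in "ACGT" if b != original]
        rng.shuffle(choices)
        for b in choices:
            seq[pos] = b
            cstart = frame0 + 3 * ((pos - frame0) // 3)
            codon = "".join(seq[cstart : cstart + 3])
            if codon not in STOP_CODONS:
                placed += 1
                break
            seq[pos] = original
    if placed < k:
        raise RuntimeError("could not place requested substitutions")
    return "".join(seq), k


def _pick(rng: np.random.Generator, items: Sequence):
    return items[int(rng.integers(0, len(items)))]


def _draw_mut_pct(
    status: str, config: SimulationConfig, rng: np.random.Generator
) -> float:
    lo, hi = config.shm_u_range if status == "U" else config.shm_m_range
    if status == "M":
        return float(rng.uniform(lo, hi))
    # U draws stay strictly below the M threshold
    return float(rng.uniform(lo, min(hi, 1.999)))


def simulate_rearrangement(
    germline: Sequence[GermlineSegment],
    fraction: CellFraction,
    status: str,
    rng: np.random.Generator,
    config: SimulationConfig | None = None,
    molecule_id: str = "M0",
) -> tuple[str, TruthRecord]:
    """One productive background rearrangement: V + N/D/N insert + J, with
    somatic mutations in the V region per the stratum's mutational status."""
    config = config or SimulationConfig(seed=0)
    vs = [g for g in germline if g.segment_kind is SegmentKind.V]
    ds = [g for g in germline if g.segment_kind is SegmentKind.D]
    js = [g for g in germline if g.segment_kind is SegmentKind.J]
    v, j = _pick(rng, vs), _pick(rng, js)
    use_d = ds and rng.random() < 0.7
    d = _pick(rng, ds) if use_d else None

    for _ in range(100):
        np1 = _random_nt(rng, int(rng.geometric(1 / 6.0)))
        np2 = _random_nt(rng, int(rng.geometric(1 / 6.0)))
        insert = np1 + (d.sequence if d else "") + np2
        trim = len(insert) % 3
        insert = insert[: len(insert) - trim] if trim else insert
        junction_nt = v.sequence[-3:] + insert + j.sequence[: 3 * j.anchor_codon]
        if "*" not in _translate(junction_nt):
            break
    else:
        raise RuntimeError("failed to draw a stop-free junction")

    target = _draw_mut_pct(status, config, rng)
    mut_v, k = _apply_shm(
        v.sequence, _shm_count(status, target, len(v.sequence)), rng
    )
    seq = mut_v + insert + j.sequence + ISOTYPE_MOTIFS["IGHM"] + _random_nt(rng, 4)
    junction_aa = _translate(junction_nt)
    truth = TruthRecord(
        molecule_id=molecule_id,
        v_call=v.gene_name,
        d_call=d.gene_name if d else None,
        j_call=j.gene_name,
        junction_aa=junction_aa,
        n_mutations=k,
        v_mutation_pct=100.0 * k / len(v.sequence),
        fraction=fraction,
        spike_subset=None,
    )
    return seq, truth


def spike_cdr3_variant(
    d: SubsetDefinition,
    rng: np.random.Generator,
    n_subs: tuple[int, int] = (1, 2),
    classes: ResidueClassTable | None = None,
) -> str:
    """A reference CDR3 with a drawn number of class-preserving substitutions.

    Positions constrained to a literal residue by the subset's motif are never
    substituted, so the variant always keeps 100% similarity and the motif.
    """
    classes = classes or ResidueClassTable()
    ref = str(_pick(rng, d.reference_cdr3s))
    lo, hi = n_subs
    k = int(rng.integers(lo, hi + 1))
    literal_pos = {
        d.pattern.offset + i
        for i, elem in enumerate(d.pattern.motif)
        if elem not in ("x", "X", "any") and elem not in classes.classes
    }
    eligible = [i for i in range(len(ref)) if i not in literal_pos]
    if k > len(eligible):
        raise ValueError("more substitutions requested than substitutable positions")
    pos = rng.choice(len(eligible), size=k, replace=False)
    out = list(ref)
    for p in (eligible[int(i)] for i in pos):
        cls = classes.class_of(out[p])
        alternatives = sorted(classes.members_of(cls) - {out[p]})
        out[p] = str(_pick(rng, alternatives))
    return "".join(out)


def spike_stereotype(
    d: SubsetDefinition,
    germline: Sequence[GermlineSegment],
    fraction: CellFraction,
    rng: np.random.Generator,
    config: SimulationConfig | None = None,
    n_subs: tuple[int, int] = (1, 2),
    typical_only: bool = True,
    classes: ResidueClassTable | None = None,
    molecule_id: str = "S0",
) -> tuple[str, TruthRecord]:
    """One stereotyped spike-in rearrangement for subset ``d``.

    The CDR3 derives from a reference CDR3 by class-preserving substitution,
    the V gene is drawn from the subset's typical genes (or the clan's
    non-typical complement), and the mutational status matches the core.
    """
    config = config or SimulationConfig(seed=0)
    classes = classes or ResidueClassTable()
    from .reference import clan_of

    clans = default_clan_table()
    vs = [g for g in germline if g.segment_kind is SegmentKind.V]
    if typical_only:
        pool = [g for g in vs if g.gene_name in d.typical_v_genes]
    else:
        pool = [
            g
            for g in vs
            if clan_of(g.gene_name, clans) is d.clan
            and g.gene_name not in d.typical_v_genes
        ]
    if not pool:
        raise ValueError(
            f"no germline V genes available for subset {d.subset_id} "
            f"(typical_only={typical_only})"
        )
    v = _pick(rng, pool)
    js = [g for g in germline if g.segment_kind is SegmentKind.J]
    j = _pick(rng, js)

    cdr3 = spike_cdr3_variant(d, rng, n_subs, classes)
    cdr3_nt = _reverse_translate(cdr3, rng)
    if d.core_mut_status is CoreMutStatus.EITHER:
        status = "U" if rng.random() < 0.5 else "M"
    else:
        status = d.core_mut_status.value
    target = _draw_mut_pct(status, config, rng)
    mut_v, k = _apply_shm(
        v.sequence, _shm_count(status, target, len(v.sequence)), rng
    )
    # J contributed from its anchor codon onward: the CDR3 is exactly `cdr3`
    j_piece = j.sequence[3 * (j.anchor_codon - 1) :]
    seq = mut_v + cdr3_nt + j_piece + ISOTYPE_MOTIFS["IGHM"] + _random_nt(rng, 4)
    junction_aa = "C" + cdr3 + _translate(j_piece[:3])
    truth = TruthRecord(
        molecule_id=molecule_id,
        v_call=v.gene_name,
        d_call=None,
        j_call=j.gene_name,
        junction_aa=junction_aa,
        n_mutations=k,
        v_mutation_pct=100.0 * k / len(v.sequence),
        fraction=fraction,
        spike_subset=d.subset_id,
    )
    return seq, truth


# ---------------------------------------------------------------------------
# read emission

FASTQ_NAME = "reads_{donor}_{cd5}_{lc}_{bsub}.fastq"


def _unique_umis(
    n: int, lengths: Sequence[int], rng: np.random.Generator
) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 50 * n + 1000:
            raise RuntimeError("UMI space exhausted")
        L = int(_pick(rng, lengths))
        umi = _random_nt(rng, L)
        if umi not in seen:
            seen.add(umi)
            out.append(umi)
    return out


def emit_reads(
    molecules: Sequence[tuple[str, TruthRecord]],
    config: SimulationConfig,
    rng: np.random.Generator,
    outdir: str | Path,
    reads_per_molecule: int | None = None,
) -> tuple[Path, Path]:
    """Write UMI-tagged FASTQ per fraction, a samplesheet, and the truth table.

    Each molecule receives a unique UMI and >=1 reads with iid substitution
    errors at the configured rate. ``reads_per_molecule`` forces a fixed read
    count (otherwise 1 + Poisson). Returns (samplesheet path, truth path).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    umis = _unique_umis(len(molecules), config.umi_lengths, rng)

    by_file: dict[str, list[str]] = {}
    sheet_rows: dict[str, CellFraction] = {}
    truth_rows = []
    for (seq, truth), umi in zip(molecules, umis):
        frac = truth.fraction
        fname = FASTQ_NAME.format(
            donor=frac.donor_id,
            cd5=frac.cd5.value,
            lc=frac.light_chain.value,
            bsub=frac.b_subset.value,
        )
        sheet_rows[fname] = frac
        lines = by_file.setdefault(fname, [])
        n_reads = (
            reads_per_molecule
            if reads_per_molecule is not None
            else 1 + int(rng.poisson(config.read_count_poisson_mean))
        )
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        for i in range(n_reads):
            read = arr.copy()
            if config.error_rate > 0:
                errs = np.flatnonzero(rng.random(len(read)) < config.error_rate)
                for p in errs:
                    cur = read[p]
                    alternatives = _NT[_NT != cur]
                    read[p] = alternatives[int(rng.integers(0, 3))]
            read_seq = read.tobytes().decode()
            lines.append(f"@{truth.molecule_id}_r{i} UMI={umi}")
            lines.append(read_seq)
            lines.append("+")
            lines.append("I" * len(read_seq))
        truth_rows.append(
            {
                "molecule_id": truth.molecule_id,
                "umi": umi,
                "v_call": truth.v_call,
                "d_call": truth.d_call or "",
                "j_call": truth.j_call,
                "junction_aa": truth.junction_aa,
                "cdr3_aa": truth.cdr3_aa,
                "n_mutations": truth.n_mutations,
                "v_mutation_pct": truth.v_mutation_pct,
                "donor_id": frac.donor_id,
                "cd5": frac.cd5.value,
                "light_chain": frac.light_chain.value,
                "b_subset": frac.b_subset.value,
                "spike_subset": truth.spike_subset or "",
            }
        )

    for fname, lines in by_file.items():
        (outdir / fname).write_text("\n".join(lines) + "\n")
    sheet = pd.DataFrame(
        [
            {
                "file": fname,
                "donor_id": f.donor_id,
                "cd5": f.cd5.value,
                "light_chain": f.light_chain.value,
                "b_subset": f.b_subset.value,
            }
            for fname, f in sorted(sheet_rows.items())
        ]
    )
    sheet_path = outdir / "samplesheet.tsv"
    sheet.to_csv(sheet_path, sep="\t", index=False)
    truth_path = outdir / "truth.tsv"
    pd.DataFrame(truth_rows).to_csv(truth_path, sep="\t", index=False)
    return sheet_path, truth_path


# ---------------------------------------------------------------------------
# table-level cohort simulation

def _random_cdr3s(rng: np.random.Generator, lengths: np.ndarray) -> np.ndarray:
    """Random amino-acid CDR3 strings with the given per-row lengths."""
    aa = np.frombuffer(AA_ALPHABET.encode(), dtype=np.uint8)
    out = np.empty(len(lengths), dtype=object)
    for L in np.unique(lengths):
        idx = np.flatnonzero(lengths == L)
        mat = aa[rng.integers(0, len(aa), size=(idx.size, int(L)))]
        out[idx] = mat.view(f"S{int(L)}").ravel().astype(f"U{int(L)}")
    return out


def simulate_cohort_frame(
    config: SimulationConfig,
    definitions: Sequence[SubsetDefinition],
    germline: Sequence[GermlineSegment] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Annotated rearrangement frame for a full sorted cohort.

    Equivalent to annotating error-free consensus reads (one molecule per
    row); used at desk-scale cohort sizes. Columns match
    :func:`clsig.clonotype.cluster_frame`'s contract plus truth columns
    ``spike_subset`` (empty for background) and ``true_status``.
    """
    rng = rng or np.random.default_rng(config.seed)
    germline = germline or toy_germline()
    vs = sorted(
        (g.gene_name for g in germline if g.segment_kind is SegmentKind.V)
    )
    js = sorted(
        (g.gene_name for g in germline if g.segment_kind is SegmentKind.J)
    )
    defs_by_id = {d.subset_id: d for d in definitions}
    classes = ResidueClassTable()
    clans = default_clan_table()
    from .reference import clan_of

    frames = []
    lo_len, hi_len = config.cdr3_length_range
    for frac in all_fractions(config.n_donors):
        n = config.molecules_for(frac.b_subset.value, frac.cd5.value)
        if n == 0:
            continue
        u_frac = config.u_fraction(frac.b_subset.value, frac.cd5.value)
        status = np.where(rng.random(n) < u_frac, "U", "M")
        mut = np.where(
            status == "U",
            rng.uniform(*config.shm_u_range, size=n).clip(max=1.999),
            rng.uniform(*config.shm_m_range, size=n),
        )
        lengths = np.clip(
            np.rint(rng.normal(config.cdr3_length_mean, config.cdr3_length_sd, n)),
            lo_len,
            hi_len,
        ).astype(int)
        cdr3 = _random_cdr3s(rng, lengths)
        v_call = np.array(vs, dtype=object)[rng.integers(0, len(vs), n)]
        j_call = np.array(js, dtype=object)[rng.integers(0, len(js), n)]
        spike_subset = np.full(n, "", dtype=object)

        for plan in config.spikes:
            d = defs_by_id[plan.subset_id]
            if plan.rate_basis == "status":
                if d.core_mut_status is CoreMutStatus.EITHER:
                    eligible = np.arange(n)
                else:
                    eligible = np.flatnonzero(status == d.core_mut_status.value)
            else:
                eligible = np.arange(n)
            eligible = eligible[spike_subset[eligible] == ""]
            if eligible.size == 0:
                continue
            k = rng.binomial(eligible.size, plan.freq)
            if k == 0:
                continue
            chosen = rng.choice(eligible, size=k, replace=False)
            if plan.typical_only:
                pool = sorted(d.typical_v_genes)
            else:
                pool = sorted(
                    g
                    for g in vs
                    if clan_of(g, clans) is d.clan and g not in d.typical_v_genes
                )
            if not pool:
                raise ValueError(f"no V genes for spike plan {plan.subset_id}")
            for row in chosen:
                cdr3[row] = spike_cdr3_variant(d, rng, plan.n_subs, classes)
                v_call[row] = pool[int(rng.integers(0, len(pool)))]
                spike_subset[row] = d.subset_id
                if plan.rate_basis == "all" and d.core_mut_status is not (
                    CoreMutStatus.EITHER
                ):
                    status[row] = d.core_mut_status.value
                    lo, hi = (
                        config.shm_u_range
                        if status[row] == "U"
                        else config.shm_m_range
                    )
                    mut[row] = (
                        min(rng.uniform(lo, hi), 1.999)
                        if status[row] == "U"
                        else rng.uniform(lo, hi)
                    )

        frames.append(
            pd.DataFrame(
                {
                    "sequence_id": [
                        f"{frac.donor_id}_{frac.cd5.value}_{frac.light_chain.value}"
                        f"_{frac.b_subset.value}_{i:06d}"
                        for i in range(n)
                    ],
                    "v_call": v_call,
                    "j_call": j_call,
                    "cdr3_aa": cdr3,
                    "v_mutation_pct": mut,
                    "duplicate_count": 1 + rng.poisson(
                        config.read_count_poisson_mean, n
                    ),
                    "productive": True,
                    "donor_id": frac.donor_id,
                    "cd5": frac.cd5.value,
                    "light_chain": frac.light_chain.value,
                    "b_subset": frac.b_subset.value,
                    "true_status": status,
                    "spike_subset": spike_subset,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
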