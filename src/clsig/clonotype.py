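"""Clonotype definition and representative selection.

A clonotype is the set of productive rearrangements with identical amino-acid
CDR3 using the same IGHV gene and IGHJ gene (gene level: allele suffixes are
stripped before keying). All downstream analysis operates on one representative
sequence per clonotype. Clonotyping is per donor by default; cross-donor
(public) sharing is reported separately, never merged.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .annotate import Rearrangement
from .reference import gene_of

__all__ = [
    "Clonotype",
    "clonotype_key",
    "cluster_clonotypes",
    "select_representative",
    "clonotype_frame",
    "cluster_frame",
    "write_clonotype_tsv",
]

Scope = Literal["donor", "global"]


def clonotype_key(r: Rearrangement) -> tuple[str, str, str]:
    """(V gene, J gene, CDR3 aa) at gene level."""
    return (gene_of(r.v_call), gene_of(r.j_call), r.cdr3_aa)


@dataclass(frozen=True)
class Clonotype:
    """Dedup unit: same V gene, J gene, and amino-acid CDR3."""

    clonotype_id: str
    v_gene: str
    j_gene: str
    cdr3_aa: str
    members: tuple[Rearrangement, ...]
    representative: Rearrangement

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("clonotype must have at least one member")
        if self.representative not in self.members:
            raise ValueError("representative must be a member")
        key = (self.v_gene, self.j_gene, self.cdr3_aa)
        for m in self.members:
            if clonotype_key(m) != key:
                raise ValueError("member does not share the clonotype key")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def donor_id(self) -> str:
        return self.representative.fraction.donor_id

    def fraction_profile(self) -> dict[tuple[str, str, str, str], int]:
        prof: dict[tuple[str, str, str, str], int] = defaultdict(int)
        for m in self.members:
            prof[m.fraction.key()] += 1
        return dict(prof)


def select_representative(members: Sequence[Rearrangement]) -> Rearrangement:
    """Highest read count; ties -> lowest mutation percent, then smallest id."""
    return min(
        members, key=lambda r: (-r.read_count, r.v_mutation_pct, r.sequence_id)
    )


def cluster_clonotypes(
    rearrangements: Iterable[Rearrangement], scope: Scope = "donor"
) -> list[Clonotype]:
    """Exact partition of productive rearrangements by (V gene, J gene, CDR3 aa).

    ``scope="donor"`` (default) partitions within each donor; ``"global"``
    pools the whole input. Output order is deterministic (sorted keys) and
    independent of input order.
    """
    groups: dict[tuple, list[Rearrangement]] = defaultdict(list)
    for r in rearrangements:
        if not isinstance(r, Rearrangement) or not r.productive:
            raise ValueError(
                f"clonotyping requires annotated productive rearrangements; "
                f"got {getattr(r, 'sequence_id', r)!r}"
            )
        key = clonotype_key(r)
        if scope == "donor":
            key = (r.fraction.donor_id,) + key
        groups[key].append(r)
    out: list[Clonotype] = []
    for i, key in enumerate(sorted(groups)):
        members = tuple(sorted(groups[key], key=lambda r: r.sequence_id))
        v, j, cdr3 = key[-3], key[-2], key[-1]
        out.append(
            Clonotype(
                clonotype_id=f"CT{i:06d}",
                v_gene=v,
                j_gene=j,
                cdr3_aa=cdr3,
                members=members,
                representative=select_representative(members),
            )
        )
    return out


def clonotype_frame(clonotypes: Sequence[Clonotype]) -> pd.DataFrame:
    """Tidy per-clonotype table (one row per clonotype, representative fields)."""
    rows = []
    for c in clonotypes:
        rep = c.representative
        d, cd5, lc, bs = rep.fraction.key()
        rows.append(
            {
                "clonotype_id": c.clonotype_id,
                "v_gene": c.v_gene,
                "j_gene": c.j_gene,
                "cdr3_aa": c.cdr3_aa,
                "size": c.size,
                "representative_id": rep.sequence_id,
                "read_count": rep.read_count,
                "v_mutation_pct": rep.v_mutation_pct,
                "donor_id": d,
                "cd5": cd5,
                "light_chain": lc,
                "b_subset": bs,
            }
        )
    return pd.DataFrame(rows)


def cluster_frame(df: pd.DataFrame, scope: Scope = "donor") -> pd.DataFrame:
    """Table-level clonotyping of an annotated rearrangement frame.

    Equivalent to :func:`cluster_clonotypes` on the same records (tested for
    equivalence); used for desk-scale cohorts. Expects columns sequence_id,
    v_call, j_call, cdr3_aa, v_mutation_pct, duplicate_count, donor_id, cd5,
    light_chain, b_subset, productive.
    """
    work = df.loc[df["productive"].astype(bool)].reset_index(drop=True)
    cols_out = [
        "clonotype_id", "v_gene", "j_gene", "cdr3_aa", "size",
        "representative_id", "read_count", "v_mutation_pct",
        "donor_id", "cd5", "light_chain", "b_subset",
    ]
    if work.empty:
        return pd.DataFrame(columns=[c for c in cols_out if c in set(df.columns)
                                     | {"clonotype_id", "v_gene", "j_gene",
                                        "size", "representative_id",
                                        "read_count", "cdr3_aa"}])
    vg = work["v_call"].astype(str)
    if vg.str.contains("*", regex=False).any():
        vg = vg.str.split("*").str[0]
    jg = work["j_call"].astype(str)
    if jg.str.contains("*", regex=False).any():
        jg = jg.str.split("*").str[0]
    work = work.assign(v_gene=vg, j_gene=jg)
    keys = ["v_gene", "j_gene", "cdr3_aa"]
    if scope == "donor":
        keys = ["donor_id"] + keys

    # integer group ids whose order equals lexicographic key order
    combined = np.zeros(len(work), dtype=np.int64)
    for k in keys:
        codes, uniques = pd.factorize(work[k].to_numpy(object), sort=False)
        order = np.argsort(uniques)
        rank = np.empty(len(uniques), dtype=np.int64)
        rank[order] = np.arange(len(uniques))
        combined = combined * len(uniques) + rank[codes]
    group_ids, _ = pd.factorize(combined, sort=True)
    n_groups = int(group_ids.max()) + 1
    sizes = np.bincount(group_ids, minlength=n_groups)

    # representative = max duplicate_count, then min mutation, then min id
    dup = work["duplicate_count"].to_numpy(np.int64)
    mut = work["v_mutation_pct"].to_numpy(float)
    order = np.lexsort((mut, -dup, group_ids))
    gi_sorted = group_ids[order]
    first = np.flatnonzero(np.r_[True, gi_sorted[1:] != gi_sorted[:-1]])
    rep_pos = order[first]  # one row per group, groups in sorted-key order
    multi = np.flatnonzero(sizes > 1)
    if multi.size:
        # sequence_id tie-break only matters inside multi-member groups
        sub_mask = np.isin(group_ids, multi)
        sub = pd.DataFrame(
            {
                "g": group_ids[sub_mask],
                "dup": dup[sub_mask],
                "mut": mut[sub_mask],
                "sequence_id": work.loc[sub_mask, "sequence_id"].astype(str),
            },
            index=np.flatnonzero(sub_mask),
        ).sort_values(
            ["g", "dup", "mut", "sequence_id"],
            ascending=[True, False, True, True],
            kind="stable",
        )
        best = sub.drop_duplicates("g", keep="first")
        rep_pos[best["g"].to_numpy()] = best.index.to_numpy()

    reps = work.iloc[rep_pos].reset_index(drop=True)
    out = reps[[c for c in ("v_gene", "j_gene", "cdr3_aa", "sequence_id",
                            "duplicate_count", "v_mutation_pct", "donor_id",
                            "cd5", "light_chain", "b_subset")
                if c in reps.columns]].copy()
    out.insert(0, "clonotype_id", [f"CT{i:06d}" for i in range(len(out))])
    out.insert(4, "size", sizes)
    return out.rename(
        columns={"sequence_id": "representative_id", "duplicate_count": "read_count"}
    )


def write_clonotype_tsv(clonotypes: Sequence[Clonotype], path: str | Path) -> None:
    frame = clonotype_frame(clonotypes)
    # per-fraction member counts appended as a compact profile column
    frame["fraction_profile"] = [
        ";".join(
            f"{'|'.join(k)}:{v}" for k, v in sorted(c.fraction_profile().items())
        )
        for c in clonotypes
    ]
    frame.to_csv(path, sep="\t", index=False)
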