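"""Stratified CLS-IG frequencies and the paired/binomial statistics layer.

Frequencies are per donor within a stratum (any combination of CD5 status,
light chain, B-cell subset, mutational status, assigned subset, typicality).
A stratum frequency is informative only when it contains at least two CLS-IG
clonotypes; otherwise it is UNDEFINED (NaN) and excluded from pairing rather
than imputed as zero. Paired Wilcoxon tests are computed only when three or
more donors present data on both sides; binomial tests compare observed counts
to reference proportions. Bonferroni correction is applied per declared family.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reference import AnalysisParameters

__all__ = [
    "CELL_KEYS",
    "CLSIG_KEYS",
    "TestMethod",
    "TestResult",
    "NOT_COMPUTED",
    "stratify",
    "paired_wilcoxon",
    "exact_signed_rank_p",
    "binomial_vs_reference",
    "bonferroni",
    "stars",
    "vgene_usage_comparison",
]

# stratum keys that partition the clonotype denominator
CELL_KEYS = ("cd5", "light_chain", "b_subset", "mut_status")
# keys that partition only the CLS-IG numerator
CLSIG_KEYS = ("subset_id", "typicality")


class TestMethod(str, enum.Enum):
    PAIRED_WILCOXON = "PAIRED_WILCOXON"
    BINOMIAL = "BINOMIAL"


@dataclass(frozen=True)
class TestResult:
    label: str
    method: TestMethod
    n: int
    statistic: float
    p_raw: float
    p_adjusted: float | None = None

    @property
    def p(self) -> float:
        return self.p_adjusted if self.p_adjusted is not None else self.p_raw

    @property
    def significance(self) -> str:
        return stars(self.p)


class _NotComputed:
    """Sentinel for tests with insufficient data (falsy, prints NOT_COMPUTED)."""

    def __bool__(self) -> bool:
        return False

    def __repr__(self) -> str:
        return "NOT_COMPUTED"


NOT_COMPUTED = _NotComputed()


def stars(p: float) -> str:
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def stratify(
    clonotypes: pd.DataFrame,
    keys: Sequence[str],
    params: AnalysisParameters | None = None,
) -> pd.DataFrame:
    """Per-donor gated CLS-IG frequency records for a stratification design.

    ``clonotypes`` is an assigned clonotype frame (columns donor_id, cd5,
    light_chain, b_subset, mut_status, is_clsig, and subset_id/typicality for
    assigned rows). ``keys`` may mix denominator keys (cd5, light_chain,
    b_subset, mut_status) with numerator-only keys (subset_id, typicality).
    Denominators count every clonotype in the donor x denominator-key cell;
    numerators count CLS-IG clonotypes, further split by numerator keys.
    freq_pct is NaN (UNDEFINED) when the numerator is below
    ``min_clsig_for_frequency``.
    """
    params = params or AnalysisParameters()
    unknown = set(keys) - set(CELL_KEYS) - set(CLSIG_KEYS)
    if unknown:
        raise ValueError(f"unknown stratum keys: {sorted(unknown)}")
    cell = ["donor_id"] + [k for k in keys if k in CELL_KEYS]
    num_keys = [k for k in keys if k in CLSIG_KEYS]

    totals = clonotypes.groupby(cell, dropna=False).size().rename("n_total")
    cls = clonotypes[clonotypes["is_clsig"].astype(bool)]
    n_cls = (
        cls.groupby(cell + num_keys, dropna=False).size().rename("n_clsig")
    )
    if num_keys:
        # one record per donor-cell x observed numerator combination
        rec = n_cls.reset_index().merge(totals.reset_index(), on=cell, how="left")
    else:
        rec = totals.reset_index().merge(n_cls.reset_index(), on=cell, how="left")
        rec["n_clsig"] = rec["n_clsig"].fillna(0).astype(int)
    rec["freq_pct"] = np.where(
        rec["n_clsig"] >= params.min_clsig_for_frequency,
        100.0 * rec["n_clsig"] / rec["n_total"],
        np.nan,
    )
    return rec


def exact_signed_rank_p(diffs: np.ndarray) -> tuple[float, float, int]:
    """Two-sided Wilcoxon signed-rank p-value for paired differences.

    Zero differences are dropped; ties get midranks. The exact null
    distribution of the positive-rank sum is enumerated (dynamic programming
    over doubled midranks, equivalent to full enumeration of all 2^n sign
    assignments) for n <= 25; a normal approximation with continuity and tie
    correction is used above. Returns (p, W statistic, n used).
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("no nonzero differences")
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    total = float(ranks.sum())
    if n <= 25:
        # doubled ranks are integers even with .5 midranks
        r2 = np.rint(2 * ranks).astype(int)
        t2 = int(r2.sum())
        counts = np.zeros(t2 + 1)
        counts[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(counts)
            shifted[r:] = counts[: t2 + 1 - r]
            counts = counts + shifted
        counts /= 2.0**n
        w2 = int(round(2 * w))
        lo = min(w2, t2 - w2)
        hi = t2 - lo
        p = counts[: lo + 1].sum() + counts[hi:].sum()
        p = min(1.0, float(p))
    else:
        mean = total / 2.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (
            (tie_counts**3 - tie_counts).sum() / 48.0
        )
        if var <= 0:
            return 1.0, w, n
        z = (abs(w - mean) - 0.5) / math.sqrt(var)
        p = min(1.0, 2.0 * stats.norm.sf(z))
    return p, w, n


def paired_wilcoxon(
    x: Mapping[str, float] | pd.Series,
    y: Mapping[str, float] | pd.Series,
    params: AnalysisParameters | None = None,
    label: str = "",
) -> TestResult | _NotComputed:
    """Paired Wilcoxon signed-rank test over donor-matched values.

    ``x`` and ``y`` are keyed by donor; pairs with an UNDEFINED (NaN/missing)
    side are dropped. NOT_COMPUTED when fewer than ``min_donors_for_test``
    complete pairs remain or all differences are zero.
    """
    params = params or AnalysisParameters()
    xs = pd.Series(dict(x), dtype=float)
    ys = pd.Series(dict(y), dtype=float)
    donors = xs.dropna().index.intersection(ys.dropna().index)
    if len(donors) < params.min_donors_for_test:
        return NOT_COMPUTED
    diffs = (xs[donors] - ys[donors]).to_numpy()
    if np.all(diffs == 0):
        return NOT_COMPUTED
    p, w, n = exact_signed_rank_p(diffs)
    return TestResult(
        label=label or "paired_wilcoxon",
        method=TestMethod.PAIRED_WILCOXON,
        n=n,
        statistic=w,
        p_raw=p,
    )


def binomial_vs_reference(
    observed_k: int, n: int, p_ref: float, label: str = ""
) -> TestResult:
    """Two-sided exact binomial test of an observed count against a reference
    proportion (sum of outcome probabilities not exceeding that of k)."""
    if not 0 <= observed_k <= n:
        raise ValueError("require 0 <= k <= n")
    if not 0.0 <= p_ref <= 1.0:
        raise ValueError("p_ref must lie in [0, 1]")
    p = float(stats.binomtest(observed_k, n, p_ref).pvalue)
    return TestResult(
        label=label or "binomial",
        method=TestMethod.BINOMIAL,
        n=n,
        statistic=float(observed_k),
        p_raw=p,
    )


def bonferroni(results: Sequence[TestResult]) -> list[TestResult]:
    """Bonferroni correction over one declared family: p_adj = min(1, p*m)."""
    if not results:
        raise ValueError("empty test family")
    m = len(results)
    return [replace(r, p_adjusted=min(1.0, r.p_raw * m)) for r in results]


def vgene_usage_comparison(
    clsig: pd.DataFrame,
    controls: pd.DataFrame,
    definition,
    label: str = "",
) -> dict | _NotComputed:
    """Per-IGHV-gene usage of a subset's CLS-IG versus its core-feature controls.

    ``clsig``: clonotypes assigned to the subset; ``controls``: non-CLS-IG
    clonotypes passing the same core features. Returns the usage table plus
    binomial tests of the typical-gene share and the predominant-gene share in
    CLS-IG against the control shares.
    """
    if len(controls) == 0 or len(clsig) == 0:
        return NOT_COMPUTED
    usage = pd.DataFrame(
        {
            "clsig_freq": clsig["v_gene"].value_counts(normalize=True),
            "control_freq": controls["v_gene"].value_counts(normalize=True),
        }
    ).fillna(0.0)

    typical = definition.typical_v_genes
    k_typ = int(clsig["v_gene"].isin(typical).sum())
    p_ctrl_typ = float(controls["v_gene"].isin(typical).mean())
    typical_test = binomial_vs_reference(
        k_typ, len(clsig), p_ctrl_typ, label=f"{label}:typical_share"
    )
    predominant_test = None
    if definition.predominant_v_gene is not None:
        k_pre = int((clsig["v_gene"] == definition.predominant_v_gene).sum())
        p_ctrl_pre = float(
            (controls["v_gene"] == definition.predominant_v_gene).mean()
        )
        predominant_test = binomial_vs_reference(
            k_pre, len(clsig), p_ctrl_pre, label=f"{label}:predominant_share"
        )
    return {
        "usage": usage,
        "typical_share_clsig": k_typ / len(clsig),
        "typical_share_control": p_ctrl_typ,
        "typical_test": typical_test,
        "predominant_test": predominant_test,
    }
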