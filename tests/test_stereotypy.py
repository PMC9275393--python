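"""Subset assignment criteria, confidence grading, chimeras, typicality."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from clsig.annotate import annotate_sequence
from clsig.clonotype import cluster_clonotypes
from clsig.reference import AnalysisParameters, Confidence
from clsig.simulate import spike_stereotype, spike_cdr3_variant
from clsig.stereotypy import (
    MotifPattern,
    ResidueClassTable,
    SubsetDefinition,
    Typicality,
    assign_frame,
    assign_subset,
    cdr3_identity_pct,
    cdr3_similarity_pct,
    classify_typicality,
    grade_confidence,
    make_reverse_chimera,
    pattern_matches,
    prefilter_core,
)


class Rec:
    def __init__(self, cdr3, v_gene="IGHV1-2", mut=0.5, cid="c1"):
        self.clonotype_id = cid
        self.v_gene = v_gene
        self.v_mutation_pct = mut
        self.cdr3_aa = cdr3


def simple_def(**kw):
    base = dict(
        subset_id="S1",
        clan="I",
        core_mut_status="U",
        cdr3_length=6,
        reference_cdr3s=("ARDFGW",),
        pattern=MotifPattern(0, ("x",)),
        typical_v_genes=frozenset({"IGHV1-2"}),
        cll_reference_freq=0.1,
    )
    base.update(kw)
    return SubsetDefinition(**base)


# -- identity / similarity ---------------------------------------------------

def test_identity_hand_counts():
    assert cdr3_identity_pct("ARDFGW", "ARDFGW") == 100.0
    assert cdr3_identity_pct("ARDFGW", "ARDYGW") == pytest.approx(100 * 5 / 6)
    assert cdr3_identity_pct("AAAAAA", "GGGGGG") == 0.0
    with pytest.raises(ValueError):
        cdr3_identity_pct("AA", "AAA")


def test_similarity_class_table(classes):
    # F and Y are both aromatic: similarity stays 100 where identity drops
    assert cdr3_similarity_pct("ARDFGW", "ARDYGW", classes) == 100.0
    # D (negative) vs K (positive) differ in class
    assert cdr3_similarity_pct("D", "K", classes) == 0.0


@settings(derandomize=True, max_examples=100)
@given(
    a=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=20),
    b=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=20),
)
def test_similarity_never_below_identity(a, b, classes):
    L = min(len(a), len(b))
    a, b = a[:L], b[:L]
    assert cdr3_similarity_pct(a, b, classes) >= cdr3_identity_pct(a, b)


def test_residue_classes_total_and_disjoint(classes):
    seen = set()
    for members in classes.classes.values():
        assert not (seen & members)
        seen |= members
    assert seen == set("ACDEFGHIKLMNPQRSTVWY")


# -- prefilter ---------------------------------------------------------------

def test_prefilter_rejects_wrong_length(clans):
    d = simple_def(cdr3_length=13, reference_cdr3s=("ARDFGWARDFGWA",))
    assert not prefilter_core(Rec("ARDFGWARDFGW"), d, clans)  # 12 vs 13


def test_prefilter_rejects_wrong_clan(clans):
    d = simple_def()
    assert not prefilter_core(Rec("ARDFGW", v_gene="IGHV3-21"), d, clans)


def test_prefilter_rejects_wrong_status_and_either_matches_all(clans):
    d = simple_def()
    assert not prefilter_core(Rec("ARDFGW", mut=5.0), d, clans)  # M vs U core
    assert prefilter_core(Rec("ARDFGW", mut=0.5), d, clans)
    d2 = simple_def(core_mut_status="EITHER")
    assert prefilter_core(Rec("ARDFGW", mut=5.0), d2, clans)


# -- pattern -----------------------------------------------------------------

def test_pattern_literal_class_and_any(classes):
    pat = MotifPattern(1, ("R", "aromatic", "x"))
    assert pattern_matches("ARFQ", pat, classes)
    assert pattern_matches("ARYD", pat, classes)
    assert not pattern_matches("AKFQ", pat, classes)  # literal R missing
    assert not pattern_matches("ARLQ", pat, classes)  # L not aromatic
    assert not pattern_matches("AR", pat, classes)  # runs past the end


# -- grading and assignment --------------------------------------------------

def test_exact_reference_match_is_excellent(clans, classes, params):
    d = simple_def()
    a = assign_subset(Rec("ARDFGW"), [d], clans, classes, params)
    assert a.subset_id == "S1"
    assert a.confidence is Confidence.EXCELLENT
    assert a.typicality is Typicality.TYPICAL


def test_below_identity_threshold_is_none(clans, classes, params):
    # identity 2/6 = 33% < 50%
    a = assign_subset(Rec("ARKKKK"), [simple_def()], clans, classes, params)
    assert a.subset_id is None


def test_exact_thresholds_grade_borderline_and_are_gated():
    p = AnalysisParameters()
    assert grade_confidence(50.0, 70.0, p) is Confidence.BORDERLINE
    assert grade_confidence(55.0, 75.0, p) is Confidence.AVERAGE
    assert grade_confidence(70.0, 75.0, p) is Confidence.GOOD
    assert grade_confidence(90.0, 100.0, p) is Confidence.EXCELLENT
    assert Confidence.BORDERLINE < p.min_confidence


def test_borderline_candidate_not_reported(clans, classes):
    # 10-mer: identity 5/10 = 50%, similarity 7/10 = 70% -> BORDERLINE -> None
    ref = "ARDFGWKLMN"
    d = simple_def(cdr3_length=10, reference_cdr3s=(ref,))
    # positions 0-4 identical; 5,6 class-preserving (W->Y? keep aromatic; K->R);
    # 7-9 class-breaking
    query = "ARDFG" + "Y" + "R" + "DDD"
    assert cdr3_identity_pct(query, ref) == 50.0
    assert cdr3_similarity_pct(query, ref) == 70.0
    a = assign_subset(Rec(query), [d], clans, classes)
    assert a.subset_id is None
    assert a.confidence is Confidence.BORDERLINE


def test_exact_tie_across_subsets_is_ambiguous_none(clans, classes, params):
    d1 = simple_def(subset_id="S1", reference_cdr3s=("ARDFGW",))
    d2 = simple_def(subset_id="S2", reference_cdr3s=("ARDFGW",))
    a = assign_subset(Rec("ARDFGW"), [d1, d2], clans, classes, params)
    assert a.subset_id is None and a.ambiguous


def test_assignment_exclusive_and_prefilter_sound(subset_defs, clans, classes,
                                                  params, rng):
    """Every reported assignment passes the core prefilter; one subset max."""
    from clsig.simulate import SimulationConfig, SpikePlan, simulate_cohort_frame
    from clsig.clonotype import cluster_frame

    cfg = SimulationConfig(
        seed=7, n_donors=1, molecules_per_fraction=200,
        spikes=(SpikePlan("T01", 0.01), SpikePlan("T05", 0.01)),
    )
    df = simulate_cohort_frame(cfg, subset_defs)
    clono = cluster_frame(df)
    asg = assign_frame(clono, subset_defs, clans, classes, params)
    by_id = {d.subset_id: d for d in subset_defs}
    assigned = asg[asg["is_clsig"]]
    assert len(assigned) > 0
    for row in assigned.itertuples():
        assert prefilter_core(row, by_id[row.subset_id], clans, params)


def test_frame_and_scalar_assignment_agree(subset_defs, clans, classes, params,
                                           rng):
    from clsig.simulate import SimulationConfig, SpikePlan, simulate_cohort_frame
    from clsig.clonotype import cluster_frame

    cfg = SimulationConfig(
        seed=11, n_donors=1, molecules_per_fraction=150,
        spikes=tuple(SpikePlan(s, 0.02) for s in ("T01", "T02", "T03")),
    )
    df = simulate_cohort_frame(cfg, subset_defs)
    clono = cluster_frame(df)
    asg = assign_frame(clono, subset_defs, clans, classes, params)
    for row in asg.itertuples():
        a = assign_subset(row, subset_defs, clans, classes, params)
        want = row.subset_id if pd.notna(row.subset_id) else None
        assert (a.subset_id or None) == want
        if a.assigned:
            assert a.best_identity_pct == pytest.approx(row.best_identity_pct)


# -- typicality --------------------------------------------------------------

def test_typicality_membership(clans, classes, params):
    d = simple_def(typical_v_genes=frozenset({"IGHV1-2"}))
    a = assign_subset(Rec("ARDFGW", v_gene="IGHV1-2"), [d], clans, classes, params)
    assert classify_typicality(a, Rec("ARDFGW", v_gene="IGHV1-2"), d, clans) is (
        Typicality.TYPICAL
    )
    b = assign_subset(Rec("ARDFGW", v_gene="IGHV1-69"), [d], clans, classes, params)
    assert b.typicality is Typicality.NON_TYPICAL
    # unassigned clonotype keeps NA
    c = assign_subset(Rec("ARKKKK"), [d], clans, classes, params)
    assert c.typicality is Typicality.NA
    assert classify_typicality(c, Rec("ARKKKK"), d, clans) is Typicality.NA


# -- chimeras ----------------------------------------------------------------

def _spiked_rearrangement(subset_defs, germline, fraction, rng, status):
    d = next(x for x in subset_defs if x.core_mut_status.value == status)
    seq, truth = spike_stereotype(d, germline, fraction, rng)
    r = annotate_sequence("sp", seq, germline, fraction)
    return d, r


def test_chimera_m_to_u_zeroes_mutation(subset_defs, germline, fraction, rng):
    d, r = _spiked_rearrangement(subset_defs, germline, fraction, rng, "M")
    assert r.status().value == "M"
    ch = make_reverse_chimera(r, germline, rng)
    assert ch.status().value == "U"
    assert ch.v_mutation_pct == 0.0
    assert ch.cdr3_aa == r.cdr3_aa
    assert ch.productive


def test_chimera_u_to_m_reaches_target(subset_defs, germline, fraction, rng):
    d, r = _spiked_rearrangement(subset_defs, germline, fraction, rng, "U")
    ch = make_reverse_chimera(r, germline, rng, target_mut_pct=4.0)
    assert ch.status().value == "M"
    assert 2.0 <= ch.v_mutation_pct <= 4.0 + 100.0 / 250  # one sub of slack
    assert ch.cdr3_aa == r.cdr3_aa


def test_chimera_involution_on_status(subset_defs, germline, fraction, rng):
    _, r = _spiked_rearrangement(subset_defs, germline, fraction, rng, "U")
    twice = make_reverse_chimera(
        make_reverse_chimera(r, germline, rng), germline, rng
    )
    assert twice.status().value == r.status().value
    assert twice.cdr3_aa == r.cdr3_aa


def test_chimera_target_below_threshold_rejected(subset_defs, germline,
                                                 fraction, rng):
    _, r = _spiked_rearrangement(subset_defs, germline, fraction, rng, "U")
    with pytest.raises(ValueError):
        make_reverse_chimera(r, germline, rng, target_mut_pct=1.0)


def test_rclsig_scan_direction(subset_defs, germline, fraction, rng, clans,
                               params, classes):
    """Chimeras of clonotypes assigned to status-restricted subsets lose the
    assignment; CDR3 is always preserved."""
    from clsig.stereotypy import rclsig_scan

    mols = []
    restricted = [d for d in subset_defs if d.core_mut_status.value in "UM"][:3]
    either = [d for d in subset_defs if d.core_mut_status.value == "EITHER"][:1]
    i = 0
    for d in restricted + either:
        for _ in range(3):
            seq, _ = spike_stereotype(d, germline, fraction, rng,
                                      molecule_id=f"S{i}")
            r = annotate_sequence(f"S{i}", seq, germline, fraction)
            mols.append(r)
            i += 1
    clons = cluster_clonotypes(mols)
    table = rclsig_scan(clons, germline, subset_defs, clans, rng,
                        classes, params)
    assert table["cdr3_preserved"].all()
    assert (table["native_status"] != table["reversed_status"]).all()
    native_restricted = table[table["native_subset"].isin(
        [d.subset_id for d in restricted])]
    assert len(native_restricted) > 0
    assert not native_restricted["reversed_assigned"].any()
    native_either = table[table["native_subset"].isin(
        [d.subset_id for d in either])]
    assert native_either["reversed_assigned"].all()
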