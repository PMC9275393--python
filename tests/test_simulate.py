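"""Synthetic cohort generator: determinism, truth consistency, spike rules."""

import numpy as np
import pandas as pd
import pytest

from clsig.annotate import annotate_sequence
from clsig.preprocess import consensus_pass, read_fastq_with_umi, read_samplesheet
from clsig.simulate import (
    SimulationConfig,
    SpikePlan,
    all_fractions,
    emit_reads,
    simulate_cohort_frame,
    simulate_rearrangement,
    spike_cdr3_variant,
    spike_stereotype,
)
from clsig.stereotypy import cdr3_identity_pct, cdr3_similarity_pct


def test_u_stratum_draw_is_below_threshold(germline, fraction):
    rng = np.random.default_rng(5)
    for i in range(30):
        _, truth = simulate_rearrangement(germline, fraction, "U", rng)
        assert truth.v_mutation_pct < 2.0
    for i in range(30):
        _, truth = simulate_rearrangement(germline, fraction, "M", rng)
        assert truth.v_mutation_pct >= 2.0


def test_fixed_seed_reproduces_sequence(germline, fraction):
    a, _ = simulate_rearrangement(germline, fraction, "M",
                                  np.random.default_rng(99))
    b, _ = simulate_rearrangement(germline, fraction, "M",
                                  np.random.default_rng(99))
    assert a == b


def test_annotation_recovers_truth(germline, fraction):
    rng = np.random.default_rng(17)
    for i in range(30):
        status = "U" if i % 2 else "M"
        seq, truth = simulate_rearrangement(germline, fraction, status, rng)
        r = annotate_sequence("x", seq, germline, fraction)
        assert r.v_call == truth.v_call
        assert r.j_call == truth.j_call
        assert r.junction_aa == truth.junction_aa
        assert r.v_mutation_pct == pytest.approx(truth.v_mutation_pct)


def test_spike_variant_identity_arithmetic(subset_defs, classes):
    d = next(x for x in subset_defs if x.cdr3_length == 13)
    rng = np.random.default_rng(3)
    v = spike_cdr3_variant(d, rng, n_subs=(2, 2), classes=classes)
    best = max(cdr3_identity_pct(v, r) for r in d.reference_cdr3s)
    assert best >= 100 * 11 / 13 - 1e-9
    assert max(cdr3_similarity_pct(v, r, classes)
               for r in d.reference_cdr3s) == 100.0


def test_spike_zero_subs_equals_reference(subset_defs, classes):
    d = subset_defs[0]
    rng = np.random.default_rng(4)
    v = spike_cdr3_variant(d, rng, n_subs=(0, 0), classes=classes)
    assert v in d.reference_cdr3s


def test_spike_too_many_subs_is_error(subset_defs, classes):
    d = subset_defs[0]
    rng = np.random.default_rng(4)
    with pytest.raises(ValueError):
        spike_cdr3_variant(d, rng, n_subs=(50, 50), classes=classes)


def test_spike_to_u_core_subset_is_u(subset_defs, germline, fraction):
    rng = np.random.default_rng(6)
    d = next(x for x in subset_defs if x.core_mut_status.value == "U")
    _, truth = spike_stereotype(d, germline, fraction, rng)
    assert truth.v_mutation_pct < 2.0
    assert truth.spike_subset == d.subset_id


def test_emit_reads_umi_uniqueness_and_truth_join(germline, fraction, tmp_path):
    rng = np.random.default_rng(8)
    cfg = SimulationConfig(seed=8, error_rate=0.0)
    mols = [
        simulate_rearrangement(germline, fraction, "U", rng, cfg, f"M{i}")
        for i in range(40)
    ]
    sheet_path, truth_path = emit_reads(mols, cfg, rng, tmp_path,
                                        reads_per_molecule=3)
    truth = pd.read_csv(truth_path, sep="\t")
    assert len(truth) == 40
    assert truth["umi"].is_unique
    fractions = read_samplesheet(sheet_path)
    [(fname, frac)] = list(fractions.items())
    reads = read_fastq_with_umi(tmp_path / fname, frac)
    assert len(reads) == 120
    # every read joins to exactly one truth record via its UMI
    by_umi = truth.set_index("umi")["molecule_id"]
    for r in reads:
        assert r.read_id.rsplit("_r", 1)[0] == by_umi[r.umi]


def test_error_free_reads_recover_molecules_end_to_end(germline, fraction,
                                                       tmp_path):
    """epsilon=0 and >=2 reads per molecule: consensus equals each molecule."""
    rng = np.random.default_rng(9)
    cfg = SimulationConfig(seed=9, error_rate=0.0)
    mols = [
        simulate_rearrangement(germline, fraction, "M", rng, cfg, f"M{i}")
        for i in range(25)
    ]
    emit_reads(mols, cfg, rng, tmp_path, reads_per_molecule=2)
    fractions = read_samplesheet(tmp_path / "samplesheet.tsv")
    reads = []
    for fname, frac in fractions.items():
        reads.extend(read_fastq_with_umi(tmp_path / fname, frac))
    kept, rejected = consensus_pass(reads)
    assert not rejected
    assert sorted(c.sequence for c in kept) == sorted(m[0] for m in mols)


def test_cohort_frame_structure_and_determinism(subset_defs):
    cfg = SimulationConfig(seed=21, n_donors=2, molecules_per_fraction=40,
                           spikes=(SpikePlan("T01", 0.01),))
    a = simulate_cohort_frame(cfg, subset_defs)
    b = simulate_cohort_frame(cfg, subset_defs)
    pd.testing.assert_frame_equal(a, b)
    assert len(a) == 2 * 24 * 40
    assert set(a["b_subset"]) == {"TR", "N", "MZ", "MO", "SM", "DN"}
    # U/M consistency between drawn status and mutation percent
    assert (a.loc[a["true_status"] == "U", "v_mutation_pct"] < 2).all()
    assert (a.loc[a["true_status"] == "M", "v_mutation_pct"] >= 2).all()


def test_cohort_spike_rate_within_status(subset_defs):
    d = next(x for x in subset_defs if x.core_mut_status.value == "U")
    cfg = SimulationConfig(seed=31, n_donors=3, molecules_per_fraction=600,
                           spikes=(SpikePlan(d.subset_id, 0.01, "status"),))
    df = simulate_cohort_frame(cfg, subset_defs)
    spiked = df["spike_subset"] == d.subset_id
    # spikes live only in U molecules, at roughly the requested rate
    assert (df.loc[spiked, "true_status"] == "U").all()
    n_u = (df["true_status"] == "U").sum()
    rate = spiked.sum() / n_u
    assert rate == pytest.approx(0.01, rel=0.35)
    # spiked rows use typical V genes of the subset
    assert df.loc[spiked, "v_call"].isin(d.typical_v_genes).all()


def test_stratum_plan_shifts_u_fraction():
    cfg = SimulationConfig(seed=1)
    assert cfg.u_fraction("TR", "POS") > cfg.u_fraction("TR", "NEG")
    assert cfg.u_fraction("N", "NEG") > cfg.u_fraction("SM", "NEG")


def test_all_fractions_covers_24_per_donor():
    fr = all_fractions(2)
    assert len(fr) == 48
    assert len({f.key() for f in fr}) == 48
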