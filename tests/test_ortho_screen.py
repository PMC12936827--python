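"""Six-contrast framework and the set-algebra screen."""

import numpy as np
import pytest

from npxscreen import (
    AnalysisConfig,
    EBayesPrior,
    SimulationConfig,
    build_screen_sets,
    evaluate_recovery,
    run_contrasts,
    simulate_cohort,
    validate_design,
)
from npxscreen.diffexp import ContrastResult
from npxscreen.ortho_screen import CONTRASTS

from conftest import make_matrix, make_trial_samples


def fake_result(name, pvalues, betas=None):
    ids = sorted(pvalues)
    p = np.array([pvalues[g] for g in ids], float)
    b = np.array([1.0 if betas is None else betas[g] for g in ids], float)
    return ContrastResult(
        contrast=name, protein_ids=ids, beta_hat=b, t_mod=b, df_total=np.full(len(ids), 10.0),
        p=p, prior=EBayesPrior(1.0, 1.0), s2_post=np.ones(len(ids)),
    )


def test_contrast_table_matches_trial_axes():
    assert (CONTRASTS["G1"].group_a, CONTRASTS["G1"].group_b) == ("T2", "C1")
    assert (CONTRASTS["G2"].group_a, CONTRASTS["G2"].group_b) == ("C2", "T1")
    assert (CONTRASTS["G3"].group_a, CONTRASTS["G3"].group_b) == ("T1", "C1")
    assert (CONTRASTS["G4"].group_a, CONTRASTS["G4"].group_b) == ("T2", "C2")
    assert CONTRASTS["P1"].paired and CONTRASTS["P1"].arm == "treatment"
    assert CONTRASTS["P2"].paired and CONTRASTS["P2"].arm == "control"
    assert sum(not c.paired for c in CONTRASTS.values()) == 4


def test_planted_positive_interaction_is_positive_in_g4_and_p1(analysis_config):
    cfg = SimulationConfig(
        delta=2.0, sigma=0.2, tau=0.3,
        class_counts={"null": 91, "treatment_specific": 1, "time_dependent": 0,
                      "baseline_shifted": 0, "mixed": 0},
        random_signs=False, seed=17,
    )
    matrix, truth = simulate_cohort(cfg)
    (g,) = truth.proteins_of_class("treatment_specific")
    results = run_contrasts(matrix, validate_design(matrix), analysis_config)
    for name in ("G4", "P1"):
        res = results[name]
        i = res.protein_ids.index(g)
        assert res.beta_hat[i] > 0
        assert res.p[i] < 0.01


def test_missing_group_is_hard_error(analysis_config):
    samples = [s for s in make_trial_samples(4, 4)
               if not (s.subject_id.startswith("C") and s.timepoint.value == "post")]
    m = make_matrix(np.random.default_rng(0).normal(size=(5, len(samples))),
                    [f"g{i}" for i in range(5)], samples)
    with pytest.raises(ValueError, match="empty"):
        run_contrasts(m, validate_design(m), analysis_config)


def test_paper_instance_cardinalities(analysis_config):
    """Memberships with |set1|=24, |set2|=14, |set3|=45, |set1&set2|=5,
    |set1&set3|=16 must yield |set4|=19 and |set5|=16."""
    G = 92
    ids = [f"g{i:02d}" for i in range(G)]
    # lay out memberships by index: set1 = 0..23; set2 = 19..32 (5 inside set1);
    # set3 = 8..23 (16 inside set1) plus 29 more outside
    in1 = set(ids[0:24])
    in2 = set(ids[19:33])
    in3 = set(ids[8:24]) | set(ids[33:62])
    assert len(in1) == 24 and len(in2) == 14 and len(in3) == 45
    assert len(in1 & in2) == 5 and len(in1 & in3) == 16

    lo, hi = 0.01, 0.5  # below / above alpha
    results = {
        "G3": fake_result("G3", {g: hi for g in ids}),  # no baseline differences
        "G4": fake_result("G4", {g: (lo if g in in1 else hi) for g in ids}),
        "P2": fake_result("P2", {g: (lo if g in in2 else hi) for g in ids}),
        "P1": fake_result("P1", {g: (lo if g in in3 else hi) for g in ids}),
    }
    sets = build_screen_sets(results, analysis_config)
    card = sets.cardinalities()
    assert card["set1"] == 24 and card["set2"] == 14 and card["set3"] == 45
    assert card["set4"] == 19
    assert card["set5"] == 16
    assert sets.core == (sets.set1 & sets.set3) - sets.set2


def test_empty_set1_empties_the_derived_sets(analysis_config):
    ids = [f"g{i}" for i in range(10)]
    results = {
        "G3": fake_result("G3", {g: 0.5 for g in ids}),
        "G4": fake_result("G4", {g: 0.5 for g in ids}),  # nothing significant post
        "P2": fake_result("P2", {g: 0.01 for g in ids}),
        "P1": fake_result("P1", {g: 0.01 for g in ids}),
    }
    sets = build_screen_sets(results, analysis_config)
    assert sets.set1 == set() and sets.set4 == set() and sets.set5 == set() and sets.core == set()


def test_missing_contrast_is_error(analysis_config):
    ids = ["a", "b"]
    results = {"G3": fake_result("G3", {g: 0.5 for g in ids})}
    with pytest.raises(ValueError, match="missing"):
        build_screen_sets(results, analysis_config)


def test_core_identity_on_random_membership_configurations(analysis_config):
    """core = (set1 & set3) \\ set2, checked against the raw p-vectors."""
    rng = np.random.default_rng(123)
    ids = [f"g{i}" for i in range(50)]
    for _ in range(1000):
        p = {c: dict(zip(ids, rng.uniform(0, 1, len(ids)))) for c in ("G3", "G4", "P1", "P2")}
        results = {c: fake_result(c, p[c]) for c in p}
        sets = build_screen_sets(results, analysis_config)
        a = analysis_config.alpha
        set1 = {g for g in ids if p["G3"][g] > a and p["G4"][g] < a}
        set2 = {g for g in ids if p["P2"][g] < a}
        set3 = {g for g in ids if p["P1"][g] < a}
        assert sets.core == (set1 & set3) - set2
        assert sets.set4 == set1 - set2 and sets.set5 == set1 & set3
        assert sets.set4 <= sets.set1
        assert len(sets.set5) >= len(sets.core)


def test_core_is_not_monotone_in_alpha(analysis_config):
    """Raising alpha can eject a protein from the core via the set2 criterion."""
    ids = ["a"]
    p = {"G3": {"a": 0.9}, "G4": {"a": 0.001}, "P1": {"a": 0.001}, "P2": {"a": 0.03}}
    results = {c: fake_result(c, p[c]) for c in p}
    strict = build_screen_sets(results, AnalysisConfig(alpha=0.01))
    loose = build_screen_sets(results, AnalysisConfig(alpha=0.05))
    assert strict.core == {"a"} and loose.core == set()


def test_dropped_protein_shrinks_screen_universe(analysis_config):
    ids = ["a", "b", "c"]
    results = {
        "G3": fake_result("G3", {g: 0.5 for g in ids}),
        "G4": fake_result("G4", {g: 0.01 for g in ids}),
        "P1": fake_result("P1", {g: 0.01 for g in ids if g != "c"}),  # c dropped in P1
        "P2": fake_result("P2", {g: 0.5 for g in ids}),
    }
    sets = build_screen_sets(results, analysis_config)
    assert sets.universe == {"a", "b"}
    assert sets.core == {"a", "b"}


# ---- recovery evaluation ----


def test_noise_free_strong_effects_recover_perfectly(analysis_config):
    cfg = SimulationConfig(
        delta=3.0, gamma=-2.0, sigma=0.05, tau=0.05,
        class_counts={"null": 72, "treatment_specific": 10, "time_dependent": 10,
                      "baseline_shifted": 0, "mixed": 0},
        seed=29,
    )
    matrix, truth = simulate_cohort(cfg)
    results = run_contrasts(matrix, validate_design(matrix), analysis_config)
    sets = build_screen_sets(results, analysis_config)
    report = evaluate_recovery(sets, truth)
    assert report.sensitivity == 1.0
    assert report.leakage["time_dependent"] == 0.0


def test_universe_mismatch_is_error(default_cohort, analysis_config):
    matrix, truth = default_cohort
    design = validate_design(matrix)
    results = run_contrasts(matrix, design, analysis_config)
    sets = build_screen_sets(results, analysis_config)
    sets.universe = sets.universe - {truth.protein_ids[0]}
    with pytest.raises(ValueError, match="mismatch"):
        evaluate_recovery(sets, truth)
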