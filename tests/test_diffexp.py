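"""Moderated-t machinery: ordinary stats, prior fit, shrinkage, FDR.

The moderated test is cross-checked three ways: against its own classic-t
limit (d0 = 0), against a straight-line reimplementation of the shrinkage
formulas, and against the reference R implementation of the same
hierarchical model (limma) on a shared random dataset.
"""

import subprocess
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from npxscreen import (
    AnalysisConfig,
    EBayesPrior,
    OrdinaryStats,
    bh_fdr,
    classify_deps,
    fit_ebayes_prior,
    moderated_test,
    ordinary_stats,
    validate_design,
)
from npxscreen.ortho_screen import ContrastSpec

from conftest import make_matrix, make_trial_samples


def stats_from_arrays(beta, s2, d, u, ids=None):
    n = len(beta)
    return OrdinaryStats(
        protein_ids=ids or [f"g{i}" for i in range(n)],
        beta_hat=np.asarray(beta, float),
        s2=np.asarray(s2, float),
        d=np.asarray(d, float),
        u=np.asarray(u, float),
    )


def two_group_matrix(a_vals, b_vals):
    """One-protein matrix: T1 holds group A, C1 group B (plus dummy post cells)."""
    samples = make_trial_samples(len(a_vals), len(b_vals))
    m = make_matrix(np.zeros((1, len(samples))), ["p1"], samples)
    for i, v in enumerate(a_vals):
        m.values[0, m.sample_index(f"T{i + 1:02d}_B")] = v
    for i, v in enumerate(b_vals):
        m.values[0, m.sample_index(f"C{i + 1:02d}_B")] = v
    return m


# ---- ordinary statistics ----


def test_unpaired_identical_groups_give_zero_effect():
    m = two_group_matrix([1, 2, 3], [1, 2, 3])
    st_ = ordinary_stats(m, validate_design(m), ContrastSpec("G3", "T1", "C1"))
    assert st_.beta_hat[0] == 0.0
    assert st_.d[0] == 4
    assert np.isclose(st_.u[0], np.sqrt(2 / 3))


def test_paired_hand_computed_example():
    # within-subject differences D = (1.0, 1.2, 0.8, 1.0)
    samples = make_trial_samples(4, 2)
    m = make_matrix(np.zeros((1, len(samples))), ["p1"], samples)
    for i, diff in enumerate([1.0, 1.2, 0.8, 1.0]):
        m.values[0, m.sample_index(f"T{i + 1:02d}_B")] = 5.0
        m.values[0, m.sample_index(f"T{i + 1:02d}_P")] = 5.0 + diff
    st_ = ordinary_stats(m, validate_design(m), ContrastSpec("P1", "T2", "T1", paired=True, arm="treatment"))
    assert np.isclose(st_.beta_hat[0], 1.0)
    assert np.isclose(st_.s2[0], 0.08 / 3)
    assert st_.d[0] == 3
    assert np.isclose(st_.u[0], 0.5)


def test_protein_with_single_pair_is_dropped_with_reason():
    samples = make_trial_samples(4, 2)
    m = make_matrix(np.zeros((2, len(samples))), ["p1", "p2"], samples)
    m.values += np.arange(len(samples))  # non-degenerate
    # p2 observed for only one treatment pair
    for j, s in enumerate(samples):
        if s.subject_id != "T01" and s.subject_id.startswith("T"):
            m.missing_mask[1, j] = True
    st_ = ordinary_stats(m, validate_design(m), ContrastSpec("P1", "T2", "T1", paired=True, arm="treatment"))
    assert st_.protein_ids == ["p1"]
    assert "p2" in st_.dropped and "pair" in st_.dropped["p2"]


# ---- empirical-Bayes prior ----


def test_prior_recovery_on_generative_model():
    rng = np.random.default_rng(0)
    d0_true, s0_true, G, d = 4.0, 1.0, 2000, 40
    sigma2 = s0_true * d0_true / rng.chisquare(d0_true, size=G)
    s2 = sigma2 * rng.chisquare(d, size=G) / d
    prior = fit_ebayes_prior(stats_from_arrays(np.zeros(G), s2, np.full(G, d), np.ones(G)))
    assert abs(prior.d0 - d0_true) / d0_true < 0.2
    assert abs(prior.s0_sq - s0_true) / s0_true < 0.1


def test_equal_variances_take_infinite_d0_branch():
    prior = fit_ebayes_prior(stats_from_arrays([0, 0, 0], [0.5, 0.5, 0.5], [10, 10, 10], [1, 1, 1]))
    assert np.isinf(prior.d0)
    # zero dispersion of log s2: s0^2 = exp(e-bar), the bias-corrected common variance
    from scipy.special import digamma

    assert np.isclose(prior.s0_sq, np.exp(np.log(0.5) - digamma(5) + np.log(5)))
    # with d0 = inf the posterior variance is s0_sq for every protein
    res = moderated_test(stats_from_arrays([1, -1, 0], [0.5, 0.4, 0.6], [10, 10, 10], [1, 1, 1]), prior)
    assert np.allclose(res.s2_post, prior.s0_sq)


def test_single_protein_cannot_be_moderated():
    with pytest.raises(ValueError, match="2 proteins"):
        fit_ebayes_prior(stats_from_arrays([1.0], [0.5], [5], [1.0]))


def test_all_zero_variances_are_degenerate():
    with pytest.raises(ValueError, match="zero"):
        fit_ebayes_prior(stats_from_arrays([1, 2], [0.0, 0.0], [5, 5], [1, 1]))


# ---- moderated test ----


def test_d0_zero_reproduces_classic_t():
    rng = np.random.default_rng(1)
    n = 30
    beta = rng.normal(size=n)
    s2 = rng.chisquare(5, size=n) / 5
    d = np.full(n, 7.0)
    u = np.full(n, 0.5)
    res = moderated_test(stats_from_arrays(beta, s2, d, u), EBayesPrior(d0=0.0, s0_sq=1.0))
    t_classic = beta / (np.sqrt(s2) * u)
    p_classic = 2 * sps.t.sf(np.abs(t_classic), 7)
    assert np.allclose(res.t_mod, t_classic, atol=1e-10)
    assert np.allclose(res.p, p_classic, atol=1e-10)


def test_d0_infinite_uses_normal_tail():
    res = moderated_test(
        stats_from_arrays([1.0], [0.3], [5], [0.5]), EBayesPrior(d0=np.inf, s0_sq=0.25)
    )
    t_expect = 1.0 / (0.5 * 0.5)
    assert np.isclose(res.t_mod[0], t_expect)
    assert np.isclose(res.p[0], 2 * sps.norm.sf(t_expect), atol=1e-12)


def test_shrinkage_formulas_match_straight_line_reimplementation():
    """Paired example with d0=4, s0^2=0.05 vs an independent line-by-line oracle."""
    beta, s2, d, u = 1.0, 0.08 / 3, 3.0, 0.5
    d0, s0 = 4.0, 0.05
    res = moderated_test(stats_from_arrays([beta], [s2], [d], [u]), EBayesPrior(d0, s0))
    s2_post = (d0 * s0 + d * s2) / (d0 + d)
    t_oracle = beta / (np.sqrt(s2_post) * u)
    p_oracle = 2 * sps.t.sf(abs(t_oracle), d0 + d)
    assert np.isclose(res.s2_post[0], (4 * 0.05 + 3 * 0.08 / 3) / 7, atol=1e-15)
    assert np.isclose(res.t_mod[0], t_oracle, atol=1e-12)
    assert np.isclose(res.p[0], p_oracle, atol=1e-12)


@given(st.floats(0.1, 50.0))
@settings(deadline=None, max_examples=30)
def test_posterior_variance_lies_between_s2_and_prior(d0):
    s2 = np.array([0.1, 0.5, 2.0])
    prior = EBayesPrior(d0=d0, s0_sq=0.7)
    res = moderated_test(stats_from_arrays([1, 1, 1], s2, [5, 5, 5], [1, 1, 1]), prior)
    lo = np.minimum(s2, prior.s0_sq)
    hi = np.maximum(s2, prior.s0_sq)
    assert np.all(res.s2_post >= lo - 1e-12) and np.all(res.s2_post <= hi + 1e-12)
    # larger d0 pulls the posterior variance monotonically toward s0_sq
    res2 = moderated_test(stats_from_arrays([1, 1, 1], s2, [5, 5, 5], [1, 1, 1]),
                          EBayesPrior(d0=d0 * 2, s0_sq=0.7))
    assert np.all(np.abs(res2.s2_post - 0.7) <= np.abs(res.s2_post - 0.7) + 1e-12)


def test_sign_of_t_follows_sign_of_effect():
    res = moderated_test(
        stats_from_arrays([2.0, -3.0, 0.0], [0.5, 0.5, 0.5], [5, 5, 5], [1, 1, 1]),
        EBayesPrior(d0=4.0, s0_sq=0.5),
    )
    assert np.sign(res.t_mod[0]) == 1 and np.sign(res.t_mod[1]) == -1 and res.t_mod[2] == 0


# ---- DEP classification ----


@pytest.mark.parametrize(
    "p,beta,expected_p_only,expected_p_and_fc",
    [
        (0.04, 0.6, "up", "up"),
        (0.04, 0.3, "up", "ns"),  # the Methods-vs-volcano threshold divergence
        (0.50, 2.0, "ns", "ns"),
        (0.04, -0.6, "down", "down"),
        (0.05, 0.6, "ns", "ns"),  # tie at alpha is not significant
    ],
)
def test_dep_classification_rules(p, beta, expected_p_only, expected_p_and_fc):
    from npxscreen.diffexp import ContrastResult

    res = ContrastResult(
        contrast="G4", protein_ids=["g"], beta_hat=np.array([beta]),
        t_mod=np.array([1.0]), df_total=np.array([10.0]), p=np.array([p]),
        prior=EBayesPrior(1.0, 1.0), s2_post=np.array([1.0]),
    )
    cfg = AnalysisConfig()
    labels, counts = classify_deps(res, cfg, rule="p_only")
    assert labels[0] == expected_p_only
    assert sum(counts.values()) == 1
    labels, _ = classify_deps(res, cfg, rule="p_and_fc")
    assert labels[0] == expected_p_and_fc


# ---- BH FDR ----


def bh_oracle(p):
    """Hand step-up: q_(i) = min_{j >= i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@pytest.mark.parametrize(
    "p,expected",
    [
        ((0.01, 0.02, 0.03, 0.04), (0.04, 0.04, 0.04, 0.04)),
        ((0.2,), (0.2,)),
        ((0.5, 1.0), (1.0, 1.0)),
    ],
)
def test_bh_known_values(p, expected):
    assert np.allclose(bh_fdr(p), expected, atol=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50))
@settings(deadline=None, max_examples=200)
def test_bh_matches_hand_oracle(p):
    assert np.allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)


# ---- cross-check against the reference R implementation ----


def test_moderated_t_matches_limma_on_shared_dataset(tmp_path):
    """Same unpaired two-group dataset through our code and through limma."""
    rng = np.random.default_rng(7)
    G, na, nb = 40, 8, 6
    data = rng.normal(5.0, 1.0, size=(G, na + nb))
    data[:5, :na] += 1.0  # a few real effects
    np.savetxt(tmp_path / "x.tsv", data, delimiter="\t")
    script = textwrap.dedent(
        f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.table("{tmp_path}/x.tsv", sep="\\t"))
        design <- cbind(Intercept=1, GroupA=c(rep(1,{na}), rep(0,{nb})))
        fit <- eBayes(lmFit(x, design))
        out <- data.frame(t=fit$t[,2], p=fit$p.value[,2],
                          d0=fit$df.prior, s0=fit$s2.prior)
        write.table(out, "{tmp_path}/limma.tsv", sep="\\t", row.names=FALSE)
        """
    )
    subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
    ref = np.genfromtxt(tmp_path / "limma.tsv", delimiter="\t", names=True)

    samples = make_trial_samples(na, nb)
    m = make_matrix(np.zeros((G, len(samples))), [f"g{i}" for i in range(G)], samples)
    a_cols = [m.sample_index(f"T{i + 1:02d}_B") for i in range(na)]
    b_cols = [m.sample_index(f"C{i + 1:02d}_B") for i in range(nb)]
    m.values[:, a_cols] = data[:, :na]
    m.values[:, b_cols] = data[:, na:]
    # dummy post cells so the design validates; the G3 contrast ignores them
    post = [j for j, s in enumerate(samples) if s.timepoint.value == "post"]
    m.values[:, post] = rng.normal(size=(G, len(post)))

    st_ = ordinary_stats(m, validate_design(m), ContrastSpec("G3", "T1", "C1"))
    prior = fit_ebayes_prior(st_)
    res = moderated_test(st_, prior)
    assert np.isclose(prior.d0, ref["d0"][0], rtol=1e-4)
    assert np.isclose(prior.s0_sq, ref["s0"][0], rtol=1e-4)
    np.testing.assert_allclose(res.t_mod, ref["t"], rtol=1e-6, atol=1e-8)
    np.testing.assert_allclose(res.p, ref["p"], rtol=1e-6, atol=1e-10)
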