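"""Per-protein differential expression with empirical-Bayes moderated t.

Each contrast reduces a protein to an ordinary effect estimate: for unpaired
(group vs group) contrasts the difference of group means, for paired
(post vs pre) contrasts the mean within-subject difference.  Because NPX is
already a log2-scale unit, the effect estimate IS the log2 fold change —
no re-exponentiation anywhere.

The per-protein residual variances s2_g are then shrunk toward a panel-wide
prior by the empirical-Bayes hierarchical model: assuming
s2_g | sigma_g^2 ~ sigma_g^2 * chi2_d / d and 1/sigma_g^2 ~ scaled chi2 with
d0 degrees of freedom and scale s0^2, the posterior variance is

    s_tilde2_g = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g)

and the moderated statistic t_mod = beta_hat / (sqrt(s_tilde2_g) * u_g)
follows a Student t with d0 + d_g degrees of freedom under the null.  The
prior (d0, s0^2) is estimated from the observed log-variances by a
method-of-moments fit: matching the mean and excess variance of
log s2_g against the digamma/trigamma moments implied by the model.

With d0 = 0 the moderated test collapses to the classic t-test; with
d0 = +inf every protein is tested against the common variance s0^2 with a
normal reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .npx_io import NPXMatrix, StudyDesign, Arm

if TYPE_CHECKING:  # pragma: no cover
    from .ortho_screen import ContrastSpec

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "OrdinaryStats",
    "EBayesPrior",
    "ContrastResult",
    "ordinary_stats",
    "fit_ebayes_prior",
    "moderated_test",
    "classify_deps",
    "bh_fdr",
]


@dataclass
class AnalysisConfig:
    """Thresholds and settings shared across the analysis stages."""

    alpha: float = 0.05
    fc_cut: float = 0.5  # |log2FC| threshold for volcano labelling
    membership_rule: str = "p_only"  # or "p_and_fc"
    seed: int = 0
    rf_n_trees: int = 500
    rf_max_features: str | int = "sqrt"
    rf_target: str = "timepoint"  # or "arm"
    sex_test: str = "mannwhitney"  # or "welch"
    correlation_scope: str = "treatment_pooled"  # or "per_timepoint"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.fc_cut < 0:
            raise ValueError("fc_cut must be >= 0")
        if self.membership_rule not in ("p_only", "p_and_fc"):
            raise ValueError("membership_rule must be 'p_only' or 'p_and_fc'")


@dataclass
class OrdinaryStats:
    """Per-protein classic summary statistics for one contrast.

    Only proteins meeting the data preconditions are kept; the rest are
    listed in ``dropped`` with the reason.  ``u`` is the unscaled standard
    error: SE(beta_hat) = sqrt(s2) * u.
    """

    protein_ids: list[str]
    beta_hat: np.ndarray
    s2: np.ndarray
    d: np.ndarray
    u: np.ndarray
    dropped: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.protein_ids)
        for name in ("beta_hat", "s2", "d", "u"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per kept protein")
        if np.any(self.s2 < 0):
            raise ValueError("residual variances must be >= 0")
        if np.any(self.d < 1):
            raise ValueError("kept proteins need residual df >= 1")
        if np.any(self.u <= 0):
            raise ValueError("unscaled standard errors must be > 0")


@dataclass(frozen=True)
class EBayesPrior:
    """Prior degrees of freedom and variance of the shrinkage model."""

    d0: float  # may be math.inf; 0 is the degenerate no-moderation limit
    s0_sq: float

    def __post_init__(self) -> None:
        if not self.d0 >= 0:
            raise ValueError("d0 must be >= 0")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be > 0")


@dataclass
class ContrastResult:
    """Moderated-test outcome for one contrast across the kept proteins."""

    contrast: str
    protein_ids: list[str]
    beta_hat: np.ndarray  # log2FC (NPX is log2-scale)
    t_mod: np.ndarray
    df_total: np.ndarray
    p: np.ndarray
    prior: EBayesPrior
    s2_post: np.ndarray
    dropped: dict[str, str] = field(default_factory=dict)
    direction: np.ndarray | None = None
    q: np.ndarray | None = None

    def p_of(self, protein_id: str) -> float:
        return float(self.p[self.protein_ids.index(protein_id)])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "protein": self.protein_ids,
                "log2fc": self.beta_hat,
                "t_mod": self.t_mod,
                "df": self.df_total,
                "p": self.p,
            }
        )
        df["q"] = bh_fdr(self.p) if self.q is None else self.q
        if self.direction is not None:
            df["direction"] = self.direction
        return df


# ---------------------------------------------------------------------------
# ordinary statistics


def _complete_rows(matrix: NPXMatrix, cols: Sequence[int]) -> np.ndarray:
    vals = matrix.values[:, cols]
    mask = matrix.missing_mask[:, cols]
    return vals, mask


def ordinary_stats(
    matrix: NPXMatrix, design: StudyDesign, contrast: "ContrastSpec"
) -> OrdinaryStats:
    """Classic per-protein effect, variance, df and unscaled SE for a contrast.

    Unpaired: beta_hat = mean(A) - mean(B), pooled variance with
    d = nA + nB - 2 and u = sqrt(1/nA + 1/nB).  Paired: within-subject
    differences D = post - pre, beta_hat = mean(D), s2 = var(D, ddof=1),
    d = n_pairs - 1, u = sqrt(1/n_pairs).  Proteins with too few complete
    observations (or pairs) are dropped with a logged reason.
    """
    ids = matrix.protein_ids
    kept_ids: list[str] = []
    beta, s2, d, u = [], [], [], []
    dropped: dict[str, str] = {}

    if contrast.paired:
        arm = Arm.TREATMENT if contrast.arm == "treatment" else Arm.CONTROL
        pairs = design.paired_sample_ids(arm)
        if not pairs:
            raise ValueError(f"contrast {contrast.name}: no paired subjects in {contrast.arm} arm")
        pre_idx = [matrix.sample_index(b) for b, _ in pairs]
        post_idx = [matrix.sample_index(p) for _, p in pairs]
        diffs = matrix.values[:, post_idx] - matrix.values[:, pre_idx]
        ok = ~(matrix.missing_mask[:, post_idx] | matrix.missing_mask[:, pre_idx])
        for i, g in enumerate(ids):
            dg = diffs[i, ok[i]]
            n = dg.size
            if n < 2:
                dropped[g] = f"only {n} complete pair(s); need >= 2"
                continue
            kept_ids.append(g)
            beta.append(dg.mean())
            s2.append(dg.var(ddof=1))
            d.append(n - 1)
            u.append(1.0 / np.sqrt(n))
    else:
        a_ids = design.group_samples(contrast.group_a)
        b_ids = design.group_samples(contrast.group_b)
        if not a_ids or not b_ids:
            raise ValueError(f"contrast {contrast.name}: empty group")
        ai = [matrix.sample_index(s) for s in a_ids]
        bi = [matrix.sample_index(s) for s in b_ids]
        for i, g in enumerate(ids):
            a = matrix.values[i, ai][~matrix.missing_mask[i, ai]]
            b = matrix.values[i, bi][~matrix.missing_mask[i, bi]]
            na, nb = a.size, b.size
            if na < 2 or nb < 2:
                dropped[g] = f"complete observations A={na}, B={nb}; need >= 2 each"
                continue
            kept_ids.append(g)
            beta.append(a.mean() - b.mean())
            pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
            s2.append(pooled)
            d.append(na + nb - 2)
            u.append(np.sqrt(1.0 / na + 1.0 / nb))

    for g, reason in dropped.items():
        logger.info("contrast %s: dropped %s (%s)", contrast.name, g, reason)
    if not kept_ids:
        raise ValueError(f"contrast {contrast.name}: no protein meets the data preconditions")
    return OrdinaryStats(
        protein_ids=kept_ids,
        beta_hat=np.array(beta),
        s2=np.array(s2),
        d=np.array(d, dtype=float),
        u=np.array(u),
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes prior


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (y > 0); bracketed root find."""
    if y <= 0:
        raise ValueError("trigamma target must be > 0")
    # trigamma is strictly decreasing from +inf to 0 on (0, inf);
    # 1/y and 1/sqrt(y) bracket the root generously
    lo, hi = 1e-8, max(1.0 / y, 1.0 / np.sqrt(y)) + 10.0
    while special.polygamma(1, hi) > y:  # pragma: no cover - generous bracket
        hi *= 2
    return float(optimize.brentq(lambda x: special.polygamma(1, x) - y, lo, hi, xtol=1e-12))


def fit_ebayes_prior(stats_in: OrdinaryStats) -> EBayesPrior:
    """Method-of-moments fit of (d0, s0^2) from observed log variances.

    Under the hierarchical model, e_g = log s2_g - digamma(d_g/2) + log(d_g/2)
    has mean log s0^2 + digamma(d0/2) - log(d0/2) and variance
    trigamma(d_g/2) + trigamma(d0/2).  Matching the empirical mean and the
    excess of the empirical variance over the known trigamma(d_g/2) term
    yields d0 (via a trigamma inversion) and then s0^2.  A non-positive
    excess means the observed variances are no more dispersed than sampling
    noise alone: d0 = +inf and every protein shares s0^2 = exp(mean e).
    """
    s2 = np.asarray(stats_in.s2, dtype=float)
    d = np.asarray(stats_in.d, dtype=float)
    if len(s2) < 2:
        raise ValueError("need at least 2 proteins to fit the shrinkage prior")
    positive = s2 > 0
    if not positive.any():
        raise ValueError("all residual variances are zero; degenerate data")
    if not positive.all():
        logger.info("prior fit: excluding %d zero-variance protein(s)", int((~positive).sum()))
        s2, d = s2[positive], d[positive]
        if len(s2) < 2:
            raise ValueError("fewer than 2 proteins with positive variance")

    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + np.log(d / 2.0)
    e_bar = e.mean()
    G = len(e)
    target = float(np.mean((e - e_bar) ** 2 * G / (G - 1) - special.polygamma(1, d / 2.0)))
    if target <= 0:
        return EBayesPrior(d0=np.inf, s0_sq=float(np.exp(e_bar)))
    half_d0 = _trigamma_inverse(target)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(e_bar + special.digamma(half_d0) - np.log(half_d0)))
    return EBayesPrior(d0=d0, s0_sq=s0_sq)


# ---------------------------------------------------------------------------
# moderated test


def moderated_test(
    stats_in: OrdinaryStats, prior: EBayesPrior, contrast_name: str = ""
) -> ContrastResult:
    """Moderated t and two-sided p for every kept protein.

    s_tilde2 = (d0*s0^2 + d*s2)/(d0 + d); t_mod = beta_hat/(s_tilde * u);
    reference distribution Student t with d0 + d df (normal when d0 = inf).
    The d0 = 0 limit reproduces the classic t-test exactly.
    """
    d0, s0 = prior.d0, prior.s0_sq
    d = stats_in.d
    if np.isinf(d0):
        s2_post = np.full_like(stats_in.s2, s0)
        df_total = np.full_like(d, np.inf)
    else:
        s2_post = (d0 * s0 + d * stats_in.s2) / (d0 + d)
        df_total = d0 + d

    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = stats_in.beta_hat / (np.sqrt(s2_post) * stats_in.u)

    p = np.empty_like(t_mod)
    finite_df = np.isfinite(df_total)
    if finite_df.any():
        p[finite_df] = 2.0 * stats.t.sf(np.abs(t_mod[finite_df]), df_total[finite_df])
    if (~finite_df).any():
        p[~finite_df] = 2.0 * stats.norm.sf(np.abs(t_mod[~finite_df]))
    # a zero posterior variance (d0=0 with s2=0) gives an undefined statistic
    bad = ~np.isfinite(t_mod)
    if bad.any():
        logger.warning(
            "contrast %s: %d protein(s) with undefined moderated t (zero variance)",
            contrast_name,
            int(bad.sum()),
        )
        p[bad] = np.nan

    return ContrastResult(
        contrast=contrast_name,
        protein_ids=list(stats_in.protein_ids),
        beta_hat=stats_in.beta_hat.copy(),
        t_mod=t_mod,
        df_total=df_total,
        p=p,
        prior=prior,
        s2_post=s2_post,
        dropped=dict(stats_in.dropped),
    )


# ---------------------------------------------------------------------------
# DEP classification and FDR


def classify_deps(
    result: ContrastResult, config: AnalysisConfig, rule: str | None = None
) -> tuple[np.ndarray, dict[str, int]]:
    """Label each protein up/down/ns and count the three categories.

    Rule ``p_only``: up iff p < alpha and log2FC > 0 (down symmetric).
    Rule ``p_and_fc`` additionally requires |log2FC| > fc_cut — the volcano
    labelling convention.  Ties at exactly alpha are not significant.
    """
    rule = rule or config.membership_rule
    if rule not in ("p_only", "p_and_fc"):
        raise ValueError("rule must be 'p_only' or 'p_and_fc'")
    p, b = result.p, result.beta_hat
    sig = np.where(np.isnan(p), False, p < config.alpha)
    if rule == "p_and_fc":
        sig = sig & (np.abs(b) > config.fc_cut)
    labels = np.where(sig & (b > 0), "up", np.where(sig & (b < 0), "down", "ns"))
    counts = {
        "up": int((labels == "up").sum()),
        "down": int((labels == "down").sum()),
        "ns": int((labels == "ns").sum()),
    }
    result.direction = labels
    return labels, counts


def bh_fdr(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    NaN p-values (undefined tests) propagate as NaN q-values and do not
    count toward the number of tests.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q
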