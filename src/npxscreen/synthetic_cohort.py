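"""Synthetic two-arm, two-timepoint NPX cohorts with known ground truth.

The generator plants the exact effect structure the orthogonal screen is
designed to disentangle.  Each protein g belongs to one of five classes and
each sample s (subject in arm A_s, timepoint P_t) receives

    NPX[g, s, t] = mu_g + u[g, s] + beta_g * A_s + gamma_g * P_t
                   + delta_g * A_s * P_t + eps

with A_s = 1 for the treatment arm, P_t = 1 for the post timepoint,
subject random effects u ~ N(0, tau^2) (the pairing structure) and residual
noise eps ~ N(0, sigma^2).  The classes are:

* ``null`` — no systematic effect at all;
* ``treatment_specific`` — delta only (the signal the screen should keep);
* ``time_dependent`` — gamma only, drifting in both arms (the screen's
  control-arm contrast should remove these);
* ``baseline_shifted`` — beta only, an arm offset present before treatment;
* ``mixed`` — gamma and delta together, to exercise the screen's exclusion
  of time-confounded proteins.

Clinical scores (NIHSS 0-42, ESRS 0-9) are linear read-outs of chosen
proteins plus noise, rounded to the integer scales, so protein-score rank
correlations are planted by construction.

All randomness flows from one seed through two documented sub-streams
(stream 0: cohort; stream 1: scores), each drawing in a fixed order, so an
identical seed yields a bit-identical cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .npx_io import Arm, NPXMatrix, ProteinAssay, SampleRecord, Sex, Timepoint

__all__ = [
    "CLASS_LABELS",
    "SimulationConfig",
    "SimulationTruth",
    "simulate_cohort",
    "simulate_scores",
    "simulate_full",
]

CLASS_LABELS = ("null", "treatment_specific", "time_dependent", "baseline_shifted", "mixed")


def _default_class_counts() -> dict[str, int]:
    return {
        "null": 67,
        "treatment_specific": 10,
        "time_dependent": 10,
        "baseline_shifted": 0,
        "mixed": 5,
    }


@dataclass
class SimulationConfig:
    """Generative parameters of a synthetic cohort.

    Defaults mirror the emulated trial: 22 subjects per arm, two timepoints,
    a 92-protein cardiovascular panel, and effect sizes (in NPX units, i.e.
    log2 scale) large enough for a well-powered paired contrast at n = 22.
    """

    n_treatment: int = 22
    n_control: int = 22
    n_proteins: int = 92
    class_counts: dict[str, int] = field(default_factory=_default_class_counts)
    delta: float = 1.0  # treatment x post interaction, NPX units
    gamma: float = -0.8  # time drift common to both arms
    beta: float = 0.7  # arm offset present already at baseline
    tau: float = 0.5  # subject random-effect SD
    sigma: float = 0.4  # residual SD
    mu_range: tuple[float, float] = (2.0, 10.0)
    random_signs: bool = True  # flip effect signs +-1 per protein
    score_weights: dict[str, float] | None = None  # NIHSS coupling; None -> auto
    esrs_weights: dict[str, float] | None = None
    nihss_center: float = 8.0
    esrs_center: float = 4.0
    score_noise_sd: float = 2.0
    esrs_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tau", "sigma", "score_noise_sd", "esrs_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_treatment < 2 or self.n_control < 2:
            raise ValueError("need at least 2 subjects per arm")
        unknown = set(self.class_counts) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown protein classes: {sorted(unknown)}")
        if any(c < 0 for c in self.class_counts.values()):
            raise ValueError("class counts must be >= 0")
        total = sum(self.class_counts.values())
        if total != self.n_proteins:
            raise ValueError(
                f"class_counts sum to {total}, expected n_proteins = {self.n_proteins}"
            )


@dataclass
class SimulationTruth:
    """Ground truth of one simulated cohort, for recovery evaluation."""

    protein_ids: list[str]
    class_of: dict[str, str]
    delta_g: dict[str, float]
    gamma_g: dict[str, float]
    beta_g: dict[str, float]
    subject_effects: np.ndarray  # proteins x subjects
    subject_ids: list[str]
    seed: int

    def proteins_of_class(self, label: str) -> set[str]:
        if label not in CLASS_LABELS:
            raise ValueError(f"unknown class {label!r}")
        return {g for g, c in self.class_of.items() if c == label}


def _sex_assignment(n: int, n_male: int) -> list[Sex]:
    return [Sex.MALE] * min(n_male, n) + [Sex.FEMALE] * max(0, n - n_male)


def simulate_cohort(config: SimulationConfig) -> tuple[NPXMatrix, SimulationTruth]:
    """Draw one cohort from the generative model, with full ground truth.

    Stream order within the cohort stream: (1) per-protein baseline means
    mu_g, (2) class assignment by permutation, (3) effect signs, (4) subject
    effects u, (5) residual noise eps, (6) ages.
    """
    cohort_ss, _ = np.random.SeedSequence(config.seed).spawn(2)
    rng = np.random.default_rng(cohort_ss)

    G = config.n_proteins
    subj_ids = [f"T{i + 1:02d}" for i in range(config.n_treatment)] + [
        f"C{i + 1:02d}" for i in range(config.n_control)
    ]
    n_subj = len(subj_ids)
    arm_of_subj = np.array([1] * config.n_treatment + [0] * config.n_control)

    # sex ratio mirrors the emulated trial (treatment 50% male, control ~82%)
    sexes = _sex_assignment(config.n_treatment, round(0.5 * config.n_treatment)) + _sex_assignment(
        config.n_control, round(0.818 * config.n_control)
    )

    protein_ids = [f"PROT{i + 1:03d}" for i in range(G)]

    mu = rng.uniform(*config.mu_range, size=G)

    labels = [lab for lab in CLASS_LABELS for _ in range(config.class_counts.get(lab, 0))]
    order = rng.permutation(G)
    class_arr = np.empty(G, dtype=object)
    for pos, lab in zip(order, labels):
        class_arr[pos] = lab

    signs = rng.choice([-1.0, 1.0], size=(G, 3)) if config.random_signs else np.ones((G, 3))

    has_delta = np.isin(class_arr, ("treatment_specific", "mixed"))
    has_gamma = np.isin(class_arr, ("time_dependent", "mixed"))
    has_beta = class_arr == "baseline_shifted"
    delta_g = np.where(has_delta, config.delta * signs[:, 0], 0.0)
    gamma_g = np.where(has_gamma, config.gamma * signs[:, 1], 0.0)
    beta_g = np.where(has_beta, config.beta * signs[:, 2], 0.0)

    u = rng.normal(0.0, config.tau, size=(G, n_subj))

    # one sample per subject x timepoint; baseline block first, then post
    n_samples = 2 * n_subj
    eps = rng.normal(0.0, config.sigma, size=(G, n_samples))
    ages = np.clip(rng.normal(61.0, 12.0, size=n_subj), 30.0, 95.0)

    values = np.empty((G, n_samples))
    samples: list[SampleRecord] = []
    for t_idx, tp in enumerate((Timepoint.BASELINE, Timepoint.POST)):
        for s_idx, subj in enumerate(subj_ids):
            j = t_idx * n_subj + s_idx
            a = arm_of_subj[s_idx]
            values[:, j] = (
                mu
                + u[:, s_idx]
                + beta_g * a
                + gamma_g * t_idx
                + delta_g * a * t_idx
                + eps[:, j]
            )
            samples.append(
                SampleRecord(
                    sample_id=f"{subj}_{'B' if tp is Timepoint.BASELINE else 'P'}",
                    subject_id=subj,
                    arm=Arm.TREATMENT if a else Arm.CONTROL,
                    timepoint=tp,
                    sex=sexes[s_idx],
                    age=float(round(ages[s_idx], 1)),
                )
            )

    matrix = NPXMatrix(
        values=values,
        missing_mask=np.zeros_like(values, dtype=bool),
        proteins=[ProteinAssay(assay_id=g) for g in protein_ids],
        samples=samples,
    )
    truth = SimulationTruth(
        protein_ids=protein_ids,
        class_of={g: str(c) for g, c in zip(protein_ids, class_arr)},
        delta_g=dict(zip(protein_ids, delta_g)),
        gamma_g=dict(zip(protein_ids, gamma_g)),
        beta_g=dict(zip(protein_ids, beta_g)),
        subject_effects=u,
        subject_ids=subj_ids,
        seed=config.seed,
    )
    return matrix, truth


def _auto_weights(truth: SimulationTruth, k: int = 3, weight: float = -1.0) -> dict[str, float]:
    """Couple scores to the first few treatment-specific proteins.

    Negative weights plant the emulated pattern of higher protein levels
    accompanying milder deficits.
    """
    targets = [g for g in truth.protein_ids if truth.class_of[g] == "treatment_specific"][:k]
    return {g: weight for g in targets}


def simulate_scores(
    matrix: NPXMatrix, truth: SimulationTruth, config: SimulationConfig
) -> NPXMatrix:
    """Attach NIHSS and ESRS scores linearly coupled to chosen proteins.

    score(s, t) = round(clip(a0 + sum_g w_g * NPX[g, s, t] + noise, lo, hi))
    with the intercept a0 chosen so the noise-free score is centred on the
    configured scale centre.  Stream order within the scores stream:
    (1) NIHSS noise, (2) ESRS noise.
    """
    _, score_ss = np.random.SeedSequence(config.seed).spawn(2)
    rng = np.random.default_rng(score_ss)

    w_nihss = config.score_weights if config.score_weights is not None else _auto_weights(truth)
    w_esrs = (
        config.esrs_weights
        if config.esrs_weights is not None
        else _auto_weights(truth, k=2, weight=-0.4)
    )
    for w in (w_nihss, w_esrs):
        missing = set(w) - set(matrix.protein_ids)
        if missing:
            raise ValueError(f"score_weights reference unknown proteins: {sorted(missing)}")

    n = len(matrix.samples)
    nihss_noise = rng.normal(0.0, config.score_noise_sd, size=n)
    esrs_noise = rng.normal(0.0, config.esrs_noise_sd, size=n)

    def linear_term(weights: dict[str, float]) -> tuple[np.ndarray, float]:
        term = np.zeros(n)
        mean_term = 0.0
        for g, w in weights.items():
            i = matrix.protein_index(g)
            term += w * matrix.values[i, :]
            mean_term += w * float(np.mean(matrix.values[i, :]))
        return term, mean_term

    nihss_term, nihss_mean = linear_term(w_nihss)
    esrs_term, esrs_mean = linear_term(w_esrs)
    a0_nihss = config.nihss_center - nihss_mean
    a0_esrs = config.esrs_center - esrs_mean

    nihss = np.round(np.clip(a0_nihss + nihss_term + nihss_noise, 0, 42)).astype(int)
    esrs = np.round(np.clip(a0_esrs + esrs_term + esrs_noise, 0, 9)).astype(int)

    new_samples = [
        dataclasses.replace(s, nihss=int(nihss[j]), esrs=int(esrs[j]))
        for j, s in enumerate(matrix.samples)
    ]
    return NPXMatrix(
        values=matrix.values.copy(),
        missing_mask=matrix.missing_mask.copy(),
        proteins=list(matrix.proteins),
        samples=new_samples,
    )


def simulate_full(config: SimulationConfig) -> tuple[NPXMatrix, SimulationTruth]:
    """Cohort plus clinical scores in one call."""
    matrix, truth = simulate_cohort(config)
    return simulate_scores(matrix, truth, config), truth
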