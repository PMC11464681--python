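"""Synthetic-data generators for every stage of the analysis.

Three generators produce data with the statistical structure the analysis
assumes, so each stage can be validated by parameter recovery:

* :func:`gen_behavioral_trials` — delayed-estimation trials whose circular
  errors follow the target/swap/guess mixture, with between-subject
  parameter variation;
* :func:`gen_fc_matrices` — per-subject Fisher-z connectivity matrices with
  planted community structure among the ROIs;
* :func:`gen_linked_dataset` — subject-level tables coupling standardized
  network-connectivity features to a behavioral response through a linear
  mixed model (task fixed effect, task×FC interactions, subject random
  intercept).

The default behavioral conditions reproduce the group-level mixture
parameters observed in healthy adults on the two tasks (orientation: broad
precision σ_vM = 0.74, frequent guessing; location: tight precision
σ_vM = 0.40, frequent swaps), with between-subject spread set from the
reported standard errors (SD = SEM·√72).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .circular import sigma_to_kappa, kappa_to_sigma, wrap_angle
from .mixture import MixtureParams
from .rois import reference_partition, synthetic_roi_table

__all__ = [
    "BehavioralGenSpec",
    "FCGenSpec",
    "LinkedGenSpec",
    "gen_behavioral_trials",
    "gen_fc_matrices",
    "gen_linked_dataset",
    "orientation_condition",
    "location_condition",
    "default_fc_condition",
    "precision_model_effects",
    "guess_model_effects",
    "feature_names",
]

_N_SUBJECTS_REF = 72  # reference cohort size behind the SEM -> SD conversion


# ---------------------------------------------------------------------------
# behavioral trials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BehavioralGenSpec:
    """Conditions for one task's trial generator.

    ``between_subject_sd`` carries per-parameter between-subject SDs keyed by
    ``p_target, p_nontarget, p_guess, sigma_vm``. Subject-level probability
    triplets are drawn from a Dirichlet centred on the group means (its
    concentration moment-matched to the probability SDs, so the group means
    are preserved exactly on the simplex); subject σ_vM is drawn from a
    truncated normal and converted to κ.
    """

    group_means: MixtureParams
    between_subject_sd: dict = field(default_factory=dict)
    n_subjects: int = 72
    n_trials_per_task: int = 240
    n_nontargets: int = 2
    task: str = "orientation"
    seed: int | None = None

    def __post_init__(self):
        if self.n_nontargets < 0:
            raise ValueError("n_nontargets must be >= 0")
        if self.n_subjects < 1 or self.n_trials_per_task < 1:
            raise ValueError("n_subjects and n_trials_per_task must be >= 1")
        if self.task not in ("orientation", "location"):
            raise ValueError(f"unknown task {self.task!r}")


def _dirichlet_concentration(means: np.ndarray, sds: np.ndarray) -> float:
    """Least-squares moment match of the Dirichlet concentration to target SDs.

    A Dirichlet(c·m) has Var(p_k) = m_k(1-m_k)/(c+1); a single c cannot match
    three arbitrary SDs, so c minimises the squared variance mismatch.
    """
    a = means * (1.0 - means)
    s2 = sds**2
    if np.all(s2 <= 0):
        return np.inf
    x = float((a * s2).sum() / (a * a).sum())
    return max(1.0 / x - 1.0, 1.0)


def _subject_params(spec: BehavioralGenSpec, rng: np.random.Generator):
    m = spec.group_means
    means = np.array([m.p_target, m.p_nontarget, m.p_guess])
    sd = spec.between_subject_sd
    psds = np.array([sd.get("p_target", 0.0), sd.get("p_nontarget", 0.0),
                     sd.get("p_guess", 0.0)])
    sigma0 = kappa_to_sigma(m.kappa)
    ssd = float(sd.get("sigma_vm", 0.0))
    for _ in range(spec.n_subjects):
        if np.all(psds <= 0):
            probs = means
        else:
            c = _dirichlet_concentration(means, psds)
            probs = rng.dirichlet(np.maximum(means, 1e-6) * c)
        if ssd > 0:
            sigma = float(np.clip(rng.normal(sigma0, ssd), 0.05, 2.5))
        else:
            sigma = sigma0
        yield probs, sigma_to_kappa(sigma)


def gen_behavioral_trials(spec: BehavioralGenSpec) -> pd.DataFrame:
    """Generate a trial table for one task.

    Per trial: target and nontarget feature values uniform in (-90°, 90°];
    with probability P_T the response is a von Mises(target, κ) draw, with
    P_NT a von Mises draw around a randomly chosen nontarget, with P_G a
    uniform draw on the circle. Errors never exceed ±90° in degree space, so
    location trials contain no hemifield swaps by construction.

    Returns a table with columns ``subject, task, trial, target_deg,
    nontarget{i}_deg..., response_deg``.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_trials_per_task, spec.n_nontargets
    frames = []
    for s, (probs, kappa) in enumerate(_subject_params(spec, rng), start=1):
        target = rng.uniform(-90.0, 90.0, n)
        nontargets = rng.uniform(-90.0, 90.0, (n, m))
        comp = rng.choice(3, size=n, p=probs)
        # response error generated on the transformed model circle, where the
        # ±90° feature range spans the full 2π (so |error| <= 90° always and
        # location trials can never contain a hemifield swap)
        centre_deg = np.zeros(n)
        if m:
            pick = rng.integers(0, m, n)
            swap = comp == 1
            # swap centre: nontarget offset folded onto the model circle
            delta = wrap_angle(nontargets[swap, pick[swap]] - target[swap],
                               period=180.0)
            centre_deg[swap] = delta
        noise_deg = rng.vonmises(0.0, kappa, n) * 90.0 / np.pi
        err_deg = wrap_angle(centre_deg + noise_deg, period=180.0)
        guess = comp == 2
        err_deg[guess] = rng.uniform(-90.0, 90.0, int(guess.sum()))
        response = target + err_deg
        if spec.task == "orientation":
            response = wrap_angle(response, period=180.0)
        df = pd.DataFrame({
            "subject": f"sub-{s:03d}",
            "task": spec.task,
            "trial": np.arange(1, n + 1),
            "target_deg": target,
            "response_deg": response,
        })
        for i in range(m):
            df[f"nontarget{i + 1}_deg"] = nontargets[:, i]
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    cols = (["subject", "task", "trial", "target_deg"]
            + [f"nontarget{i + 1}_deg" for i in range(m)] + ["response_deg"])
    return out[cols]


def orientation_condition(n_subjects: int = 72, n_trials: int = 240,
                          seed: int | None = None) -> BehavioralGenSpec:
    """Orientation-task condition: broad precision, guessing-dominated tail."""
    return BehavioralGenSpec(
        group_means=MixtureParams(0.61, 0.03, 0.36, sigma_to_kappa(0.74)),
        between_subject_sd={
            "p_target": 0.02 * np.sqrt(_N_SUBJECTS_REF),
            "p_nontarget": 0.01 * np.sqrt(_N_SUBJECTS_REF),
            "p_guess": 0.03 * np.sqrt(_N_SUBJECTS_REF),
            "sigma_vm": 0.03 * np.sqrt(_N_SUBJECTS_REF),
        },
        n_subjects=n_subjects, n_trials_per_task=n_trials,
        n_nontargets=2, task="orientation", seed=seed,
    )


def location_condition(n_subjects: int = 72, n_trials: int = 240,
                       seed: int | None = None) -> BehavioralGenSpec:
    """Location-task condition: tight precision, swap-dominated tail."""
    sd = 0.01 * np.sqrt(_N_SUBJECTS_REF)
    return BehavioralGenSpec(
        group_means=MixtureParams(0.64, 0.34, 0.02, sigma_to_kappa(0.40)),
        between_subject_sd={"p_target": sd, "p_nontarget": sd,
                            "p_guess": sd, "sigma_vm": sd},
        n_subjects=n_subjects, n_trials_per_task=n_trials,
        n_nontargets=2, task="location", seed=seed,
    )


# ---------------------------------------------------------------------------
# connectivity matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FCGenSpec:
    """Conditions for the planted-community connectivity generator."""

    partition: np.ndarray
    within_corr: float = 0.5
    between_corr: float = 0.1
    n_timepoints: int = 500
    n_subjects: int = 40
    roi_labels: tuple | None = None
    roi_coords: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self):
        part = np.asarray(self.partition)
        object.__setattr__(self, "partition", part)
        if not (-1.0 < self.between_corr < self.within_corr < 1.0):
            raise ValueError("require -1 < between_corr < within_corr < 1")
        if self.n_timepoints < 4:
            raise ValueError("n_timepoints must be >= 4")

    @property
    def n_rois(self) -> int:
        return len(self.partition)


def _planted_correlation(spec: FCGenSpec) -> np.ndarray:
    part = spec.partition
    same = part[:, None] == part[None, :]
    C = np.where(same, spec.within_corr, spec.between_corr)
    np.fill_diagonal(C, 1.0)
    eig = np.linalg.eigvalsh(C)
    if eig[0] < -1e-10:
        raise ValueError(
            f"requested block-correlation model is not positive semidefinite "
            f"(smallest eigenvalue {eig[0]:.3e})"
        )
    return C


def gen_fc_matrices(spec: FCGenSpec) -> list[pd.DataFrame]:
    """One Fisher-z FC matrix per subject (DataFrame, NaN diagonal).

    Subject time series are drawn from a block-structured multivariate normal
    respecting the planted partition; Pearson correlations over
    ``n_timepoints`` samples are Fisher-transformed.
    """
    rng = np.random.default_rng(spec.seed)
    C = _planted_correlation(spec)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(spec.n_rois))
    labels = (list(spec.roi_labels) if spec.roi_labels is not None
              else [f"roi{i + 1:02d}" for i in range(spec.n_rois)])
    out = []
    for _ in range(spec.n_subjects):
        ts = rng.standard_normal((spec.n_timepoints, spec.n_rois)) @ L.T
        r = np.corrcoef(ts.T)
        z = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
        np.fill_diagonal(z, np.nan)
        out.append(pd.DataFrame(z, index=labels, columns=labels))
    return out


def default_fc_condition(n_subjects: int = 40, n_timepoints: int = 500,
                         within_corr: float = 0.5, between_corr: float = 0.1,
                         seed: int | None = None) -> FCGenSpec:
    """Planted partition = the six reference networks over the 37 ROIs."""
    rois = synthetic_roi_table()
    return FCGenSpec(
        partition=reference_partition(),
        within_corr=within_corr, between_corr=between_corr,
        n_timepoints=n_timepoints, n_subjects=n_subjects,
        roi_labels=tuple(rois["label"]),
        roi_coords=np.asarray(rois[["x_mm", "y_mm", "z_mm"]], dtype=float),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# linked brain-behavior datasets
# ---------------------------------------------------------------------------

def feature_names(n_networks: int = 6) -> list[str]:
    """Within-network then between-network FC feature names."""
    names = [f"fc_w_N{i}" for i in range(1, n_networks + 1)]
    names += [f"fc_b_N{i}_N{j}" for i in range(1, n_networks + 1)
              for j in range(i + 1, n_networks + 1)]
    return names


def _valid_terms(n_networks: int) -> list[str]:
    feats = feature_names(n_networks)
    return ["intercept", "task"] + feats + [f"task:{f}" for f in feats]


@dataclass(frozen=True)
class LinkedGenSpec:
    """Conditions for the linked brain-behavior generator.

    ``fixed_effects`` maps model terms (``intercept``, ``task``, FC feature
    names and ``task:`` interactions) to coefficients in response units per
    SD of the predictor; task is coded 0 = orientation (reference),
    1 = location.
    """

    fixed_effects: dict
    random_intercept_sd: float = 0.10
    residual_sd: float = 0.18
    n_subjects: int = 72
    n_networks: int = 6
    response: str = "sigma_vm"
    seed: int | None = None

    def __post_init__(self):
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        if self.random_intercept_sd < 0:
            raise ValueError("random_intercept_sd must be >= 0")
        if self.n_subjects < 2:
            raise ValueError(
                "need at least 2 subjects (a random intercept is "
                "unidentifiable from a single subject)"
            )
        valid = set(_valid_terms(self.n_networks))
        bad = sorted(set(self.fixed_effects) - valid)
        if bad:
            raise ValueError(
                f"unknown fixed-effect terms {bad}; valid terms are "
                f"{sorted(valid)}"
            )


def gen_linked_dataset(spec: LinkedGenSpec) -> pd.DataFrame:
    """Subject × task rows with standardized FC features and a mixed-model response.

    Features are drawn standard normal per subject (constant across that
    subject's two task rows); the response is the fixed-effect linear
    predictor plus a subject random intercept and residual noise.
    """
    rng = np.random.default_rng(spec.seed)
    feats = feature_names(spec.n_networks)
    X = rng.standard_normal((spec.n_subjects, len(feats)))
    b = rng.normal(0.0, spec.random_intercept_sd, spec.n_subjects)
    rows = []
    for s in range(spec.n_subjects):
        for task_code, task in ((0, "orientation"), (1, "location")):
            mu = 0.0
            for term, beta in spec.fixed_effects.items():
                if term == "intercept":
                    mu += beta
                elif term == "task":
                    mu += beta * task_code
                elif term.startswith("task:"):
                    mu += beta * task_code * X[s, feats.index(term[5:])]
                else:
                    mu += beta * X[s, feats.index(term)]
            y = mu + b[s] + rng.normal(0.0, spec.residual_sd)
            row = dict(subject=f"sub-{s + 1:03d}", task=task)
            row[spec.response] = y
            row.update({f: X[s, j] for j, f in enumerate(feats)})
            rows.append(row)
    return pd.DataFrame(rows)


def precision_model_effects() -> dict:
    """Generating fixed effects for the memory-precision (σ_vM) model.

    Orientation-task simple slopes of the three connectivity terms are the
    main-effect coefficients; location-task slopes (main + interaction) are
    near zero, mirroring the task-specific association pattern.
    """
    return {
        "intercept": 0.74,
        "task": -0.34,
        "fc_w_N6": -0.073, "task:fc_w_N6": 0.064,
        "fc_b_N2_N4": -0.076, "task:fc_b_N2_N4": 0.062,
        "fc_b_N3_N5": -0.077, "task:fc_b_N3_N5": 0.076,
    }


def guess_model_effects() -> dict:
    """Generating fixed effects for the random-guess (P_G) model."""
    return {
        "intercept": 0.36,
        "task": -0.34,
        "fc_b_N3_N5": 0.058, "task:fc_b_N3_N5": -0.052,
    }


def linked_condition(response: str = "sigma_vm", n_subjects: int = 72,
                     seed: int | None = None) -> LinkedGenSpec:
    effects = precision_model_effects() if response == "sigma_vm" else guess_model_effects()
    return LinkedGenSpec(fixed_effects=effects, n_subjects=n_subjects,
                         response=response, seed=seed)


def with_seed(spec, seed: int):
    """Copy of a generator spec with its seed replaced."""
    return replace(spec, seed=seed)
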