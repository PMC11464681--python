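import numpy as np
import pandas as pd
import pytest

from vwm_errnet.circular import sigma_to_kappa
from vwm_errnet.mixture import MixtureParams
from vwm_errnet.synthesize import (
    BehavioralGenSpec,
    FCGenSpec,
    gen_behavioral_trials,
    gen_fc_matrices,
)
from vwm_errnet import io as vio


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


def make_mixture_data(rng, p_target, p_nontarget, p_guess, kappa, n, m=2):
    """Draw (errors, deltas) in radians directly from the response model."""
    deltas = rng.uniform(-np.pi, np.pi, (n, m)) if m else np.zeros((n, 0))
    comp = rng.choice(3, size=n, p=[p_target, p_nontarget, p_guess])
    centre = np.zeros(n)
    if m:
        pick = rng.integers(0, m, n)
        swap = comp == 1
        centre[swap] = deltas[swap, pick[swap]]
    err = centre + rng.vonmises(0.0, kappa, n)
    guess = comp == 2
    err[guess] = rng.uniform(-np.pi, np.pi, int(guess.sum()))
    err = np.angle(np.exp(1j * err))
    return err, deltas


@pytest.fixture
def mixture_dataset(rng):
    """A well-identified mixture draw: (errors, deltas, generating params)."""
    params = MixtureParams(0.6, 0.1, 0.3, 8.0)
    err, deltas = make_mixture_data(rng, 0.6, 0.1, 0.3, 8.0, n=2000)
    return err, deltas, params


@pytest.fixture
def prepared_two_task_trials():
    """A small two-task cohort, prepared for fitting."""
    frames = []
    for task, sigma, seed in (("orientation", 0.74, 11), ("location", 0.40, 12)):
        spec = BehavioralGenSpec(
            group_means=MixtureParams(0.6, 0.1, 0.3, sigma_to_kappa(sigma)),
            n_subjects=6, n_trials_per_task=150, n_nontargets=2,
            task=task, seed=seed)
        frames.append(gen_behavioral_trials(spec))
    return vio.prepare_trials(pd.concat(frames, ignore_index=True))


@pytest.fixture
def planted_fc_small():
    """3 planted communities over 12 ROIs, strong contrast, 10 subjects."""
    part = np.repeat([1, 2, 3], 4)
    spec = FCGenSpec(partition=part, within_corr=0.6, between_corr=0.05,
                     n_timepoints=400, n_subjects=10, seed=7)
    return gen_fc_matrices(spec), part
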