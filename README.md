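# vwm-errnet

Decomposing visual-working-memory (VWM) errors into distinct sources —
imprecise memory, swaps with nontarget items, and random guesses — and
relating each source to intrinsic functional brain networks.

Analog-report ("delayed estimation") tasks ask a participant to reproduce a
memorized feature (an orientation, a location) on a continuous circular
scale. The distribution of response errors is modelled as a three-component
mixture (Bays-style):

    p(e) = P_T·φ_κ(e) + (P_NT/m)·Σᵢ φ_κ(e − δᵢ) + P_G/2π

with φ_κ a von Mises density, δᵢ the nontarget offsets, P_T + P_NT + P_G = 1.
The concentration κ converts to a circular SD, σ_vM = √(−2 ln(I₁(κ)/I₀(κ))),
an inverse measure of memory precision. Parameters are estimated per
participant and task by expectation–maximization.

On the imaging side, ROI-to-ROI functional connectivity (Fisher-z Pearson
correlation of time series from 37 regions engaged by VWM tasks) is
partitioned into intrinsic networks by complete-linkage hierarchical
clustering under a hybrid distance,

    d(p,q) = r·Σⱼ(F̄_pj − F̄_qj)² + (1−r)·Σₖ(C_pk − C_qk)²,   r = 0.95,

mixing functional-profile dissimilarity with anatomical proximity. Average
within- and between-network connectivity (FC_W, FC_B) then enters linear
mixed-effects models of each behavioral parameter (task fixed effect,
task×FC interactions, subject random intercept) with step-up model
selection, Satterthwaite inference, parametric bootstrap CIs, simple-slope
decomposition of interactions, and influence diagnostics.

Because raw behavioral and imaging data of this kind are rarely
redistributable, the package ships first-class synthetic-data generators for
every stage — mixture-distributed circular responses with between-subject
variation, FC matrices with planted community structure, and linked
brain–behavior datasets — so the entire chain is verifiable by parameter
recovery. The intended users are cognitive/behavioral modellers and
neuroimaging researchers who want a tested, seedable reference
implementation of this analysis chain.

## Worked example

```python
import numpy as np
from vwm_errnet import (gen_behavioral_trials, fit_subjects, ks_uniform_screen,
                        gen_fc_matrices, group_mean_fc, HybridNetworkClustering,
                        gen_linked_dataset, fit_mixed_model, simple_slopes)
from vwm_errnet.synthesize import (orientation_condition, default_fc_condition,
                                   linked_condition, with_seed)
from vwm_errnet.io import prepare_trials
from vwm_errnet.rois import synthetic_roi_table

# 1) behavioral: generate an orientation-task cohort, screen, fit by EM
trials = gen_behavioral_trials(with_seed(orientation_condition(n_subjects=24), 0))
prepared = prepare_trials(trials)
keep = ks_uniform_screen(prepared)
fits = fit_subjects(prepared, random_state=0)
print("retained:", int(keep['keep'].sum()), "/ 24 subjects")
print(fits[["p_target", "p_nontarget", "p_guess", "sigma_vm"]].mean().round(3))

# 2) networks: planted-community FC, hybrid-distance complete linkage
mats = gen_fc_matrices(default_fc_condition(n_subjects=20, seed=1))
rois = synthetic_roi_table()
net = HybridNetworkClustering(r=0.95).fit(
    group_mean_fc(mats), centroids=rois[["x_mm", "y_mm", "z_mm"]].to_numpy())
print("networks:", net.n_clusters_, "sizes:", np.bincount(net.labels_)[1:])

# 3) association: linked dataset, interaction model, simple slopes
data = gen_linked_dataset(linked_condition("sigma_vm", seed=2))
fit = fit_mixed_model(data, "sigma_vm",
                      ["intercept", "task", "fc_w_N6", "task:fc_w_N6"])
print(simple_slopes(fit, "fc_w_N6").slopes.round(3))
```

Output:

```
retained: 23 / 24 subjects
p_target       0.693
p_nontarget    0.029
p_guess        0.277
sigma_vm       0.844
dtype: float64
networks: 6 sizes: [ 3 11  4  4 10  5]
          task  slope     se       df      p
0  orientation -0.084  0.025  129.132  0.001
1     location  0.010  0.025  129.132  0.702
```

Reading it: the screen keeps 23/24 simulated subjects (one looked like a
pure guesser); the EM group means land near the generating orientation-task
condition (target reports ≈ 0.69 vs 0.61 generated, guessing ≈ 0.28 vs 0.36,
precision σ_vM ≈ 0.84 vs 0.74 — a 24-subject cohort estimates group means
only to ±1 SEM, and ML mixture estimates at this operating point carry a
known small bias; see `docs/methods.md`). Clustering recovers the planted
six networks with their sizes. The mixed model recovers the planted
task-specific coupling: within-N6 connectivity predicts precision in the
orientation task (slope −0.084, p ≈ 0.001) but not the location task
(slope ≈ 0.01, n.s.).

A full pipeline run (simulate → screen/fit → cluster → associate, with a
hashed manifest for reproducibility) is one command:

```bash
vwm-errnet full --config configs/demo.yaml --out runs/demo
```

Individual stages are exposed as `vwm-errnet simulate|fit-behavior|cluster|associate`.

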