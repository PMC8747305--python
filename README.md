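# trunkmoment

Estimation of the moment the human trunk generates about the lumbosacral
(L5/S1) joint, for proportional control of back-support exoskeletons — and a
study of how far the per-user calibration procedure can be trimmed before
predictive accuracy degrades.

The package is aimed at biomechanists and exoskeleton-control engineers. It
implements the three-model pipeline used in this line of research, end to
end, on synthetic lifting trials with known ground truth:

1. **Inverse dynamics (ID)** — the reference. A sagittal bottom-up
   Newton–Euler recursion from the ground reaction force through
   feet–shanks–thighs–pelvis yields the net L5/S1 moment `M_Net`; in
   exoskeleton trials the human share is `M_Human = M_Net − M_Exo`.
2. **EMG-driven trunk muscle model (EMGMod)** — twelve muscle elements
   (bilateral rectus abdominis, internal/external oblique, iliocostalis,
   longissimus pars lumborum/pars thoracis) produce moment through fixed
   moment arms. Per element *m*,

       M_active  = Σ_m σ_m · G · A_m · PCSA_m · f_l(λ_m; w) · f_v(λ̇_m; S_e, S_c) · r_m
       M_passive = Σ_extensors S_p (e^{c(λ_m − λ₀)} − 1)_+ · PCSA_m · r_m

   with activation `A_m` the MVC-normalized EMG envelope and normalized
   length `λ_m` driven by lumbar flexion. Seven subject-specific parameters
   `P = (G, λ₀, S_p, S_e, S_c, θ_opt, w)` are calibrated per user by
   minimizing the time-integrated squared gap to the ID reference,

       J(P) = Σ_trials ∫ (M_Human^ID − M_active(P) − M_passive(P))² dt,

   by bound-constrained trust-region least squares with multi-starts.
3. **Reduced-sensor regression model (RegMod)** — a "coarse" Gaussian-kernel
   ε-SVR predicting EMGMod's active moment from signals available during
   exoskeleton operation: 4 back-muscle EMG channels plus trunk
   inclination, angular velocity, angular acceleration, trunk flexion and
   hip angle.

The **calibration-set study** evaluates which lifting trials a user must
perform for calibration: the Full set (14 lift conditions: 2 masses ×
{stoop, squat} × {slow, normal} plus 2 masses × free × {very slow, normal,
fast}), every n-trial subset (n = 1..3), the Selected family (3-trial sets
covering both extremes of mass, technique and speed), the Worst-selected
member, and a Quasi-static set (the two very-slow free lifts). Prediction
error is the per-trial RMSE of the reconstructed human moment against ID on
an unseen test battery (exoskeleton lifts under four control strategies,
box stacking lift/carry, shelf lifts, isometric push/pull), pooled per task
group and compared with a two-way within-subject ANOVA plus Bonferroni
post-hocs.

Because no public dataset accompanies this problem, the package ships a
first-class synthetic-trial generator: a planar five-segment body driven by
minimum-jerk joint trajectories, ground reactions from exact whole-body
Newton–Euler balance, and EMG obtained by inverting a ground-truth muscle
model plus noise — so every stage can be validated against a known answer
(see `docs/methods.md`).

## Worked example

Calibrate the muscle model for one synthetic subject and check what it
predicts on unseen test tasks:

```python
import numpy as np
from trunkmoment import EMGDrivenModel, generate_subject
from trunkmoment.study import prepare_subject

data = generate_subject(1, seed=7)          # synthetic subject, default noise
cache = prepare_subject(data)               # inverse dynamics on every trial

trials = data.calibration_trials            # 14 conditions x 2 repetitions
refs = [cache.references[t.trial_id] for t in trials]
result = EMGDrivenModel(trials, refs).fit(n_starts=5, seed=0)
print(result.summary())
```

```
EMG-driven trunk muscle model calibration
--------------------------------------------
parameter           estimate            bounds
gain                 34.5770         [10, 120]
passive_offset        1.0022        [0.9, 1.3]
passive_scale        15.5490           [0, 60]
ecc_scale             0.3546          [0, 0.8]
con_scale             0.6752            [0, 1]
optimum_angle         0.4565          [0, 1.2]
fl_width              0.4588          [0.2, 1]
--------------------------------------------
objective J = 583.401 (N·m)^2·s over 28 trial(s), 11608 samples
starts: 6, converged: 6
```

The recovered EMG-to-stress gain (34.58 N/cm²) is within half a percent of
this subject's ground truth (34.73 N/cm²), and the calibrated model
reconstructs the human moment on the unseen test battery with a mean RMSE
of 1.31 N·m — about 1% of the ~190 N·m peak moment of a 15 kg stoop lift,
the residual coming from the injected EMG noise:

```python
true = data.truth.params_true
print(f"true gain {true.gain:.2f} N/cm^2, recovered {result.params.gain:.2f}")
errs = []
for t in data.test_trials:
    pred = result.predict(t).values_nm
    ref = cache.references[t.trial_id].values_nm
    errs.append(np.sqrt(np.mean((pred - ref) ** 2)))
print(f"test-trial human-moment RMSE: {np.mean(errs):.2f} N·m")
# true gain 34.73 N/cm^2, recovered 34.58
# test-trial human-moment RMSE: 1.31 N·m
```

The full study (generation → ID → EMGMod → RegMod → RMSE tables → ANOVA →
figures) runs from the shell:

```bash
trunkmoment study --subjects 10 --seed 1 --out-dir study_out
trunkmoment simulate --subjects 2 --seed 0 --out-dir data   # trial files
```

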