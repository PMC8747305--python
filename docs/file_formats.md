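# File formats

## Trial files

One trial per file, UTF-8 text. A `#`-prefixed `key: value` metadata header
is followed by a comma-separated header row naming every channel and one
row per 50 Hz sample. Values are written with full round-trip precision
(`repr`), so read-after-write preserves numerics to better than 1e-10.

Header keys: `trial_id`, `subject_id`, `mass_kg`, `technique`
(stoop/squat/free/n-a), `velocity` (very_slow/slow/normal/fast/n-a),
`task_group` (calibration_lift/exo_lift/stack_lift/stack_carry/shelf_lift/
push_pull), `exo_strategy` (none/inclination/dynamic/velocity/transparent),
`fs_hz`, plus optional `meta_*` entries (e.g. the infeasible-activation
flag).

Channel columns, in order:

| group | columns | units |
|---|---|---|
| time | `time_s` | s |
| measured angles | `trunk_inclination`, `trunk_inclination_vel`, `trunk_inclination_acc`, `trunk_flexion`, `hip_angle`, `lumbar_flexion`, `lumbar_flexion_vel` | rad, rad/s, rad/s² |
| segment orientations | `phi_shank`, `phi_thigh`, `phi_pelvis`, `phi_trunk`, `phi_arm` | rad from vertical, forward positive |
| joint positions | `knee_x/y`, `hip_x/y`, `l5s1_x/y`, `shoulder_x/y`, `hand_x/y` | m (x forward, y up; ankle at x = 0) |
| ground reaction | `grf_fx`, `grf_fy`, `cop_x` | N, N, m |
| external load | `load_mass_kg` (effective supported box mass), `hand_force_x` | kg, N |
| exoskeleton | `exo_torque_nm` | N·m, extension positive |
| EMG | `emg_RA_L`, `emg_RA_R`, `emg_IO_L`, `emg_IO_R`, `emg_EO_L`, `emg_EO_R`, `emg_IL_L`, `emg_IL_R`, `emg_LTpl_L`, `emg_LTpl_R`, `emg_LTpt_L`, `emg_LTpt_R` | MVC-normalized envelope, ≥ 0 |

Invariants enforced on read: uniform 50 Hz time base, non-negative EMG,
identically zero exoskeleton torque when `exo_strategy` is `none`.

## Subject files

Flat `key: value` text: `subject_id`, `body_mass_kg`, `stature_m`,
`ankle_height_m`, one `segment_<name>` line per lumped segment with
`mass_kg,length_m,com_fraction,inertia_kgm2`, and `mvc_peaks` (12
comma-separated per-channel MVC envelope peaks, arbitrary amplifier
units). Segment masses must sum to the body mass.

## Study outputs

`trunkmoment study` writes CSV tables (`per_trial_rmse.csv`,
`task_group_rmse.csv`, `selected_family.csv`, `anova_<model>.csv`,
optionally `subset_sweep.csv`), PNG figures, a markdown report and a JSON
run log with the configuration. `scripts/acceptance.py` writes one JSON
object mapping quantity names to `{"value": ..., "n": ...}`.

## Calibrated parameter files

`trunkmoment calibrate` writes `name: value` lines for the seven muscle
model parameters plus the final objective; `trunkmoment train` consumes
them and writes a pickled regressor bundle.
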