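"""Simulate one walking bout and extract the seven gait variables.

The generator knows the bout's true kinematics, so the printout pairs each
estimated variable with its ground truth: close agreement means the full
chain (confidence gating, imputation, filtering, foot-strike detection,
normalization) is working.
"""

from gaitvid import GaitSimParams, extract_features, simulate_bout

params = GaitSimParams(
    seed=1,
    cadence_spm=105.0,  # programmed steps/min
    step_width_ratio=0.5,  # ankle separation in hip-span units
    stance_time_split=0.55,  # mild left/right timing asymmetry
    pixel_noise_sd=1.5,
    dropout_rate=0.10,  # 10% of keypoints get low confidence
    perspective_scale_end=1.6,  # walker grows 1.6x while approaching
)
bout, truth = simulate_bout(params)
vec = extract_features(bout)

print(f"bout: {bout.duration_s:.0f} s at {bout.fps:.0f} fps, {vec.n_steps} detected steps")
print(f"{'variable':<16}{'estimated':>10}{'truth':>10}")
for name, true_key in [
    ("cadence", "cadence"),
    ("si_step_time", "si_step_time"),
    ("cv_step_time", "cv_step_time"),
    ("avg_step_width", "avg_step_width"),
]:
    print(f"{name:<16}{getattr(vec, name):>10.3f}{truth.features[true_key]:>10.3f}")
print(f"{'avg_emos':<16}{vec.avg_emos:>10.3f}{'—':>10}")
print(f"{'min_emos':<16}{vec.min_emos:>10.3f}{'—':>10}")
print()
print("cadence/SI/CV/width should match the generator truth closely; the eMOS")
print("pair has no closed-form truth but must satisfy min_emos <= avg_emos.")
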