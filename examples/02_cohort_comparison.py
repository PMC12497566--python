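"""Compare normalized moment arms across a four-model cohort.

The cohort spans the morphotype contrast between trunk-to-trunk leapers
(attachments placed farther from the joint center, favouring torque) and
horizontal leapers (attachments closer in, favouring rotational velocity),
at different body masses.  Dividing by mass**0.33 makes the moment arms
comparable across sizes.
"""

import tempfile

from hipmma import generate_cohort, read_model, summarize_relative_lengths, sweep

with tempfile.TemporaryDirectory() as tmp:
    models = [read_model(path) for path, _ in generate_cohort(4, tmp)]

print("normalized gluteus medius MMA (mm / g^0.33) at three poses:\n")
print(f"{'model':28s} {'mass (g)':>9s} {'20 deg':>8s} {'90 deg':>8s} {'160 deg':>8s}")
for model in models:
    curve = sweep(model).muscle_curve("gluteus_medius", "mma_normalized")
    print(f"{model.name:28s} {model.body_mass:9.0f} "
          f"{curve[20.0]:8.3f} {curve[90.0]:8.3f} {curve[160.0]:8.3f}")

print("\nsize-corrected skeletal and resting-muscle lengths (mm / g^0.33):\n")
for model in models:
    df = summarize_relative_lengths(model).set_index("element")
    print(f"{model.name:28s} femur {df.loc['femur','relative_length']:6.2f}  "
          f"pelvis {df.loc['pelvis','relative_length']:6.2f}  "
          f"biceps femoris {df.loc['biceps_femoris','relative_length']:6.2f}")

print(
    "\nThe trunk-leaper morphotype shows the largest normalized gluteal\n"
    "moment arm at every pose: longer leverage for hip-extension torque,\n"
    "at the cost of joint rotation speed."
)
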