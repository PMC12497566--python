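"""The three robustness analyses on one synthetic model.

1. placement repeatability — re-placing every attachment centroid with
   0.5 mm Gaussian scatter (snapped back to the bone surface), five times;
2. body-mass perturbation — +/-10% and +/-20% of the measured mass;
3. origin shift — sliding the biceps femoris origin along the pelvis long
   axis by +/-10% and +/-20% of pelvic length.
"""

import tempfile
import warnings

from hipmma import (
    SyntheticModelSpec,
    generate_model,
    mass_perturbation,
    origin_shift,
    placement_repeatability,
    read_model,
)

with tempfile.TemporaryDirectory() as tmp:
    descriptor, _ = generate_model(SyntheticModelSpec(), tmp)
    model = read_model(descriptor)

rep = placement_repeatability(model, sigma_mm=0.5, replicates=5, seed=1)
sd = rep.quantity("mma_projected_mm").sd
print(f"placement jitter (sigma=0.5 mm, 5 replicates):")
print(f"  projected-MMA sd across replicates: "
      f"mean {sd.mean():.3f} mm, max {sd.max():.3f} mm")

rep = mass_perturbation(model)
norm = rep.quantity("mma_normalized")
print(f"\nbody-mass perturbation (+/-10%, +/-20%):")
print(f"  normalized MMA spread (max-min)/mean: "
      f"{((norm['max']-norm['min'])/norm['mean']).max():.3f}")
print("  raw moment arms are untouched; normalized values scale exactly "
      "as (1+f)^-0.33")

with warnings.catch_warnings():
    warnings.simplefilter("ignore", UserWarning)
    rep = origin_shift(model, muscle="biceps_femoris")
ref = rep.replicates.query("angle_deg == 90.0").sort_values("level")
print(f"\nbiceps femoris origin shift (fraction of pelvic length):")
for _, row in ref.iterrows():
    print(f"  shift {row.level:+5.2f}: projected MMA at 90 deg = "
          f"{row.mma_projected_mm:6.2f} mm")

print(
    "\nCaudal shifts (negative fractions) move the origin away from the\n"
    "hip and lengthen the moment arm; attachment placement is the single\n"
    "most influential modelling choice, which is why it is audited."
)
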