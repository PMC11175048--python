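"""Calibrate a clay model with PLSR and repeated double cross-validation.

The inner 10-fold loop picks the latent-variable count with minimum
standard error of prediction; the outer 4-fold loop estimates prediction
error; the scheme repeats with fresh random splits.
"""

import numpy as np

from moistspec import (
    SyntheticConfig,
    evaluate,
    fit_pls,
    generate_dataset,
    make_split,
    predict,
    preprocess_pipeline,
    rdcv,
)

config = SyntheticConfig(n_samples=40, seed=9)
raw, chemistry = generate_dataset(config, "full_range")
sieved, _ = preprocess_pipeline(raw.select(treatment="lab_sieved"))
split = make_split(sieved, 0.70)

chem = chemistry.set_index("sample_id")
cal = sieved.reorder_by_ids(split.calibration_ids)
val = sieved.reorder_by_ids(split.validation_ids)
y_cal = chem.loc[split.calibration_ids, "clay"].to_numpy()
y_val = chem.loc[split.validation_ids, "clay"].to_numpy()

result = rdcv(cal.values, y_cal, lv_max=10, repetitions=10, seed=2)
counts = np.bincount(result.lv_selections, minlength=11)
print("outer-fold LV selections (LV: times chosen):",
      {lv: int(c) for lv, c in enumerate(counts) if c})
print(f"final LV count (mode): {result.final_lv}")
print(f"cross-validated RMSE (mean over repetitions): {result.outer_rmse_mean:.2f} % clay")
print(f"cross-validated R^2:  {result.outer_r2_mean:.3f}")

model = fit_pls(cal.values, y_cal, result.final_lv)
metrics = evaluate(y_val, predict(model, val.values))
print(f"\nvalidation-set performance (n={metrics.n}):")
print(f"  RMSEP {metrics.rmsep:.2f} %  R2 {metrics.r2:.2f}  "
      f"RPIQ {metrics.rpiq:.2f}  bias {metrics.bias:+.2f}  CCC {metrics.ccc:.2f}")
print("\nRPIQ is the validation interquartile range over RMSEP - "
      "values near 2 or above indicate a usable soil calibration.")
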