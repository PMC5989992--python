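"""Binary classification: ICV-only benchmark vs ICV + fingerprint components.

Truncating a coefficient out of a logistic model distorts the predicted
probabilities, so for binary attributes the confound is handled by
comparison instead: each fold fits an ICV-only logistic LASSO and a full
model adding the component scores, and the fingerprint's contribution is
the accuracy gap between them. A label carried by the latent axes should
open a gap; a label independent of everything should leave both models at
exactly the majority-class base rate (intercept-only null fits).
"""

import numpy as np

from lcpmap import (
    AttributeSpec,
    CohortConfig,
    CVConfig,
    generate_cohort,
    run_cv_binary,
)

cfg = CohortConfig(n_subjects=200, n_features=1500, n_latent=3,
                   latent_scales=0.4, seed=20)
cohort = generate_cohort(cfg, [
    AttributeSpec("signal_label", family="binary", class_fractions=(0.6, 0.4),
                  effect_axes=(0,), effect_sizes=(4.0,)),
    AttributeSpec("null_label", family="binary", class_fractions=(0.8, 0.2)),
])
X = cohort.fingerprints.values

for name in ("signal_label", "null_label"):
    y = cohort.attributes.column(name).to_numpy().astype(int)
    base = max(np.mean(y == 0), np.mean(y == 1))
    res = run_cv_binary(X, cohort.icv, y, CVConfig(seed=21),
                        compute_training=False)
    print(f"{name}: base rate {base:.4f}, "
          f"CV accuracy ICV-only {res.metric_icv_only:.4f}, "
          f"ICV + components {res.metric:.4f}")

print("-> the planted label is classified well above its base rate only "
      "when fingerprint components enter the model; the null label sits at "
      "the base rate exactly, because every penalized fit is intercept-only")
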