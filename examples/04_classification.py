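"""Subject-wise Random-Forest classification with merged-prediction AUROC.

Fifty repeated splits each hold out 3 vestibular + 3 control participants
(all their trials); the held-out probabilities are pooled across repeats and
scored once. Compares the eyes-closed task against self-selected-speed
walking for a left-arm IMU.
"""

import numpy as np

import vestigait as vg

config = vg.SimConfig(tasks=("GEC", "SSGS"), placements=("l_arm",), seed=1)
trials, _ = vg.simulate_cohort(config)
spec = vg.FeatureSpec(("l_arm",))

for task in ("GEC", "SSGS"):
    dataset = vg.build_dataset(trials, task, spec)
    labels = np.array([dataset.participant_labels()[p]
                       for p in dataset.participants])
    plan = vg.make_split_plan(dataset.participants, labels,
                              n_repeats=50, seed=1001)
    result = vg.evaluate(plan, dataset,
                         vg.ModelConfig.singleton(n_estimators=200, seed=2001))
    lo, hi = result.auroc_ci
    print(f"{task}: merged AUROC {result.auroc:.3f} [{lo:.3f}, {hi:.3f}], "
          f"accuracy {100 * result.accuracy:.0f}%, "
          f"sensitivity {100 * result.sensitivity:.0f}%, "
          f"specificity {100 * result.specificity:.0f}%")

print("\nThe eyes-closed task separates the classes best: the arm-swing "
      "contrast is applied at full strength only when vision is removed.")
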