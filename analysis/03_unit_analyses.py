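"""Unit-level dissection of the trained agent.

Loads the desk-scale checkpoint (run 02_train_agent.py first), records
cell-state activations on the four fixed two-landmark environments,
then runs the full unit-analysis battery: response-pattern typing
(spatial / landmark / conjunctive), functional-module identification
(vector / transition / unspecialized), module lesions, location and
adjacency decoding, and representational-geometry centroids.

Writes:
    results/unit_labels.csv        per-unit type and ANOVA p-values
    results/module_assignment.csv  per-unit module membership and R^2
    results/lesion_effects.csv     excess steps and strategy shift per lesion
    results/decoding_errors.csv    ridge / logistic decoding by module
    results/geometry_centroids.csv per-location PC centroids (vector units)
"""

from pathlib import Path

import numpy as np
import pandas as pd

from metanav import agent as ag
from metanav import units

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"
CKPT = ROOT / "scratch" / "desk_checkpoint.npz"
if not CKPT.exists():
    raise SystemExit("missing scratch/desk_checkpoint.npz -- run 02_train_agent.py first")
params = ag.load_params(CKPT)

ds = units.record_activations(params, n_trials_per_env=250, seed=7)
print("recorded %d timesteps over %d environments" % (len(ds), len(set(ds.env_id))))

labels = units.classify_units(ds)
label_df = pd.DataFrame({
    "unit": range(len(labels)),
    "label": [l.label for l in labels],
    "p_quadrant": [l.p_quadrant for l in labels],
    "p_landmark": [l.p_landmark for l in labels],
    "p_interaction": [l.p_interaction for l in labels],
})
label_df.to_csv(OUT / "unit_labels.csv", index=False)
print("unit-type fractions:")
print((label_df["label"].value_counts() / len(label_df)).round(3).to_string())

modules = units.identify_functional_modules(ds, k=10)
module_df = pd.DataFrame({
    "unit": range(ds.n_units),
    "r2_direction": modules.r2_direction,
    "r2_state": modules.r2_state,
    "module": [
        "vector" if u in set(modules.vector)
        else "transition" if u in set(modules.transition)
        else "unspecialized" if u in set(modules.unspecialized)
        else "other"
        for u in range(ds.n_units)
    ],
})
module_df.to_csv(OUT / "module_assignment.csv", index=False)
print("\nmodule sizes:", module_df["module"].value_counts().to_dict())

lesion_task = ag.TaskConfig(
    conditions=("directions_only", "states_only"), kinds=("open",)
)
lesions = {
    "vector": modules.vector,
    "transition": modules.transition,
    "unspecialized": modules.unspecialized,
}
effects = units.evaluate_lesioned(params, lesions, lesion_task, n_trials=200, seed=3)
effects.to_csv(OUT / "lesion_effects.csv", index=False)
print("\nlesion effects (excess steps vs intact):")
print(effects.round(2).to_string(index=False))

rows = []
for name, unit_set in lesions.items():
    rows.append({
        "module": name,
        "current_location_error": units.decode_continuous(ds, unit_set, "current"),
        "goal_location_error": units.decode_continuous(ds, unit_set, "goal"),
        "landmark_adjacency_error": units.decode_binary(ds, unit_set, "landmark"),
        "goal_adjacency_error": units.decode_binary(ds, unit_set, "goal"),
    })
decoding = pd.DataFrame(rows)
decoding.to_csv(OUT / "decoding_errors.csv", index=False)
print("\ndecoding by module:")
print(decoding.round(3).to_string(index=False))

geometry = units.representational_pca(ds, modules.vector, "post_landmark")
geometry.to_csv(OUT / "geometry_centroids.csv", index=False)
evr = geometry.attrs["explained_variance_ratio"]
print("\nvector-unit PCA variance explained (first 3 PCs):", np.round(evr, 3))
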