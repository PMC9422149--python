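"""Assign a cohort and a severity degree to new query images.

Trains on one simulated study, then scores query images from a second
study (same generating process, different seed) with the frozen model:
cohort by minimum total score, severity on the training 0-1 scale.
"""

import pandas as pd

import cortexscore as cs
from cortexscore.severity import fit_severity, severity_for_new
from cortexscore.thickness import cohort_map

train_m, train_meta, _ = cs.simulate_cohort_study(cs.preset("separated", seed=1))
query_m, query_meta, _ = cs.simulate_cohort_study(cs.preset("separated", seed=99))
queries = query_m.iloc[:, :6]  # six unseen images

fitted = cs.fit_pipeline(train_m, train_meta, cs.AnalysisConfig())
predictions = cs.classify_images(fitted.model, queries)

rows = []
for img, row in predictions.iterrows():
    label = row["group"]
    if label not in fitted.essential:
        continue
    vids = fitted.essential[label].vertex_ids
    group_imgs = fitted.assignment.index[fitted.assignment["group"] == label]
    block = train_m.loc[vids, group_imgs]
    block = block[block.std(axis=1, ddof=0) > 0]
    _, _, sev_model = fit_severity(block, cohort_map(train_meta))
    sd = severity_for_new(queries.loc[block.index, [img]], sev_model)
    rows.append({"image_id": img, "clinical": cohort_map(query_meta)[img],
                 "group": label, "predicted": row["predicted"],
                 "severity_degree": round(float(sd[img]), 3)})

print(pd.DataFrame(rows).set_index("image_id").to_string())

# severity_degree reads on the training scale: ~0 is the CN basin, ~1 the
# AD basin; values between stage the subject along the CN-to-AD axis
# regardless of the hard cohort call.
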