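"""Train the convolutional-biLSTM-attention estimator and score it day-level.

A small strongly separable cohort (steeper filling, guaranteed heart-rate
ramp and denser limb movements on enuretic nights) is generated, the deep
estimator is trained against the linear probability targets, and nights are
scored enuretic/dry by whether any 10-minute block exceeds the 0.85 alarm
threshold.
"""

import numpy as np

import nocturne as nc
from nocturne import deep, estimators, evaluation, labels
from nocturne.features import ALL_FEATURES

config = nc.SimConfig(
    seed=5, n_nights=16, sleep_duration=3600.0,
    bi_fill_slope=-4.0, bi_fill_slope_ne=-12.0,
    hr_ramp_probability=1.0, plm_index_target=5.0, plm_index_target_ne=30.0,
)
nights = nc.simulate.simulate_balanced_cohort(config)
data = []
for night in nights:
    grid = nc.resample_and_align(night)
    frame = nc.extract_features(night, grid)
    curve = labels.probability_curve(night, grid)
    data.append((night, frame, curve))

model, log = deep.train_de([(f, c) for _, f, c in data],
                           deep.DEConfig(epochs=6, seed=1))
print(f"model: {model.n_parameters()} parameters")
print("training loss per epoch:", [round(x, 4) for x in log.train_loss])

predictions = []
for night, frame, _ in data:
    decisions = []
    for block in estimators.make_blocks(frame):
        X = block.features[list(ALL_FEATURES)].to_numpy()
        if block.complete and not np.isnan(X).any():
            decisions.append(estimators.WindowDecision(
                block.start_time, "DE", None, deep.de_estimate(model, X)))
    predictions.append(
        evaluation.day_level_decision(decisions, night.is_ne_day, night.night_id))

metrics = evaluation.day_metrics(predictions)
print(f"day-level accuracy {metrics.accuracy:.2f} "
      f"(TP={metrics.tp} FP={metrics.fp} FN={metrics.fn} TN={metrics.tn})")
print("an enuretic night counts as predicted when any block probability > 0.85")
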