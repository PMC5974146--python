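"""Train, calibrate a specificity threshold, and call an independent set.

A pool of proteins is partitioned into a balanced training set, a
negatives-only specificity-estimation set and an independent test set.  The
threshold for a requested estimated specificity is the empirical quantile
of the calibration negatives' scores; score >= threshold calls a protein
mitochondrial.
"""

from plantmito import calibration as cal, evaluation as ev, models, pipeline
from plantmito import seqdata, synthetic
from plantmito.features import FeatureConfig

config = synthetic.GeneratorConfig(n_pos=160, n_neg=400, seed=3)
records, profiles, meta = synthetic.generate_study(config)
part = seqdata.partition(records, n_train_per_class=120, n_spec_neg=200,
                         n_test_per_class=40, seed=0)

fconfig = FeatureConfig()
knn_config = pipeline.training_knn_config(part.training)
train_fs = pipeline.build_feature_set(part.training, profiles, meta,
                                      knn_config, fconfig)
model = models.svm_model(train_fs.X, train_fs.y,
                         fingerprint=train_fs.fingerprint)

spec_fs = pipeline.build_feature_set(part.specificity_set, profiles, meta,
                                     knn_config, fconfig)
table = cal.build_calibration(models.predict(model, spec_fs.vectors))

test_fs = pipeline.build_feature_set(part.test, profiles, meta,
                                     knn_config, fconfig)
scores = models.predict(model, test_fs.vectors)
for level in (0.90, 0.95, 0.99):
    t = cal.threshold_for_specificity(table, level)
    calls = cal.classify(scores, t)
    rep = ev.metrics(ev.confusion(test_fs.y, calls))
    print(f"specificity level {level:.2f}: threshold {t:+.3f}, "
          f"{calls.sum()} positive calls, "
          f"test sensitivity {rep.sensitivity:.2f}, "
          f"test specificity {rep.specificity:.2f}")
print("Raising the level trades sensitivity for fewer false positives; "
      "the threshold guarantees the requested specificity on the "
      "calibration negatives.")
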