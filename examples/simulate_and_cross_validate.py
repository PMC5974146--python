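"""Generate a synthetic study and cross-validate both classifiers.

The generator plants the two signals the predictor exploits: an N-terminal
composition bias (enriched R/W/H/L/K/A/Y/I, depleted D/E/V/N/G/P/M) in 70%
of the positives, and a shared expression factor that makes positives
co-express.  Fold-safe 10-fold CV then measures how well the SVM and the
maxout network recover the labels.
"""

from plantmito import models, pipeline, synthetic

config = synthetic.GeneratorConfig(n_pos=150, n_neg=150, seed=1)
records, profiles, meta = synthetic.generate_study(config)
print(f"study: {len(records)} proteins, "
      f"{sum(r.label == 'positive' for r in records)} positive")

svm_cv = pipeline.cross_validate(records, profiles, meta, kind="svm", seed=0)
print(f"SVM    mean CV AUC = {svm_cv.mean_auc:.3f}")

dnn_config = models.DNNConfig(hidden_sizes=(32, 32, 16), max_epochs=60)
dnn_cv = pipeline.cross_validate(records, profiles, meta, kind="dnn",
                                 dnn_config=dnn_config, seed=0)
print(f"maxout mean CV AUC = {dnn_cv.mean_auc:.3f}")

print("AUC ~0.5 would mean the features carry no label information; "
      "values near 1 mean the planted mitochondrial signals are recovered.")
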