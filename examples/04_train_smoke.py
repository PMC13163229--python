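"""Two-stage transfer-learning run on a separable phantom cohort.

A reduced-width model (64-px input, width-8 streams) is trained with the
full protocol: stage 1 freezes the backbone (Adam, lr 0.001, early stopping
on validation AUC with patience 7, lr halved after 3 plateaued epochs),
stage 2 unfreezes it at lr 0.0001 with patiences 10/7. Batch-norm moving
statistics are calibrated on the training set first, since a random
backbone starts with uninformative statistics.
"""

from dsanet import ModelConfig, PhantomSpec, SplitSpec, build_model, generate_cohort, split_dataset
from dsanet.training import calibrate_batchnorm, records_to_arrays, train_two_stage

records = generate_cohort(40, 5, class_balance=0.5, spec=PhantomSpec(image_size=64), seed=7)
train, val, test = split_dataset(records, SplitSpec(seed=7))

config = ModelConfig.smoke(64)
model = build_model(config, seed=7)
xtr, ytr = records_to_arrays(train, config.input_size)
xval, yval = records_to_arrays(val, config.input_size)

calibrate_batchnorm(model, xtr)
model, history = train_two_stage(model, (xtr, ytr), (xval, yval), batch_size=16, seed=7)

df = history.to_dataframe()
print(df[["epoch", "stage", "lr", "train_loss", "val_acc", "val_auc"]].tail(8).to_string(index=False))
stage1 = df[df.stage == 1]
print(f"\nstage-1 best validation AUC: {stage1.val_auc.max():.3f} "
      f"(stopped at epoch {int(stage1.epoch.max())}, {history.stopping['stage1']['reason']})")
print(f"final validation AUC: {df.val_auc.iloc[-1]:.3f}")
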