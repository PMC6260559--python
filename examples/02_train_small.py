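"""Train a small residual network on a small synthetic dataset.

Uses a reduced problem (6 subjects x 3 slices of 96x96, depth-6 net,
800 patches, 8 epochs) so the script finishes in a couple of minutes on
one CPU; the full protocol is in marcnet.benchmark.
"""

from marcnet import DatasetConfig, TrainConfig, build_dataset, save_checkpoint, train

dataset = build_dataset(6, 3, seed=0, config=DatasetConfig(size=(96, 96)))
config = TrainConfig(
    patch_size=50, n_patches=800, epochs=8, depth=6, n_filters=8,
    batch_size=64, seed=0,
)
result = train(config, dataset)

h = result.history
print(f"initial validation loss: {h['initial_val_loss']:.3e}")
print(f"final validation loss:   {h['val_loss'][-1]:.3e}")
print(f"best epoch: {h['val_loss'].index(min(h['val_loss'])) + 1} of {config.epochs}")
save_checkpoint(result.state, "scratch_checkpoint.npz")
print("checkpoint written to scratch_checkpoint.npz")
# A falling validation loss shows the network is learning the mapping from
# artifact-insert patches to their artifact residuals.
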