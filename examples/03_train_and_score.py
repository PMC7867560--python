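"""Train candidate C on a small cohort and score unseen calcifications.

Every voxel of each segmented calcification contributes one 2.5D patch
triplet (with left-right mirror augmentation); at inference the per-voxel
stone probabilities are averaged into one score per calcification.
"""

from calcnet import (RunConfig, TrainConfig, build_network, generate_cohort,
                     score_calcification, segment_stack, train)
from calcnet.patches import build_training_set

train_stacks, _ = generate_cohort(12, 12, seed=1, id_prefix="tr")
test_stacks, _ = generate_cohort(3, 3, seed=2, id_prefix="te")

items = [(s, segment_stack(s), s.label) for s in train_stacks]
training_set = build_training_set(items)  # one triplet per voxel, mirrored
print(f"{len(training_set)} training triplets from {len(items)} calcifications")

model = build_network("C", patch_size=31, seed=0)
log = train(model, training_set, TrainConfig(epochs=4, seed=0))
print(log[["epoch", "train_loss", "train_acc"]].to_string(index=False))

for stack in test_stacks:
    cs = score_calcification(model, stack, segment_stack(stack))
    print(f"{stack.id}: true={stack.label:<11s} score={cs.score:.3f} "
          f"-> {cs.predicted_label}  ({cs.n_voxels} voxels)")
# score is the mean per-voxel stone probability; >= 0.5 is called stone
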