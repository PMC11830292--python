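"""Train/validation/test sizing: sequential rounding, stratified, grouped.

The test share is rounded off the whole first, then the validation share
off the remainder.  On 15,231 segments at 15%/15% this gives
11,004 / 1,942 / 2,285 - which naive simultaneous 70/15/15 rounding
does not.  Splitting is grouped by recording, so windows cut from one
recording never straddle partitions.
"""

from pcgnet import split_sizes
from pcgnet.dataset_split import split_dataset
from pcgnet.segment_augment import LabeledDataset, Segment

import numpy as np

train, val, test = split_sizes(15_231, test_frac=0.15, val_frac=0.15)
print(f"sequential split of 15,231 segments: train={train:,} val={val:,} test={test:,}")
sim = split_sizes(15_231, 0.15, 0.15, mode="simultaneous")
print(f"simultaneous rounding would give:    train={sim[0]:,} val={sim[1]:,} test={sim[2]:,}")

# grouped: 20 recordings x 3 windows each
segments = [
    Segment(samples=np.zeros(16), fs=2000.0, label=lab, source_id=f"rec{r}", start_s=float(j))
    for r, lab in enumerate(["normal"] * 10 + ["abnormal"] * 10)
    for j in range(3)
]
split = split_dataset(LabeledDataset(segments), 0.2, 0.2, seed=0)
print(f"\n60 windows from 20 recordings -> sizes {split.sizes()}")
for name, part in (("train", split.train), ("val", split.val), ("test", split.test)):
    recs = sorted({s.source_id for s in part.segments})
    print(f"  {name:5s}: {len(part):2d} windows from recordings {recs}")
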