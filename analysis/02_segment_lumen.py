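#!/usr/bin/env python
"""Segment the trunk slice stack and score it against ground truth.

Runs the per-slice chain (morphological reconstruction denoising, Otsu
binarization, edge map, snake initialized from the previous slice) and
reports the per-slice intersection-over-union.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from eecp_hemoflow.io import read_contours_csv, read_image_stack, write_contours_csv
from eecp_hemoflow.segment import contour_iou, segment_stack

IN = Path("results/inputs")
OUT = Path("results/segmentation")
OUT.mkdir(parents=True, exist_ok=True)

stack = read_image_stack(IN / "stack")
truth = read_contours_csv(IN / "truth_contours.csv")
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    contours = segment_stack(stack, truth[0])
write_contours_csv(OUT / "contours.csv", contours)

ious = [contour_iou(c, t, stack[0].shape) for c, t in zip(contours, truth)]
pd.DataFrame({"slice": range(len(ious)), "iou": ious}).to_csv(
    OUT / "iou.csv", index=False
)
print(f"segmented {len(contours)} slices")
print(f"mean IoU vs truth: {np.mean(ious):.4f} (min {min(ious):.4f})")
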