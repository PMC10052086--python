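#!/usr/bin/env python
"""Segmentation quality and the coverage time series.

The excess-green segmenter is scored against the rendered ground-truth
masks with mean IoU, and the coverage trajectory it produces is compared
with ground truth.  Writes coverage.csv and the coverage figure.
"""

import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from canopyspace.segmentation import coverage, exg_segment, miou
from canopyspace.synth import SimConfig, simulate_batch

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = SimConfig(seed=seed)
    batch = simulate_batch(cfg)
    rows = []
    for day in batch.days:
        i = batch.frame_index(day)
        pred = exg_segment(batch.frames[i].rgb)
        rows.append(
            {
                "day": day,
                "coverage_exg_pct": coverage(pred).percent,
                "coverage_gt_pct": batch.gt_coverage_pct(day),
                "miou": miou(pred, batch.masks[i]),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "coverage.csv", index=False)

    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(df["day"], df["coverage_gt_pct"], label="ground truth")
    ax.plot(df["day"], df["coverage_exg_pct"], "--", label="excess-green segmenter")
    ax.set_xlabel("day after transplanting")
    ax.set_ylabel("coverage [%]")
    ax.legend()
    fig.tight_layout()
    fig.savefig(RESULTS / "coverage.png", dpi=110)

    print(f"mean IoU over {len(df)} daily frames: {df['miou'].mean():.4f} "
          f"(min {df['miou'].min():.4f})")
    print(
        "max |coverage error| vs ground truth: "
        f"{np.abs(df['coverage_exg_pct'] - df['coverage_gt_pct']).max():.3f} points"
    )


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
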