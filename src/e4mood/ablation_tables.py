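"""Published ablation summaries bundled as reference data.

These two tables reproduce, verbatim, the ablation results printed in the
study that introduced the self-supervised wearable mood-episode pipeline this
package implements: the change in target-task segment and subject accuracy
(percentage points, against the full-collection reference model) when the
unlabeled pretraining collection is (a) stratified-downsampled to a given
ratio, or (b) deprived of one constituent dataset at a time.

They serve as worked inputs for the correlation analysis: the association
between unlabeled-data availability and downstream performance is summarized
by Pearson correlations between the ablation axis (downsampling ratio, or a
left-out dataset's relative share of the collection) and the accuracy change.
"""

from __future__ import annotations

import pandas as pd

from .train import pearson_corr

__all__ = ["downsampling_table", "leave_one_out_table", "ablation_correlations"]


def downsampling_table() -> pd.DataFrame:
    """Stratified downsampling of the unlabeled collection (ratio in %)."""
    return pd.DataFrame({
        "ratio_pct": [80, 60, 40, 20, 0],
        "delta_acc_segment": [-0.23, -2.14, -6.07, -6.35, -7.07],
        "delta_acc_subject": [-1.57, -1.57, -4.70, -4.70, -7.82],
    })


def leave_one_out_table() -> pd.DataFrame:
    """Leave-one-dataset-out ablation; relative size is the dataset's share (%)."""
    return pd.DataFrame({
        "dataset": [
            "ADARP", "Stress Predict", "Toadstool", "UE4W", "WEEE", "WESAD",
            "WESD", "In-GaugeEn-Gage", "Nurse Stress Detection", "BIG IDEAs Lab",
            "PPG-DaLiA", "TIMEBASE/INTREPIBD",
        ],
        "relative_size_pct": [12.34, 0.30, 0.04, 2.32, 0.18, 0.42,
                              0.72, 17.55, 11.82, 19.38, 0.69, 34.24],
        "delta_acc_segment": [-2.44, -0.21, 0.52, -1.93, 1.19, -0.51,
                              1.90, -4.44, -0.81, -2.09, 1.93, -4.32],
        "delta_acc_subject": [-1.57, -1.57, -3.13, -4.70, 1.57, -1.57,
                              1.57, -4.70, -1.57, -1.57, 4.70, -3.13],
    })


def ablation_correlations() -> dict[str, float]:
    """Pearson correlations summarizing both ablation tables."""
    ds = downsampling_table()
    loo = leave_one_out_table()
    return {
        "downsampling_vs_delta_segment": pearson_corr(ds.ratio_pct, ds.delta_acc_segment),
        "downsampling_vs_delta_subject": pearson_corr(ds.ratio_pct, ds.delta_acc_subject),
        "size_vs_delta_segment": pearson_corr(loo.relative_size_pct, loo.delta_acc_segment),
        "size_vs_delta_subject": pearson_corr(loo.relative_size_pct, loo.delta_acc_subject),
    }
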