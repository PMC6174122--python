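#!/usr/bin/env python
"""Extract evoked-force and EMG fatigue metrics from the pre/post assessments.

Regenerates the study and analyzes every neuromuscular recording: MVC peak
force, superimposed and resting evoked amplitudes, voluntary activation level
(interpolated-twitch with the off-peak correction), P10/P100 and the
M-wave-normalized EMG RMS.  Writes the per-assessment table plus pre/post x
condition group means to results/.
"""

from pathlib import Path

from sprintox.pipeline import RunConfig, run_analyze, run_generate

SEED = 42
RESULTS = Path("results")
RESULTS.mkdir(exist_ok=True)


def main() -> None:
    cfg = RunConfig(seed=SEED, n_participants=11, output_dir="results",
                    skip_stats=True)
    dataset = run_generate(cfg, write=False)
    tables = run_analyze(cfg, dataset, write=False)

    nm = tables["neuromuscular_summary"]
    nm.to_csv(RESULTS / "neuromuscular_summary.csv", index=False,
              float_format="%.4f")
    cols = ["mvc_N", "val_pct", "p10_p100", "rms_mwave"]
    group = nm.groupby(["condition", "phase"])[cols].agg(["mean", "std"])
    group.round(3).to_csv(RESULTS / "neuromuscular_group_means.csv",
                          float_format="%.4f")
    print("neuromuscular metrics by condition x phase (means):")
    print(nm.groupby(["condition", "phase"])[cols].mean().round(3).to_string())
    flagged = nm["val_flagged"].sum()
    print(f"assessments with VAL clamped at 100%: {int(flagged)}")


if __name__ == "__main__":
    main()
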