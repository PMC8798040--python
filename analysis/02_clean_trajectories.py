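"""Clean every simulated cohort: quartile-fence outlier filtering and
3-frame smoothing; writes the cleaned datasets and removal reports.

Requires ``01_simulate_cohorts.py`` to have run.
"""

import json
from pathlib import Path

import volgrowth as vg

IN = Path("results/data")
OUT = Path("results/clean")


def main() -> None:
    for cohort_dir in sorted(IN.iterdir()):
        if not cohort_dir.is_dir():
            continue
        ds = vg.read_dataset(cohort_dir)
        clean, report = vg.preprocess_dataset(ds)
        out = OUT / cohort_dir.name
        out.mkdir(parents=True, exist_ok=True)
        clean.trajectories.to_csv(out / "trajectories.csv", index=False,
                                  float_format="%.10g")
        clean.annotations.to_csv(out / "annotations.csv", index=False,
                                 float_format="%.10g")
        (out / "dataset.json").write_text(json.dumps(
            {"frame_interval": clean.frame_interval,
             "provenance": clean.provenance}, indent=2, default=str))
        report.to_csv(out / "removals.csv", index=False)
        frac = len(report) / max(len(ds.trajectories), 1)
        print(f"{cohort_dir.name:15s} removed {len(report):5d} points "
              f"({frac:.1%}) from {ds.n_cells} cells")


if __name__ == "__main__":
    main()
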