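"""Simulate the study cohort: 29 low-SES and 29 high-SES synthetic subjects.

Each subject is 240 s of 60-channel, 1000 Hz resting-state-like EEG in 2-s
epochs, generated from the canonical A-D templates with a semi-Markov label
stream at unit SNR.  The low-SES group carries the direction-of-effect
preset: class-A dwell up 30%, A<->B and A<->D switching up, B<->C and C<->D
switching down.  Recordings land under scratch/ (large), the demographic
table and ground-truth manifest under results/.

Run:  python analysis/01_simulate_cohort.py [--n 29] [--duration 240]
"""

import argparse
import json
from pathlib import Path

import ses_microstates as ms
from ses_microstates import io as msio

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n", type=int, default=29, help="subjects per group")
    ap.add_argument("--duration", type=float, default=240.0, help="seconds per subject")
    ap.add_argument("--seed", type=int, default=2024)
    args = ap.parse_args()

    out_data = ROOT / "scratch" / "cohort"
    out_res = ROOT / "results"
    out_data.mkdir(parents=True, exist_ok=True)
    out_res.mkdir(parents=True, exist_ok=True)

    cohort = ms.simulate_cohort(ms.low_ses_contrast_spec(args.n),
                                ms.high_ses_spec(args.n),
                                duration_s=args.duration, seed=args.seed)
    for sid in cohort.subject_ids:
        msio.write_recording_tsv(cohort.render(sid), out_data / f"{sid}.tsv")
    cohort.demographics.to_csv(out_data / "demographics.tsv", sep="\t", index=False)
    cohort.demographics.to_csv(out_res / "demographics.tsv", sep="\t", index=False)
    (out_res / "ground_truth.json").write_text(json.dumps(cohort.manifest(), indent=1))

    print(f"wrote {len(cohort.subject_ids)} recordings "
          f"({args.duration:.0f} s each) to {out_data}")
    print(f"demographics + ground truth manifest in {out_res}")


if __name__ == "__main__":
    main()
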