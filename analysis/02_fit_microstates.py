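"""Fit the microstate model to the simulated cohort.

Per subject: 2-20 Hz band-pass, average reference, GFP-peak extraction,
polarity-invariant AAHC at K=4.  Per group: pooled re-clustering of the
individual templates, canonical A-D sorting against the atlas, then each
subject's own maps sorted against their group set, backfitting, and the
temporal parameter tables.  Writes parameters, transitions, per-subject GEV
and the sorted group templates under results/.

Run after 01_simulate_cohort.py:  python analysis/02_fit_microstates.py
"""

from pathlib import Path

import ses_microstates as ms
from ses_microstates import io as msio

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    data = ROOT / "scratch" / "cohort"
    out = ROOT / "results"
    if not data.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    out.mkdir(parents=True, exist_ok=True)
    demo = msio.read_demographics(data / "demographics.tsv")
    groups = dict(zip(demo["subject_id"], demo["group"]))
    cfg = ms.PipelineConfig()

    files = sorted(p for p in data.glob("S*.tsv"))
    recs = ((p.stem, msio.read_recording(p)) for p in files)
    result = ms.analyze_cohort(recs, groups, cfg)

    result.params.to_csv(out / "parameters.tsv", sep="\t", index=False)
    result.transitions.to_csv(out / "transitions.tsv", sep="\t", index=False)
    result.subject_gev.to_csv(out / "gev.tsv", sep="\t", index=False)
    for g, tset in result.group_template_sets.items():
        msio.write_templates(tset, out / f"templates_{g}.json")
    (out / "config.json").write_text(cfg.to_json())

    gev = result.subject_gev.groupby("group")["gev"].agg(["mean", "std"])
    print("backfit GEV by group (fraction of GFP-peak variance explained):")
    print(gev.round(4))
    print(f"parameter tables in {out}")


if __name__ == "__main__":
    main()
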