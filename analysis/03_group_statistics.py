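"""Group statistics on the fitted microstate parameters.

SES composite scoring, Pearson correlations of SES with each parameter,
mixed-design repeated-measures ANCOVAs (group x class, age + gender
covariates) for duration / occurrence / coverage, Bonferroni post hoc group
contrasts per class, and independent-samples t-tests on the 12 ordered
transition probabilities.  Writes tidy TSVs under results/ and prints the
headline effects.

Run after 02_fit_microstates.py:  python analysis/03_group_statistics.py
"""

from pathlib import Path

import pandas as pd

import ses_microstates as ms
from ses_microstates import io as msio

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    out = ROOT / "results"
    out.mkdir(parents=True, exist_ok=True)
    params = pd.read_csv(out / "parameters.tsv", sep="\t")
    transitions = pd.read_csv(out / "transitions.tsv", sep="\t")
    demo = msio.read_demographics(out / "demographics.tsv")
    cfg = ms.PipelineConfig()

    results = ms.group_statistics(params, transitions, demo, cfg)
    ms.write_results(results, out, cfg)

    anc = results["ancova"]
    print("mixed ANCOVA (group x class, covarying age and gender):")
    print(anc[["parameter", "effect", "statistic", "df1", "df2", "p",
               "effect_size"]].round(4).to_string(index=False))
    sig = results["posthoc"].query("p_adj < 0.05")
    print("\nBonferroni post hoc contrasts with adjusted p < 0.05:")
    cols = ["parameter", "effect", "statistic", "p_adj"]
    print(sig[cols].round(4).to_string(index=False) if len(sig) else "  none")
    tsig = results["transition_tests"].query("p < 0.05")
    print("\ntransition t-tests with p < 0.05:")
    print(tsig[["effect", "statistic", "p"]].round(4).to_string(index=False)
          if len(tsig) else "  none")


if __name__ == "__main__":
    main()
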