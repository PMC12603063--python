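"""Group-level model comparison with exceedance probabilities.

Feeds the per-participant AICs from the learning fits (M1-M3) and the
closeness fits (C1-C2, ingroup and outgroup pooled by summing each
participant's AICs across groups) to random-effects Bayesian model
selection, and writes the per-model XP / expected frequency / summed AIC
reports to results/.
"""

from pathlib import Path

import pandas as pd

from grouplearn.model_selection import compare_models

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    learning = pd.read_csv(OUT / "fits_learning.csv")
    closeness = pd.read_csv(OUT / "fits_closeness.csv")

    reports = []
    for culture, df in learning.groupby("culture"):
        aic = df.pivot(index="participant", columns="model", values="aic")
        res = compare_models(aic, seed=0)
        print(f"\n[{culture}] learning models\n{res.summary()}")
        rep = res.to_frame()
        rep.insert(0, "set", "learning")
        rep.insert(0, "culture", culture)
        reports.append(rep)

    for culture, df in closeness.groupby("culture"):
        aic = df.groupby(["participant", "model"])["aic"].sum().unstack()
        res = compare_models(aic, seed=0)
        print(f"\n[{culture}] closeness models\n{res.summary()}")
        rep = res.to_frame()
        rep.insert(0, "set", "closeness")
        rep.insert(0, "culture", culture)
        reports.append(rep)

    pd.concat(reports).to_csv(OUT / "model_selection.csv", index=False)
    print(f"\nwrote {OUT / 'model_selection.csv'}")


if __name__ == "__main__":
    main()
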