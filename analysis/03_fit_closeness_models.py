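"""Fit the two closeness models per participant and group.

For each synthetic participant, takes the prediction-error trajectory of
their fitted M3 learning model (the winning variant), then fits C1 (one
weight on signed PEs) and C2 (separate positive/negative weights) to the
ingroup and outgroup closeness-change series separately.  Writes
results/fits_closeness.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from grouplearn.fitting import fit_closeness, fit_learning, fits_to_frame
from grouplearn.task_design import INGROUP, OUTGROUP

sys.path.insert(0, str(Path(__file__).resolve().parent))
from importlib import import_module

sessions_by_culture = import_module("02_fit_learning_models").sessions_by_culture

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    frames = []
    for culture, sessions in sessions_by_culture():
        fits = []
        for i, s in enumerate(sessions):
            m3 = fit_learning(s, "M3", n_restarts=10, seed=i)
            for group in (INGROUP, OUTGROUP):
                for variant in ("C1", "C2"):
                    fits.append(
                        fit_closeness(s, m3.trajectory, variant, group, n_restarts=5, seed=i)
                    )
        df = fits_to_frame(fits)
        df.insert(0, "culture", culture)
        frames.append(df)
        print(f"{culture}: mean r2 by model/group:")
        print(df.groupby(["model", "group"])["r2"].mean().round(3))
    pd.concat(frames).to_csv(OUT / "fits_closeness.csv", index=False)
    print(f"wrote {OUT / 'fits_closeness.csv'}")


if __name__ == "__main__":
    main()
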