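"""Link fitted parameters to impression change on the synthetic cohorts.

Per culture and frame: stepwise regression of intergroup impression change
((in - out) after minus before) on the fitted learning rates and closeness
weights; moderation of the W_neg_in association by frame; moderation by
ingroup identification within the loss frame; influence diagnostics on the
selected model; and the initial-bias vs identification correlation.
Writes results/linkage.csv.
"""

import sys
from importlib import import_module
from pathlib import Path

import pandas as pd

from grouplearn.fitting import fit_closeness, fit_learning
from grouplearn.linkage import (
    bias_identification_correlation,
    influence_filter,
    moderation,
    stepwise_regression,
)
from grouplearn.synthetic_data import participants_table
from grouplearn.task_design import INGROUP, OUTGROUP

sys.path.insert(0, str(Path(__file__).resolve().parent))
sessions_by_culture = import_module("02_fit_learning_models").sessions_by_culture

OUT = Path(__file__).resolve().parent.parent / "results"


def parameter_table(sessions) -> pd.DataFrame:
    rows = []
    for i, s in enumerate(sessions):
        m3 = fit_learning(s, "M3", n_restarts=10, seed=i)
        row = {"participant": s.participant, "frame": s.frame,
               "identification": s.identification,
               "impression_change": s.intergroup_impression_change, **m3.params}
        for group, tag in ((INGROUP, "in"), (OUTGROUP, "out")):
            c2 = fit_closeness(s, m3.trajectory, "C2", group, n_restarts=5, seed=i)
            row[f"w_pos_{tag}"] = c2.params["w_pos"]
            row[f"w_neg_{tag}"] = c2.params["w_neg"]
        rows.append(row)
    return pd.DataFrame(rows)


CANDIDATES = [
    "alpha_in_pos", "alpha_in_neg", "alpha_out_pos", "alpha_out_neg",
    "w_pos_in", "w_neg_in", "w_pos_out", "w_neg_out",
]


def main() -> None:
    OUT.mkdir(exist_ok=True)
    records = []
    for culture, sessions in sessions_by_culture():
        params = parameter_table(sessions)
        parts = participants_table(sessions)
        corr = bias_identification_correlation(parts)
        print(f"\n[{culture}] initial bias vs identification: "
              f"r = {corr['r']:.3f} (p = {corr['p']:.4f}), rho = {corr['rho']:.3f}")
        records.append({"culture": culture, "analysis": "bias_identification",
                        "term": "r", "estimate": corr["r"], "p": corr["p"]})

        for frame, df in params.groupby("frame"):
            step = stepwise_regression(df[CANDIDATES], df["impression_change"])
            print(f"[{culture}/{frame}] stepwise selected: {step.selected_predictors or 'none'}")
            for _, r in step.coefficients.iterrows():
                records.append({"culture": culture, "analysis": f"stepwise_{frame}",
                                "term": r["term"], "estimate": r["coef"], "p": r["p"]})
            if step.selected_predictors:
                infl = influence_filter(step.model_fit)
                rob = infl.robustness.set_index("term")
                print(f"  after removing {len(infl.flagged)} influential cases: "
                      + ", ".join(f"{t}: b={rob.loc[t, 'coef']:.3f} (p={rob.loc[t, 'p']:.3f})"
                                  for t in rob.index if t != "const"))

        # frame as moderator of the W_neg_in association
        frame_mod = moderation(
            params["w_neg_in"], (params["frame"] == "loss").astype(float),
            params["impression_change"], x_name="w_neg_in", moderator_name="frame",
        )
        print(f"[{culture}] frame moderation: interaction b = "
              f"{frame_mod.interaction['coef']:.3f}, p = {frame_mod.interaction['p']:.4f}")
        print(frame_mod.simple_slopes.round(3).to_string(index=False))
        records.append({"culture": culture, "analysis": "moderation_frame",
                        "term": "w_neg_in:frame", "estimate": frame_mod.interaction["coef"],
                        "p": frame_mod.interaction["p"]})

        # identification as moderator within the loss frame
        loss = params[params["frame"] == "loss"]
        ident_mod = moderation(
            loss["w_neg_in"], loss["identification"], loss["impression_change"],
            x_name="w_neg_in", moderator_name="identification",
        )
        print(f"[{culture}] identification moderation (loss frame): interaction b = "
              f"{ident_mod.interaction['coef']:.3f}, p = {ident_mod.interaction['p']:.4f}")
        records.append({"culture": culture, "analysis": "moderation_identification",
                        "term": "w_neg_in:identification",
                        "estimate": ident_mod.interaction["coef"],
                        "p": ident_mod.interaction["p"]})

    pd.DataFrame(records).to_csv(OUT / "linkage.csv", index=False)
    print(f"\nwrote {OUT / 'linkage.csv'}")


if __name__ == "__main__":
    main()
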