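"""Generate the synthetic two-culture study dataset.

Simulates a Western-profile cohort (n = 112) and an East Asian-profile
cohort (n = 100), each split across gain and loss frames on 96-trial
schedules (4 blocks x 24 trials, 75% positive outcomes, equalized
ingroup/outgroup exposure), and writes the long-format trials table and
the per-participant table (identification, pre/post impressions) under
results/.
"""

from pathlib import Path

import pandas as pd

from grouplearn.synthetic_data import generate_study, participants_table, trials_table

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260901


def main() -> None:
    OUT.mkdir(exist_ok=True)
    all_trials, all_parts = [], []
    for culture, n, seed in (("western", 112, SEED), ("east_asian", 100, SEED + 1)):
        sessions = generate_study(n_agents=n, frame_split=0.52, culture_profile=culture, seed=seed)
        t = trials_table(sessions)
        p = participants_table(sessions)
        t.insert(0, "culture", culture)
        p.insert(0, "culture", culture)
        all_trials.append(t)
        all_parts.append(p)
        print(
            f"{culture}: {n} agents, {len(t)} trial rows, "
            f"mean identification {p['identification'].mean():.2f}, "
            f"mean initial bias {(p['impression_pre_in'] - p['impression_pre_out']).mean():.2f}"
        )
    pd.concat(all_trials).to_csv(OUT / "trials.csv", index=False)
    pd.concat(all_parts).to_csv(OUT / "participants.csv", index=False)
    print(f"wrote {OUT / 'trials.csv'} and {OUT / 'participants.csv'}")


if __name__ == "__main__":
    main()
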