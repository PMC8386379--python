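"""Simulate the demo cohort and summarize what was generated.

A 20-participant, 12-week synthetic study with the default 80:20
depressed:control split and default missingness.  Raw minutely streams
are large, so they go to scratch/ (regenerable from the config); the
summary lands in results/.
"""

import json

from _demo import DEMO, RESULTS, SCRATCH

from phenoweek import generate_cohort


def main() -> None:
    data = generate_cohort(DEMO)
    out = SCRATCH / "demo_cohort"
    data.write(out)
    RESULTS.mkdir(exist_ok=True)
    DEMO.to_yaml(RESULTS / "demo_config.yaml")

    arms = data.participants["arm"].value_counts().to_dict()
    summary = {
        "n_participants": int(len(data.participants)),
        "arms": arms,
        "rows_per_stream": {name: int(len(df)) for name, df in sorted(data.streams.items())},
        "phq9_surveys_completed": int(len(data.streams["phq9"])),
        "phq9_surveys_possible": DEMO.n_participants * DEMO.n_weeks,
    }
    (RESULTS / "01_cohort_summary.json").write_text(json.dumps(summary, indent=2))
    print(f"simulated {summary['n_participants']} participants ({arms}) over {DEMO.n_weeks} weeks")
    print(f"PHQ-9 surveys: {summary['phq9_surveys_completed']}/{summary['phq9_surveys_possible']}")
    print(f"raw streams under {out}, summary in results/01_cohort_summary.json")


if __name__ == "__main__":
    main()
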