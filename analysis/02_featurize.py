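"""Filter days/weeks for data sufficiency and derive the 34 weekly features.

Re-simulates the demo cohort in a streaming pass (no dependence on the
scratch files from step 01) and writes the retained participant-week
feature matrix.
"""

from _demo import DEMO, RESULTS

from phenoweek.featurize import featurize_cohort


def main() -> None:
    matrix = featurize_cohort(DEMO)
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "participant_weeks.csv"
    matrix.to_csv(out, index=False, float_format="%.6g")
    retained = len(matrix)
    possible = DEMO.n_participants * DEMO.n_weeks
    print(
        f"retained {retained}/{possible} participant-weeks "
        f"({matrix['participant_id'].nunique()} participants) -> {out}"
    )
    print(
        f"weeks with PHQ-9: {int(matrix['phq9_sum'].notna().sum())}; "
        f"depressed weeks: {int(matrix['depressed_week'].sum())}"
    )


if __name__ == "__main__":
    main()
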