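"""Cohort accounting: adherence, retention and depressed-week fractions.

Reports the synthetic demo cohort's funnel alongside the study-report
arithmetic (printed numerator/denominator percentages under half-up
rounding), so every percentage in the write-up traces to a computation.
"""

import dataclasses
import json

from _demo import DEMO, RESULTS

from phenoweek.featurize import featurize_cohort
from phenoweek.pipeline import STUDY_FUNNEL, funnel_percentages, synthetic_accounting


def main() -> None:
    matrix = featurize_cohort(DEMO)
    acct = synthetic_accounting(DEMO, matrix)
    printed = {name: funnel_percentages(num, den, dec) for name, (num, den, dec) in STUDY_FUNNEL.items()}
    out = {"synthetic": dataclasses.asdict(acct), "printed_funnel_pct": printed}
    (RESULTS / "05_accounting.json").write_text(json.dumps(out, indent=2))

    print(f"PHQ-9 adherence: {acct.phq9_completed}/{acct.n_weeks_possible} = {acct.adherence_pct}%")
    print(f"retained weeks: {acct.n_retained_weeks} from {acct.n_participants_with_weeks} participants")
    print(
        f"complete cases: {acct.complete_case_weeks} weeks / {acct.complete_case_participants} participants "
        f"({acct.complete_case_depressed_pct}% depressed)"
    )
    print(
        f"after imputation: {acct.imputed_weeks} weeks / {acct.imputed_participants} participants "
        f"({acct.imputed_depressed_pct}% depressed)"
    )
    print("printed-report arithmetic:", json.dumps(printed))


if __name__ == "__main__":
    main()
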