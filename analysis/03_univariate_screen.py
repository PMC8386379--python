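"""Univariate Spearman screen of the 34 features against weekly PHQ-9.

Reads the feature matrix from step 02, correlates each feature with the
PHQ-9 sum over pairwise-complete weeks, adjusts the 34 P values with the
Benjamini-Hochberg step-up, and reports the significant features ordered
by absolute correlation.
"""

import pandas as pd

from _demo import RESULTS

from phenoweek.stats import significant_features, spearman_screen

ALPHA = 0.001


def main() -> None:
    matrix = pd.read_csv(RESULTS / "participant_weeks.csv")
    screen = spearman_screen(matrix)
    screen.to_csv(RESULTS / "03_screen.csv", index=False, float_format="%.6g")
    sig = significant_features(screen, ALPHA)
    sig.to_csv(RESULTS / "03_significant.csv", index=False, float_format="%.6g")
    print(f"{len(sig)} of {int(screen['defined'].sum())} testable features "
          f"significant at BH-adjusted p < {ALPHA}:")
    for row in sig.itertuples():
        print(f"  {row.feature:34s} r={row.spearman_r:+.3f}  adj p={row.p_adjusted:.2e}  n={row.n_weeks}")


if __name__ == "__main__":
    main()
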