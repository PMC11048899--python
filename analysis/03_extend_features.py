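"""Expand each panel into the 76 extended predictor variables.

For every base measurement the two predictor exams are summarised as the
closest value (C), mean (M), standard deviation (S) and difference (D),
giving the feature matrices the models are trained on.

Run after 02:  python analysis/03_extend_features.py
"""

from pathlib import Path

import pandas as pd

from verselect.features import extend_variables

OUT = Path("results")


def main() -> None:
    for name in ("cohort_default", "cohort_planted_n1000"):
        panel = pd.read_csv(OUT / f"{name}.panel.csv")
        features = extend_variables(panel)
        features.to_csv(OUT / f"{name}.features.csv", index=False)
        print(
            f"{name}: feature matrix {features.shape[0]} subjects x "
            f"{features.shape[1] - 2} extended variables"
        )


if __name__ == "__main__":
    main()
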