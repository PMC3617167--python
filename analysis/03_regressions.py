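"""Correlation table and regression models 1-3 on the moment-exact cohort."""

from pathlib import Path

import pandas as pd

from vaspan.association import correlation_matrix, ols_fit, partial_correlation
from vaspan.pipeline_io import MODELS

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = pd.read_csv(RESULTS / "cohort.csv")
    variables = ["age", "va_span", "C", "K", "reading_speed"]

    lines = ["Pairwise correlations (stars: * .05, ** .01, *** .001)", ""]
    res = correlation_matrix(cohort, variables)
    lines.append(res.r.round(3).to_string())
    lines.append("")
    lines.append("Age-controlled partial correlations")
    non_age = [v for v in variables if v != "age"]
    for i, u in enumerate(non_age):
        for v in non_age[i + 1:]:
            r = partial_correlation(cohort, u, v, "age")
            lines.append(f"  {u} ~ {v} | age: {r:.3f}")
    lines.append("")

    for name, (resp, preds) in MODELS.items():
        fit = ols_fit(cohort, resp, preds)
        lines.append(f"{name}: {resp} ~ {' + '.join(preds)}")
        lines.append(f"  R^2 = {fit.r_squared:.4f}")
        for p in preds:
            lines.append(
                f"  {p:<10} b = {fit.params[p]:>8.4f}   p = {fit.pvalues[p]:.4f}"
            )
        lines.append("")

    out = RESULTS / "03_regressions.txt"
    out.write_text("\n".join(lines) + "\n")
    print(out.read_text())


if __name__ == "__main__":
    main()
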