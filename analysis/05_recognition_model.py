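"""Single-trial recognition model: the full study end to end.

Runs the complete pipeline (wake epochs -> predictors -> sleep/coupling ->
generated outcomes -> balanced maps -> mixed-effects logistic fits) and then
performs forward-stepwise AIC selection over the candidate fixed effects,
printing the selected model with odds ratios and VIFs.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, study_config

from repstab.model import stepwise_aic
from repstab.pipeline import run_study


def main() -> None:
    cfg = study_config()
    report = run_study(cfg)
    for variant in ("early", "late"):
        m = report["stages"]["model"][variant]
        print(f"model ({variant} reinstatement): N = {m['n']}, "
              f"AIC = {m['aic']:.1f}, log-likelihood = {m['loglik']:.1f}, "
              f"sigma_u = {m['sigma_u']:.2f}")
        for term, or_ in m["odds_ratios"].items():
            print(f"  {term:28s} OR = {or_:6.2f}  p = {m['p_values'][term]:.2e}")
        if m["vif"]:
            print(f"  max VIF = {max(m['vif'].values()):.2f}")

    trials = pd.read_csv(Path(cfg.output_dir) / "trial_table.tsv", sep="\t")
    trials["outcome"] = trials["outcome"].astype(int)
    fit, trace = stepwise_aic(trials, list(cfg.model_terms))
    print(f"stepwise AIC selected: {fit.terms} (AIC {fit.aic:.1f})")
    pd.DataFrame(trace).to_csv(RESULTS / "stepwise_trace.tsv", sep="\t",
                               index=False)
    fit.summary().to_csv(RESULTS / "selected_model.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
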