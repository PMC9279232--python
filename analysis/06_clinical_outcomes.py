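#!/usr/bin/env python
"""Prognostic relevance of the baseline classification: regress baseline
EDSS and long-term outcomes on baseline subtype, stage, their interaction,
age and sex (plus follow-up time and therapy for long-term outcomes).

Ordinal outcomes use proportional-odds models, the secondary-progressive
transition a logistic model; CIs are percentile bootstrap over subjects
(500 resamples here; raise to the 5000 production default for final runs).

Writes results/outcome_<name>.csv and results/outcomes_summary.json.
"""

import json

import pandas as pd

from msstratify import (
    fit_outcome,
    label_subtypes,
    merge_assignments,
    read_biomarker_table,
    read_clinical_table,
    read_model,
)

from study_config import CONFIG, RESULTS, SEED

BOOTSTRAP_REPS = 500


def main() -> None:
    model = read_model(RESULTS / "model.json")
    z = read_biomarker_table(RESULTS / "data" / "patients_z.csv", scale="zscore")
    clinical = read_clinical_table(RESULTS / "data" / "clinical.csv")
    assignments = pd.read_csv(RESULTS / "assignments.csv")

    labels = label_subtypes(model, CONFIG.dgm_biomarkers, CONFIG.cortical_biomarkers, CONFIG.lesion_biomarker)
    baseline = z.baseline()
    merged = merge_assignments(baseline, assignments[assignments["visit_index"] == 0], clinical)
    merged["subtype_coded"] = merged["ml_subtype"].map(
        {c: int(lab != "DGM-first") for c, lab in labels.items()}  # DGM-first = 0
    )

    summary = {}
    for name in ("baseline_edss", "lt_edss", "lt_bicams", "lt_sp"):
        fit = fit_outcome(merged, name, bootstrap_reps=BOOTSTRAP_REPS, seed=SEED)
        fit.params.to_csv(RESULTS / f"outcome_{name}.csv")
        summary[name] = {
            "family": fit.family,
            "n": fit.n,
            "nagelkerke_r2": fit.overall["nagelkerke_r2"],
            "lr_p": fit.overall["lr_p"],
            "stage_b": fit.coef("stage"),
            "stage_ci": fit.ci("stage"),
            "subtype_b": fit.coef("subtype"),
        }
        stage = fit.params.loc["stage"]
        print(f"{name} ({fit.family}, n={fit.n}): stage b = {stage['b']:.3f} "
              f"[{stage['ci_low']:.3f}, {stage['ci_high']:.3f}], p = {stage['p']:.2g}; "
              f"Nagelkerke R2 = {fit.overall['nagelkerke_r2']:.3f}")
    (RESULTS / "outcomes_summary.json").write_text(json.dumps(summary, indent=2, default=float))


if __name__ == "__main__":
    main()
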