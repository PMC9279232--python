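#!/usr/bin/env python
"""Generate the synthetic study: patients, reference populations, clinical
outcomes and ground truth.

Writes results/data/{patients,hc,external,clinical,truth_subjects,
truth_visits}.csv.  The cohort uses a reduced grid (4 gray-matter regions +
lesion volume, z-levels {1,2}) so every downstream script runs in minutes
on a laptop; the generator's full defaults (11 biomarkers, levels {1,2,3},
425 patients) are available by editing CONFIG below.
"""

from msstratify import (
    generate_clinical_outcomes,
    generate_longitudinal_visits,
    generate_patient_cohort,
    generate_reference_populations,
    write_biomarker_table,
    write_clinical_table,
)

from study_config import CONFIG, RESULTS, SEED

OUT = RESULTS / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    hc, external = generate_reference_populations(CONFIG, SEED)
    baseline, truth = generate_patient_cohort(CONFIG, SEED + 1)
    visits, truth = generate_longitudinal_visits(truth, CONFIG, SEED + 2)
    clinical = generate_clinical_outcomes(truth, CONFIG, SEED + 3)

    write_biomarker_table(visits, OUT / "patients.csv")
    write_biomarker_table(hc, OUT / "hc.csv")
    write_biomarker_table(external, OUT / "external.csv")
    write_clinical_table(clinical, OUT / "clinical.csv")
    truth.subjects.to_csv(OUT / "truth_subjects.csv", index=False)
    truth.visits.to_csv(OUT / "truth_visits.csv", index=False)

    n_visits = visits.n_visits
    print(f"simulated {CONFIG.n_patients} patients ({n_visits} MRI visits, "
          f"{n_visits / CONFIG.n_patients:.1f} per patient), "
          f"{CONFIG.n_hc} healthy controls, {CONFIG.n_external} external patients")
    print(f"two latent subtypes with fractions {CONFIG.fractions}, "
          f"stage rate {CONFIG.beta_time}/year, plateau {CONFIG.plateau}")
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
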