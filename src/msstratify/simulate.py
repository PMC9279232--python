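"""Synthetic cohorts with known subtypes, stages and outcomes.

The generator mirrors the fitted model's own generative assumptions so that
every pipeline stage can be exercised against ground truth: subjects carry
a latent subtype (with its event sequence) and a latent stage; observed
z-scores are the subtype trajectory value at the stage plus Gaussian noise;
raw volumes are reconstructed by inverting the z-scoring (healthy-control
norms for gray matter, an external patient population for lesion volume).
Longitudinal visits advance the latent stage linearly in time with a
subject-specific random slope and a plateau term (negative baseline-stage x
time interaction), and clinical outcomes are drawn from proportional-odds /
logistic models on stage, subtype, age, sex, follow-up time and therapy.

Defaults emulate the study conditions this pipeline targets: 425
relapsing-remitting MS patients with on average ~2.7 MRI visits each, 148
healthy controls, 80 external patients, 11 biomarkers (10 gray-matter
regions + total lesion volume), two subtypes with 60/40 mixing, ~0.2
stages/year progression with a -0.05 plateau coefficient.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import BiomarkerTable, ClinicalTable
from .sustain import EventGrid, expected_matrix, is_valid_sequence
from .zscore import ReferenceStats

DGM_REGIONS = ("thalamus_left", "thalamus_right", "putamen_right")
CORTICAL_REGIONS = (
    "insula_left",
    "insula_right",
    "cuneus_left",
    "cuneus_right",
    "cingulate_ant_left",
    "cingulate_ant_right",
    "cingulate_mid_right",
)
LESION = "tlv"

#: healthy-control raw-volume norms, mL (mean, SD)
HC_NORMS = {
    "thalamus_left": (7.5, 0.8),
    "thalamus_right": (7.4, 0.8),
    "putamen_right": (5.0, 0.6),
    "insula_left": (7.0, 0.8),
    "insula_right": (7.1, 0.8),
    "cuneus_left": (3.5, 0.5),
    "cuneus_right": (3.6, 0.5),
    "cingulate_ant_left": (4.2, 0.6),
    "cingulate_ant_right": (4.1, 0.6),
    "cingulate_mid_right": (4.0, 0.6),
}
#: external-patient lesion-volume norm, mL (mean, SD)
EXTERNAL_TLV = (3.4, 5.3)
#: healthy controls carry a small incidental lesion load
HC_TLV = (0.3, 0.4)


@dataclasses.dataclass
class SimulationConfig:
    """Ground-truth parameters of the synthetic study."""

    n_patients: int = 425
    n_hc: int = 148
    n_external: int = 80
    gm_biomarkers: tuple[str, ...] = DGM_REGIONS + CORTICAL_REGIONS
    dgm_biomarkers: tuple[str, ...] = DGM_REGIONS
    lesion_biomarker: str = LESION
    levels: tuple[float, ...] = (1.0, 2.0, 3.0)
    z_max: float = 5.0
    fractions: tuple[float, ...] = (0.6, 0.4)
    sigma_gen: float = 0.25
    # longitudinal dynamics (stages/year)
    beta_time: float = 0.2
    plateau: float = -0.05
    random_slope_sd: float = 0.1
    mean_extra_visits: float = 1.7
    # demographics
    age_mean: float = 35.9
    age_sd: float = 9.9
    prob_female: float = 0.708
    # long-term clinical follow-up (years)
    lt_fu_mean: float = 10.0
    lt_fu_sd: float = 2.0
    dmt_probs: tuple[float, ...] = (0.073, 0.787, 0.028, 0.112)
    outcome_blocks: dict = dataclasses.field(default_factory=lambda: default_outcome_blocks())

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions)
        if not np.isclose(f.sum(), 1.0) or np.any(f < 0):
            raise ValueError("fractions must lie on the simplex")
        if self.sigma_gen <= 0:
            raise ValueError("sigma_gen must be > 0")

    @property
    def biomarkers(self) -> tuple[str, ...]:
        return self.gm_biomarkers + (self.lesion_biomarker,)

    @property
    def cortical_biomarkers(self) -> tuple[str, ...]:
        return tuple(b for b in self.gm_biomarkers if b not in self.dgm_biomarkers)

    def grid(self) -> EventGrid:
        names = self.biomarkers
        return EventGrid(names, tuple(self.levels for _ in names), tuple(self.z_max for _ in names))

    def true_sequences(self) -> list[np.ndarray]:
        return default_sequences(self.grid(), self.dgm_biomarkers, self.cortical_biomarkers, self.lesion_biomarker)[
            : len(self.fractions)
        ]

    def reference_stats(self) -> ReferenceStats:
        """The generating norms as z-scoring stats (flip -1 for GM atrophy,
        +1 for lesion accrual)."""
        mean, sd, flip, refid = {}, {}, {}, {}
        for b in self.gm_biomarkers:
            mu, s = HC_NORMS.get(b, (5.0, 0.7))
            mean[b], sd[b], flip[b], refid[b] = mu, s, -1, "HC"
        mean[self.lesion_biomarker], sd[self.lesion_biomarker] = EXTERNAL_TLV
        flip[self.lesion_biomarker], refid[self.lesion_biomarker] = 1, "external_patients"
        return ReferenceStats(mean, sd, flip, refid)


def default_outcome_blocks() -> dict:
    """Generating coefficients for the clinical outcomes (latent-logistic
    proportional-odds blocks for ordinal outcomes, a logit block for the
    secondary-progressive transition)."""
    return {
        "baseline_edss": {
            "stage": 0.042, "subtype": -0.28, "subtype_x_stage": -0.012,
            "age": 0.033, "sex": -0.12,
            "thresholds": tuple(np.linspace(-2.5, 6.0, 20)),
            "levels": tuple(np.arange(0, 10.5, 0.5)),
        },
        "motor_disability_lt": {
            "stage": 0.030, "subtype": -0.06, "subtype_x_stage": -0.016,
            "age": 0.015, "sex": 0.0, "fu_time": -0.11, "dmt": 0.28,
            "thresholds": (1.2, 2.7, 4.0), "levels": (0, 1, 2, 3),
        },
        "cognitive_disability_lt": {
            "stage": 0.048, "subtype": -0.44, "subtype_x_stage": -0.08,
            "age": 0.001, "sex": 0.2, "fu_time": 0.11, "dmt": 0.09,
            "thresholds": (1.5, 2.5, 3.5), "levels": (0, 1, 2, 3),
        },
        "sp_transition": {
            "intercept": -4.5, "stage": 0.079, "subtype": 0.42, "subtype_x_stage": 0.044,
            "age": 0.095, "sex": -0.93, "fu_time": -0.30, "dmt": 0.57,
        },
    }


def default_sequences(
    grid: EventGrid,
    dgm: Sequence[str],
    cortical: Sequence[str],
    lesion: str,
) -> list[np.ndarray]:
    """Two mirrored orderings: DGM-first (deep gray matter events, then
    lesion accrual, then cortex, within each z-level tier) and cortex-first
    (the biomarker order reversed within tiers)."""
    def tier_sequence(order: Sequence[str]) -> np.ndarray:
        events = grid.events
        seq = []
        n_levels = max(len(lv) for lv in grid.levels)
        for tier in range(n_levels):
            for name in order:
                bi = grid.biomarkers.index(name)
                if tier < len(grid.levels[bi]):
                    ev = grid.event_indices_of(bi)[tier]
                    seq.append(int(ev))
        return np.array(seq, dtype=int)

    present = [b for b in grid.biomarkers]
    dgm = [b for b in dgm if b in present]
    cortical = [b for b in cortical if b in present]
    lesion_part = [lesion] if lesion in present else []
    s0 = tier_sequence(list(dgm) + lesion_part + list(cortical))
    s1 = tier_sequence(list(cortical) + lesion_part + list(dgm))
    assert is_valid_sequence(s0, grid) and is_valid_sequence(s1, grid)
    return [s0, s1]


@dataclasses.dataclass
class GroundTruth:
    """Latent state behind a generated cohort."""

    subjects: pd.DataFrame          # subject_id, true_subtype, true_baseline_stage, age_years, sex
    visits: pd.DataFrame            # subject_id, visit_index, years_from_baseline, true_stage
    sequences: list[np.ndarray]
    fractions: np.ndarray
    grid: EventGrid


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _meta_frame(ids, ages, sexes, visit_index=0, years=0.0) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": ids,
            "visit_index": visit_index,
            "years_from_baseline": years,
            "age_years": ages,
            "sex": sexes,
        }
    )


def generate_reference_populations(config: SimulationConfig, seed: int = 0) -> tuple[BiomarkerTable, BiomarkerTable]:
    """Healthy-control and external-patient raw-volume tables (one visit per
    subject).  HC gray matter follows the configured norms; the external
    table supplies the lesion-volume reference."""
    if config.n_hc < 2 or config.n_external < 2:
        raise ValueError("reference populations need >= 2 subjects")
    rng = np.random.default_rng(seed)
    stats = config.reference_stats()

    def draw(n, prefix, tlv_norm, gm_shift=0.0):
        ids = [f"{prefix}{i:04d}" for i in range(n)]
        ages = rng.normal(config.age_mean, config.age_sd, size=n).round(1)
        sexes = np.where(rng.random(n) < config.prob_female, "F", "M")
        df = _meta_frame(ids, ages, sexes)
        for b in config.gm_biomarkers:
            mu, s = stats.mean[b], stats.sd[b]
            df[b] = rng.normal(mu - gm_shift * s, s, size=n)
        df[config.lesion_biomarker] = rng.normal(tlv_norm[0], tlv_norm[1], size=n)
        return BiomarkerTable(df, scale="raw")

    hc = draw(config.n_hc, "HC", HC_TLV)
    external = draw(config.n_external, "EXT", EXTERNAL_TLV, gm_shift=0.5)
    return hc, external


def _raw_from_z(Z: np.ndarray, config: SimulationConfig) -> np.ndarray:
    stats = config.reference_stats()
    names = config.biomarkers
    mu = np.array([stats.mean[b] for b in names])
    sd = np.array([stats.sd[b] for b in names])
    fl = np.array([stats.flip[b] for b in names], dtype=float)
    # invert z = flip * (x - mu)/sd
    return mu + Z * sd / fl


def _z_at_stage(stages: np.ndarray, subtypes: np.ndarray, sequences, grid: EventGrid) -> np.ndarray:
    """Noise-free expected z for (possibly fractional) stages."""
    mats = [expected_matrix(s, grid) for s in sequences]
    support = np.arange(grid.n_events + 1, dtype=float)
    Z = np.empty((len(stages), grid.n_biomarkers))
    for c, E in enumerate(mats):
        mask = subtypes == c
        if mask.any():
            for bi in range(grid.n_biomarkers):
                Z[mask, bi] = np.interp(stages[mask], support, E[bi])
    return Z


def generate_patient_cohort(config: SimulationConfig, seed: int = 0) -> tuple[BiomarkerTable, GroundTruth]:
    """Baseline patient cohort on the raw scale.

    Subtype ~ categorical(fractions); baseline stage ~ uniform over 0..N;
    z = trajectory(stage) + Normal(0, sigma_gen); raw volumes invert the
    z-scoring against the generating norms.
    """
    rng = np.random.default_rng(seed)
    grid = config.grid()
    sequences = config.true_sequences()
    for s in sequences:
        if not is_valid_sequence(s, grid):
            raise ValueError("configured true sequence is invalid for the grid")
    n = config.n_patients
    subtypes = rng.choice(len(sequences), size=n, p=np.asarray(config.fractions))
    stages = rng.integers(0, grid.n_events + 1, size=n).astype(float)
    Z = _z_at_stage(stages, subtypes, sequences, grid) + rng.normal(0.0, config.sigma_gen, size=(n, grid.n_biomarkers))
    ids = [f"MS{i:04d}" for i in range(n)]
    ages = rng.normal(config.age_mean, config.age_sd, size=n).round(1)
    sexes = np.where(rng.random(n) < config.prob_female, "F", "M")
    df = _meta_frame(ids, ages, sexes)
    raw = _raw_from_z(Z, config)
    for j, b in enumerate(config.biomarkers):
        df[b] = raw[:, j]
    table = BiomarkerTable(df, scale="raw")
    subjects = pd.DataFrame(
        {
            "subject_id": ids,
            "true_subtype": subtypes,
            "true_baseline_stage": stages,
            "age_years": ages,
            "sex": sexes,
        }
    )
    visits = pd.DataFrame(
        {
            "subject_id": ids,
            "visit_index": 0,
            "years_from_baseline": 0.0,
            "true_stage": stages,
        }
    )
    truth = GroundTruth(subjects, visits, sequences, np.asarray(config.fractions), grid)
    return table, truth


def generate_longitudinal_visits(
    truth: GroundTruth,
    config: SimulationConfig,
    seed: int = 0,
) -> tuple[BiomarkerTable, GroundTruth]:
    """Multi-visit raw table: latent stage advances as
    k(t) = clip(k0 + (beta_time + plateau*k0 + subject slope) * t, 0, N),
    with visit counts ~ 1 + Poisson(mean_extra_visits) and ~yearly spacing;
    biomarker values are regenerated from the latent stage."""
    rng = np.random.default_rng(seed)
    grid, sequences = truth.grid, truth.sequences
    n_events = grid.n_events
    rows, vrows = [], []
    slopes = rng.normal(0.0, config.random_slope_sd, size=len(truth.subjects))
    for i, subj in truth.subjects.iterrows():
        k0 = float(subj["true_baseline_stage"])
        n_extra = int(rng.poisson(config.mean_extra_visits))
        times = np.concatenate([[0.0], np.cumsum(rng.uniform(0.6, 1.4, size=n_extra))])
        rate = config.beta_time + config.plateau * k0 + slopes[i]
        stages = np.clip(k0 + rate * times, 0.0, float(n_events))
        subtype = np.full(len(times), int(subj["true_subtype"]))
        Z = _z_at_stage(stages, subtype, sequences, grid)
        Z = Z + rng.normal(0.0, config.sigma_gen, size=Z.shape)
        raw = _raw_from_z(Z, config)
        for v, t in enumerate(times):
            row = {
                "subject_id": subj["subject_id"],
                "visit_index": v,
                "years_from_baseline": float(t),
                "age_years": float(subj["age_years"]) + float(t),
                "sex": subj["sex"],
            }
            row.update({b: raw[v, j] for j, b in enumerate(config.biomarkers)})
            rows.append(row)
            vrows.append(
                {
                    "subject_id": subj["subject_id"],
                    "visit_index": v,
                    "years_from_baseline": float(t),
                    "true_stage": float(stages[v]),
                }
            )
    table = BiomarkerTable(pd.DataFrame(rows), scale="raw")
    subjects = truth.subjects.copy()
    subjects["true_slope"] = slopes
    new_truth = GroundTruth(subjects, pd.DataFrame(vrows), sequences, truth.fractions, grid)
    return table, new_truth


def generate_clinical_outcomes(
    truth: GroundTruth,
    config: SimulationConfig,
    seed: int = 0,
) -> ClinicalTable:
    """Clinical table drawn from the configured coefficient blocks.

    Ordinal outcomes come from a latent-logistic proportional-odds model on
    (stage, subtype, subtype x stage, age, sex [+ follow-up time, DMT]);
    the SP transition from the logit block.  Subtype enters with the
    DGM-first = 0 / cortex-first = 1 coding.
    """
    rng = np.random.default_rng(seed)
    subj = truth.subjects
    n = len(subj)
    stage = subj["true_baseline_stage"].to_numpy(float)
    subtype = subj["true_subtype"].to_numpy(float)
    age = subj["age_years"].to_numpy(float)
    sex = (subj["sex"] == "M").astype(float).to_numpy()
    fu = rng.normal(config.lt_fu_mean, config.lt_fu_sd, size=n)
    dmt = rng.choice(4, size=n, p=np.asarray(config.dmt_probs)).astype(float)

    def linpred(block, with_lt):
        eta = (
            block["stage"] * stage
            + block["subtype"] * subtype
            + block["subtype_x_stage"] * subtype * stage
            + block["age"] * age
            + block["sex"] * sex
        )
        if with_lt:
            eta = eta + block["fu_time"] * fu + block["dmt"] * dmt
        return eta

    def draw_ordinal(block, with_lt):
        missing = [k for k in ("stage", "subtype", "subtype_x_stage", "age", "sex") if k not in block]
        if missing:
            raise ValueError(f"coefficient block missing terms: {missing}")
        latent = linpred(block, with_lt) + rng.logistic(0.0, 1.0, size=n)
        codes = np.searchsorted(np.asarray(block["thresholds"]), latent)
        return np.asarray(block["levels"])[codes]

    blocks = config.outcome_blocks
    edss = draw_ordinal(blocks["baseline_edss"], with_lt=False)
    motor = draw_ordinal(blocks["motor_disability_lt"], with_lt=True)
    cognitive = draw_ordinal(blocks["cognitive_disability_lt"], with_lt=True)
    sp_block = blocks["sp_transition"]
    eta_sp = sp_block["intercept"] + linpred(sp_block, with_lt=True)
    sp = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta_sp))).astype(int)

    return ClinicalTable(
        pd.DataFrame(
            {
                "subject_id": subj["subject_id"],
                "baseline_edss": edss,
                "motor_disability_lt": motor,
                "cognitive_disability_lt": cognitive,
                "sp_transition": sp,
                "dmt_code": dmt.astype(int),
                "fu_time_years": fu,
            }
        )
    )


def generate_feature_selection_cohort(
    seed: int = 0,
    n_ms: int = 425,
    n_hc: int = 148,
    n_regions: int = 116,
    n_strong: int = 10,
    effect_sd: float = 1.2,
) -> tuple[BiomarkerTable, BiomarkerTable, list[str]]:
    """A wide cohort for exercising effect-size selection: ``n_regions``
    gray-matter columns of which ``n_strong`` carry a true MS-vs-HC shift of
    ``effect_sd`` reference SDs, plus an elevated lesion volume.  Returns
    (MS table, HC table, names of the truly affected columns + lesion)."""
    rng = np.random.default_rng(seed)
    regions = [f"gm_region_{i:03d}" for i in range(n_regions)]
    strong = list(rng.choice(regions, size=n_strong, replace=False))

    def build(n, prefix, shifted):
        ids = [f"{prefix}{i:04d}" for i in range(n)]
        ages = rng.normal(36.0, 10.0, size=n).round(1)
        sexes = np.where(rng.random(n) < 0.6, "F", "M")
        cols = {}
        for r in regions:
            mu, s = 5.0, 0.7
            shift = effect_sd * s if (shifted and r in strong) else 0.0
            cols[r] = rng.normal(mu - shift, s, size=n)
        tlv_mu = 10.0 if shifted else 0.3
        cols[LESION] = np.abs(rng.normal(tlv_mu, 5.0 if shifted else 0.4, size=n))
        df = pd.concat([_meta_frame(ids, ages, sexes), pd.DataFrame(cols)], axis=1)
        return BiomarkerTable(df, scale="raw")

    ms = build(n_ms, "MS", shifted=True)
    hc = build(n_hc, "HC", shifted=False)
    return ms, hc, strong + [LESION]
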