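"""Reference-normalized z-scoring and effect-size feature selection.

Raw regional gray-matter volumes are referenced to a healthy-control (HC)
population; total lesion volume is referenced to an external patient
population (healthy controls carry essentially no lesion load, so an HC
reference would be degenerate).  Signs are flipped so that a *higher*
z-score always means *worse* disease: atrophy-type biomarkers (volume loss
is pathological) get flip = -1, lesion volume (accrual is pathological)
gets flip = +1.

Feature selection keeps biomarkers whose patient-vs-control difference has
Cohen's f strictly above a threshold (default 0.25, i.e. at least a
moderate effect), with lesion volume always retained.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import BiomarkerTable, ValidationError


@dataclasses.dataclass
class ReferenceStats:
    """Per-biomarker reference mean/SD, direction flip and reference id."""

    mean: dict[str, float]
    sd: dict[str, float]
    flip: dict[str, int]
    reference_id: dict[str, str]

    def __post_init__(self) -> None:
        for b, s in self.sd.items():
            if not s > 0:
                raise ValidationError(f"reference SD for {b!r} must be > 0 (got {s})")
        for b, f in self.flip.items():
            if f not in (-1, 1):
                raise ValidationError(f"flip for {b!r} must be +1 or -1")

    @property
    def biomarkers(self) -> list[str]:
        return list(self.mean)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "biomarker": self.biomarkers,
                "mean": [self.mean[b] for b in self.biomarkers],
                "sd": [self.sd[b] for b in self.biomarkers],
                "flip": [self.flip[b] for b in self.biomarkers],
                "reference_id": [self.reference_id[b] for b in self.biomarkers],
            }
        )


def fit_reference_stats(
    reference: BiomarkerTable,
    biomarkers: Sequence[str] | None = None,
    flip: Mapping[str, int] | int = -1,
    reference_id: str = "HC",
) -> ReferenceStats:
    """Sample mean and SD (n-1 denominator) per biomarker from a reference
    population's baseline visits.

    ``flip`` may be a single value applied to every biomarker or a mapping.
    A zero-variance biomarker raises (its z-scores would be undefined).
    """
    base = reference.baseline()
    names = list(biomarkers) if biomarkers is not None else base.biomarkers
    if base.n_subjects < 2:
        raise ValidationError("reference population needs >= 2 subjects")
    mean, sd, flips, refids = {}, {}, {}, {}
    for b in names:
        x = base.df[b].dropna().to_numpy(dtype=float)
        if len(x) < 2:
            raise ValidationError(f"biomarker {b!r}: fewer than 2 reference observations")
        s = float(np.std(x, ddof=1))
        if s == 0.0:
            raise ValidationError(f"biomarker {b!r}: zero variance in reference population")
        mean[b] = float(np.mean(x))
        sd[b] = s
        flips[b] = int(flip[b] if isinstance(flip, Mapping) else flip)
        refids[b] = reference_id
    return ReferenceStats(mean, sd, flips, refids)


def combine_reference_stats(*parts: ReferenceStats) -> ReferenceStats:
    """Merge disjoint per-biomarker stats (e.g. HC for GM, external for TLV)."""
    mean, sd, flip, refid = {}, {}, {}, {}
    for p in parts:
        overlap = set(mean) & set(p.mean)
        if overlap:
            raise ValidationError(f"biomarkers mapped to more than one reference: {sorted(overlap)}")
        mean.update(p.mean)
        sd.update(p.sd)
        flip.update(p.flip)
        refid.update(p.reference_id)
    return ReferenceStats(mean, sd, flip, refid)


def apply_zscore(table: BiomarkerTable, stats: ReferenceStats) -> BiomarkerTable:
    """z = flip * (x - mean) / sd per biomarker; missing stays missing."""
    if table.scale != "raw":
        raise ValidationError("apply_zscore expects a raw-scale table")
    names = table.biomarkers
    missing = [b for b in names if b not in stats.mean]
    if missing:
        raise ValidationError(f"no reference stats for biomarkers: {missing}")
    X = table.values(names)
    mu = np.array([stats.mean[b] for b in names])
    sig = np.array([stats.sd[b] for b in names])
    fl = np.array([stats.flip[b] for b in names], dtype=float)
    Z = fl * (X - mu) / sig
    return table.with_values(Z, names, scale="zscore")


# ---------------------------------------------------------------------------
# effect sizes
# ---------------------------------------------------------------------------

def cohens_f(
    ms_values: np.ndarray,
    hc_values: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> float:
    """Cohen's f for the patient-vs-control group effect.

    f = sqrt(eta_p^2 / (1 - eta_p^2)) where eta_p^2 is the partial eta
    squared of the group factor in a linear model, optionally adjusted for
    covariates (rows: MS observations first, then HC).  Without covariates
    this is the classical one-way-ANOVA f.
    """
    x = np.asarray(ms_values, dtype=float)
    y = np.asarray(hc_values, dtype=float)
    keep_x, keep_y = ~np.isnan(x), ~np.isnan(y)
    x, y = x[keep_x], y[keep_y]
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("cohens_f needs >= 2 observations per group")
    values = np.concatenate([x, y])
    group = np.concatenate([np.ones(len(x)), np.zeros(len(y))])

    if covariates is None:
        C = np.ones((len(values), 1))
    else:
        cov = np.asarray(covariates, dtype=float)
        keep = np.concatenate([keep_x, keep_y])
        if len(cov) != len(keep):
            raise ValidationError("covariate rows must match ms+hc observations")
        cov = cov[keep]
        C = np.column_stack([np.ones(len(values)), cov])

    # partial eta^2 via nested least squares: reduced (covariates only)
    # vs full (covariates + group)
    full = np.column_stack([C, group])
    rss_red = _rss(C, values)
    rss_full = _rss(full, values)
    if rss_full <= 1e-12 * max(1.0, rss_red):
        raise ValidationError("zero residual variance: Cohen's f is infinite")
    eta_p = (rss_red - rss_full) / rss_red
    eta_p = min(max(eta_p, 0.0), 1.0 - 1e-15)
    return float(np.sqrt(eta_p / (1.0 - eta_p)))


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


@dataclasses.dataclass
class FeatureSelectionReport:
    """Per-biomarker effect size and selection flag."""

    table: pd.DataFrame  # columns: biomarker, cohens_f, selected, always_included
    threshold: float

    @property
    def selected(self) -> list[str]:
        return self.table.loc[self.table["selected"], "biomarker"].tolist()


def select_biomarkers(
    ms_baseline: BiomarkerTable,
    hc: BiomarkerTable,
    threshold: float = 0.25,
    always_include: Sequence[str] = (),
    covariates: tuple[pd.DataFrame, pd.DataFrame] | None = None,
) -> FeatureSelectionReport:
    """Keep biomarkers with Cohen's f strictly above ``threshold`` in the
    MS-baseline vs HC comparison; ``always_include`` names (lesion volume)
    are kept regardless of their effect size.
    """
    ms = ms_baseline.baseline()
    hcb = hc.baseline()
    common = [b for b in ms.biomarkers if b in hcb.biomarkers]
    rows = []
    for b in common:
        if covariates is None:
            f = cohens_f(ms.df[b].to_numpy(float), hcb.df[b].to_numpy(float))
        else:
            cov = pd.concat([covariates[0], covariates[1]], ignore_index=True)
            f = cohens_f(ms.df[b].to_numpy(float), hcb.df[b].to_numpy(float), covariates=cov)
        always = b in always_include
        rows.append({"biomarker": b, "cohens_f": f, "selected": (f > threshold) or always, "always_included": always})
    for b in always_include:
        if b not in common and b in ms.biomarkers:
            rows.append({"biomarker": b, "cohens_f": np.nan, "selected": True, "always_included": True})
    report = pd.DataFrame(rows)
    if not report["selected"].any():
        raise ValidationError("feature selection kept no biomarkers")
    return FeatureSelectionReport(report, threshold)
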