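"""Cox models, the subnetwork risk score, and survival stratification.

The prognostic model is a multivariate Cox proportional-hazards fit with
the per-sample subnetwork activity scores as continuous covariates; the
risk score of a sample is the linear predictor

    risk = sum_i SS_i * beta_i

over subnetworks, with the betas frozen once fitted. The cohort is split at
the median risk score (score > median -> high risk, <= median -> low), and
high vs low survival is compared with Kaplan-Meier curves and the two-group
log-rank test. External cohorts reuse the frozen betas; only the median is
recomputed within the new cohort.

Partial-likelihood fitting, product-limit estimation and the log-rank test
are delegated to lifelines (Efron handling of tied event times); the risk
score, stratification and validation logic live here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from subnetmark.data_io import ClinicalTable, ValidationError
from subnetmark.scoring import SubnetworkScoreMatrix

logger = logging.getLogger(__name__)

#: Published multivariate Cox coefficients of a 15-subnetwork colorectal
#: cancer risk model, rounded to one decimal. Shipped as a reference fixture
#: for worked examples (an all-ones score vector gives a risk score of -5.4).
CRC15_RISK_BETAS = (
    -1.4, -1.1, -1.3, -1.4, -1.0, 1.2, 1.0, -1.2, 1.1, 1.0, -1.2, 1.0, -1.2, 1.0, -1.9,
)

#: Clinical covariate -> (column, level coded 1); reference level coded 0.
CLINICAL_CONTRASTS = {
    "age_group": ">=50",
    "gender": "female",
    "stage_group": "III-IV",
    "lymphatic_invasion": "yes",
}


@dataclass
class CoxFit:
    """One covariate's estimate from a Cox proportional-hazards model."""

    covariate: str
    beta: float
    hr: float
    ci95: tuple[float, float]
    p_value: float
    model_tag: str  # "univariate" | "multivariate"


@dataclass
class RiskModel:
    """Frozen per-subnetwork Cox coefficients plus the training median."""

    subnetwork_ids: list[int]
    betas: list[float]
    threshold: float

    def __post_init__(self) -> None:
        if len(self.subnetwork_ids) != len(self.betas):
            raise ValidationError("subnetwork_ids and betas lengths differ")
        if not np.isfinite(self.threshold):
            raise ValidationError("threshold must be finite")


@dataclass
class KMResult:
    """Per-group product-limit curves plus the log-rank comparison."""

    curves: dict[str, pd.DataFrame]  # columns: time, at_risk, survival
    chi_square: float
    df: int
    p_value: float


def encode_clinical(clinical: ClinicalTable) -> pd.DataFrame:
    """0/1 design columns for the available clinical contrasts (NaN kept)."""
    out = pd.DataFrame(index=clinical.data.index)
    for column, one_level in CLINICAL_CONTRASTS.items():
        if column in clinical.data.columns:
            values = clinical.data[column]
            out[column] = np.where(
                values.isna(), np.nan, (values == one_level).astype(float)
            )
    return out


def cox_fit(
    clinical: ClinicalTable,
    covariates: pd.DataFrame | None = None,
    mode: str = "multivariate",
) -> list[CoxFit]:
    """Cox proportional-hazards estimates with Wald 95% CIs.

    ``covariates`` is a samples x covariates design frame (defaults to the
    encoded clinical contrasts). ``mode="multivariate"`` fits one joint
    model; ``mode="univariate"`` fits each covariate alone. Rows with
    missing covariate values are dropped per model. Ties are handled with
    the Efron approximation.
    """
    if mode not in ("univariate", "multivariate"):
        raise ValueError(f"unknown mode {mode!r}")
    design = encode_clinical(clinical) if covariates is None else covariates
    if design.shape[1] == 0:
        raise ValidationError("no covariates to fit")
    base = clinical.data[["time", "event"]].join(design, how="inner")
    if base["event"].sum() == 0:
        raise ValidationError("no events observed; Cox model is not estimable")

    if mode == "multivariate":
        return _fit_one(base, list(design.columns), "multivariate")
    fits: list[CoxFit] = []
    for name in design.columns:
        fits.extend(_fit_one(base[["time", "event", name]], [name], "univariate"))
    return fits


def _fit_one(frame: pd.DataFrame, names: list[str], tag: str) -> list[CoxFit]:
    frame = frame.dropna()
    for name in names:
        if frame[name].nunique() < 2:
            raise ValidationError(f"covariate {name!r} is constant (non-identifiable)")
    fitter = CoxPHFitter()
    try:
        fitter.fit(frame, duration_col="time", event_col="event")
    except Exception as exc:
        raise ValidationError(
            f"Cox fit failed for {names} (separation or degenerate data): {exc}"
        ) from exc
    summary = fitter.summary
    fits = []
    for name in names:
        row = summary.loc[name]
        fits.append(
            CoxFit(
                covariate=str(name),
                beta=float(row["coef"]),
                hr=float(np.exp(row["coef"])),
                ci95=(
                    float(np.exp(row["coef lower 95%"])),
                    float(np.exp(row["coef upper 95%"])),
                ),
                p_value=float(row["p"]),
                model_tag=tag,
            )
        )
    return fits


def build_risk_model(
    scores: SubnetworkScoreMatrix, clinical: ClinicalTable
) -> tuple[RiskModel, list[CoxFit]]:
    """Fit the multivariate Cox of subnetwork scores and freeze the betas.

    The model threshold is the median training risk score, the cut used for
    high/low stratification.
    """
    design = scores.scores.T.copy()  # samples x subnetworks
    design.columns = [f"SS{i}" for i in scores.subnetwork_ids]
    shared = design.index.intersection(clinical.data.index)
    if len(shared) < design.shape[1] + 2:
        raise ValidationError(
            f"too few samples with both scores and outcomes ({len(shared)})"
        )
    fits = cox_fit(clinical, design.loc[shared], mode="multivariate")
    betas = [f.beta for f in fits]
    model = RiskModel(
        subnetwork_ids=list(scores.subnetwork_ids), betas=betas, threshold=0.0
    )
    risk = risk_score(scores, model)
    model.threshold = float(np.median(risk.loc[shared]))
    return model, fits


def risk_score(scores: SubnetworkScoreMatrix, model: RiskModel) -> pd.Series:
    """Per-sample weighted sum of subnetwork scores, sum_i SS_i * beta_i."""
    missing = set(model.subnetwork_ids) - set(scores.subnetwork_ids)
    if missing:
        raise ValidationError(f"score matrix missing subnetworks {sorted(missing)}")
    aligned = scores.scores.loc[model.subnetwork_ids]
    values = np.asarray(model.betas) @ aligned.to_numpy()
    return pd.Series(values, index=aligned.columns, name="risk_score")


def stratify_median(risk: pd.Series) -> tuple[dict[str, str], float]:
    """Median split: score > median -> "high", <= median -> "low".

    Samples tied with the median go to the low group. All-identical scores
    cannot be stratified and raise an error.
    """
    if len(risk) < 2:
        raise ValidationError("need >=2 samples to stratify")
    if risk.nunique() == 1:
        raise ValidationError("degenerate stratification: all risk scores identical")
    threshold = float(np.median(risk.to_numpy()))
    groups = {s: ("high" if v > threshold else "low") for s, v in risk.items()}
    return groups, threshold


def km_logrank(clinical: ClinicalTable, groups: dict[str, str]) -> KMResult:
    """Kaplan-Meier curves per group and the two-group log-rank test."""
    samples = [s for s in clinical.sample_ids if s in groups]
    if not samples:
        raise ValidationError("no overlap between clinical table and groups")
    frame = clinical.data.loc[samples, ["time", "event"]].copy()
    frame["group"] = [groups[s] for s in samples]
    present = sorted(frame["group"].unique())
    if len(present) < 2:
        raise ValidationError(f"need two non-empty groups, got {present}")
    if frame["event"].sum() == 0:
        raise ValidationError("no events in either group")

    curves: dict[str, pd.DataFrame] = {}
    for name, sub in frame.groupby("group"):
        km = KaplanMeierFitter()
        km.fit(sub["time"], sub["event"])
        table = km.event_table
        curves[name] = pd.DataFrame(
            {
                "time": table.index.to_numpy(),
                "at_risk": table["at_risk"].to_numpy(),
                "survival": km.survival_function_["KM_estimate"].to_numpy(),
            }
        )
    test = multivariate_logrank_test(frame["time"], frame["group"], frame["event"])
    return KMResult(
        curves=curves,
        chi_square=float(test.test_statistic),
        df=int(test.degrees_of_freedom),
        p_value=float(test.p_value),
    )


def external_validation(
    scores_ext: SubnetworkScoreMatrix,
    model: RiskModel,
    clinical_ext: ClinicalTable,
) -> KMResult:
    """Validate a frozen risk model on an independent cohort.

    Risk scores use the training betas unchanged; the median split is
    recomputed within the external cohort (platform scales differ), then
    KM + log-rank compare the groups.
    """
    risk = risk_score(scores_ext, model)
    groups, threshold = stratify_median(risk)
    logger.info("external validation: median threshold %.4f", threshold)
    return km_logrank(clinical_ext, groups)
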