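"""Structure volumes, normative Z-scores, QC exclusion, composites.

Raw measures (label-field volumes in mm^3 and region grading scores) are
turned into covariate-adjusted Z-scores against a normative model fitted on
cognitively healthy subjects only:

    Z = (raw - predicted(covariates)) / residual SD,

with the residual SD taken from the degrees-of-freedom-corrected OLS fit.
Volumes adjust for age, sex and estimated intracranial volume; grading
scores for age and sex. Grading Z-scores are sign-flipped by default so
that, like the volume Z-scores, *negative means more AD-like* — raw
grading increases toward AD (group tag 2) while volumes decrease.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from snipegrade.phantom import STRUCTURE_CODES

#: covariates used per measure family
VOLUME_COVARIATES = ["age", "sex_male", "icv_mm3"]
GRADING_COVARIATES = ["age", "sex_male"]

MIN_TRAINING_N = 20


class CollinearityError(ValueError):
    """Raised when the normative design matrix is rank deficient."""


@dataclass
class NormativeModel:
    """Per-measure linear adjustment model trained on CN subjects."""

    measure: str
    covariates: list[str]
    params: pd.Series  # intercept + slopes
    resid_sd: float
    n_train: int
    bse: pd.Series | None = None
    train_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def predict(self, covariates: dict | pd.Series) -> float:
        x = [1.0] + [float(covariates[c]) for c in self.covariates]
        return float(np.dot(self.params.to_numpy(), x))


@dataclass
class AdjustedScore:
    measure: str
    raw: float
    z: float
    flipped: bool  # True -> sign convention flipped so negative = AD-like


def region_volume(
    labels: np.ndarray, structure: str, voxel_size: float = 1.0
) -> float:
    """Structure volume in mm^3 = voxel count x voxel volume."""
    if structure not in STRUCTURE_CODES:
        raise KeyError(f"unknown structure {structure!r}")
    labels = np.asarray(labels)
    return float((labels == STRUCTURE_CODES[structure]).sum()) * voxel_size**3


def _design(table: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    df = table.copy()
    if "sex_male" in covariates and "sex_male" not in df:
        df["sex_male"] = (df["sex"] == "M").astype(float)
    x = df[covariates].astype(float)
    return sm.add_constant(x, has_constant="add")


def fit_normative(
    training: pd.DataFrame,
    measures: list[str],
    covariates_by_measure: dict[str, list[str]] | None = None,
) -> dict[str, NormativeModel]:
    """OLS normative fit per measure on a CN training table.

    The table must contain the measures and covariate columns (``sex`` is
    expanded to a male indicator). Requires at least 20 training subjects
    and a full-rank design; on rank deficiency the offending columns are
    named.
    """
    n = len(training)
    if n < MIN_TRAINING_N:
        raise ValueError(
            f"normative fit needs >= {MIN_TRAINING_N} CN subjects, got {n}"
        )
    models: dict[str, NormativeModel] = {}
    for measure in measures:
        covs = (covariates_by_measure or {}).get(
            measure, GRADING_COVARIATES if measure.startswith("grading") else VOLUME_COVARIATES
        )
        x = _design(training, covs)
        rank = np.linalg.matrix_rank(x.to_numpy())
        if rank < x.shape[1]:
            bad = [
                c
                for c in x.columns
                if c != "const"
                and np.linalg.matrix_rank(x.drop(columns=c).to_numpy()) == rank
            ]
            raise CollinearityError(
                f"rank-deficient normative design for {measure}: "
                f"collinear covariates {bad or list(x.columns)}"
            )
        y = training[measure].astype(float)
        if y.isna().any():
            raise ValueError(f"missing values in training measure {measure}")
        fit = sm.OLS(y, x).fit()
        resid_sd = float(np.sqrt(fit.ssr / fit.df_resid))
        if resid_sd <= 0:
            raise ValueError(f"zero residual spread for measure {measure}")
        models[measure] = NormativeModel(
            measure=measure,
            covariates=covs,
            params=fit.params,
            resid_sd=resid_sd,
            n_train=n,
            bse=fit.bse,
            train_ranges={
                c: (float(x[c].min()), float(x[c].max()))
                for c in covs
            },
        )
    return models


def z_adjust(
    raw: float,
    covariates: dict | pd.Series,
    model: NormativeModel,
    flip_sign: bool = False,
) -> AdjustedScore:
    """Covariate-adjusted Z-score; ``flip_sign`` negates it (grading
    convention: negative = more AD-like)."""
    cov = dict(covariates)
    if "sex_male" in model.covariates and "sex_male" not in cov:
        cov["sex_male"] = 1.0 if cov.get("sex") == "M" else 0.0
    for c in model.covariates:
        if c not in cov or pd.isna(cov[c]):
            raise KeyError(f"missing covariate {c!r}")
        lo, hi = model.train_ranges.get(c, (-np.inf, np.inf))
        if not lo <= float(cov[c]) <= hi:
            warnings.warn(
                f"covariate {c}={cov[c]} outside the normative training "
                f"range [{lo:.3g}, {hi:.3g}]; extrapolating",
                stacklevel=2,
            )
    z = (float(raw) - model.predict(cov)) / model.resid_sd
    if flip_sign:
        z = -z
    return AdjustedScore(measure=model.measure, raw=float(raw), z=z, flipped=flip_sign)


def qc_exclude(
    estimated: np.ndarray,
    reference: np.ndarray,
    structure: str,
    threshold: int = 100,
) -> tuple[bool, int]:
    """Segmentation QC: count voxels where exactly one of the two label
    fields carries the structure; exclude at >= ``threshold`` discrepant
    voxels (the "omission of ~100 voxels or more" rule)."""
    estimated = np.asarray(estimated)
    reference = np.asarray(reference)
    if estimated.shape != reference.shape:
        raise ValueError("label fields live on different grids")
    code = STRUCTURE_CODES[structure]
    count = int(((estimated == code) != (reference == code)).sum())
    return count >= threshold, count


def composite_score(
    scores: dict[str, AdjustedScore] | dict[str, float],
    recipe: str,
    excluded: set[str] | None = None,
) -> float:
    """Composite Z per recipe.

    * ``mean_all`` — mean over all provided region Z-scores (one modality);
    * ``mean_bilateral_snipe`` — mean of the four grading Z-scores
      (bilateral HPC + EC);
    * ``combined`` — mean of the atrophy composite and the grading
      composite, which must be supplied as ``atrophy`` and ``snipe`` keys.

    Scores must share the direction convention; any excluded region in the
    input set is an error.
    """
    excluded = excluded or set()
    vals = {
        k: (v.z if isinstance(v, AdjustedScore) else float(v))
        for k, v in scores.items()
    }
    if not vals:
        raise ValueError("empty score set")
    bad = excluded & set(vals)
    if bad:
        raise ValueError(f"excluded regions present in composite input: {sorted(bad)}")
    if recipe == "mean_all":
        return float(np.mean(list(vals.values())))
    if recipe == "mean_bilateral_snipe":
        names = [k for k in vals if "HPC" in k or "EC" in k]
        if len(names) != 4:
            raise ValueError(f"expected the 4 bilateral HPC/EC scores, got {names}")
        return float(np.mean([vals[k] for k in names]))
    if recipe == "combined":
        if set(vals) != {"atrophy", "snipe"}:
            raise ValueError("combined recipe needs 'atrophy' and 'snipe' composites")
        return float((vals["atrophy"] + vals["snipe"]) / 2.0)
    raise ValueError(f"unknown recipe {recipe!r}")


def adjust_cohort(
    table: pd.DataFrame,
    models: dict[str, NormativeModel],
    flip_measures: set[str] | None = None,
) -> pd.DataFrame:
    """Apply z_adjust to every (subject, measure); returns a tidy frame
    with columns subject_id, measure, raw, z, flipped."""
    flip_measures = flip_measures or set()
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # cohort covariates may extrapolate
        for _, row in table.iterrows():
            for measure, model in models.items():
                adj = z_adjust(
                    row[measure], row, model, flip_sign=measure in flip_measures
                )
                rows.append(
                    {
                        "subject_id": row["subject_id"],
                        "measure": measure,
                        "raw": adj.raw,
                        "z": adj.z,
                        "flipped": adj.flipped,
                    }
                )
    return pd.DataFrame(rows)
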