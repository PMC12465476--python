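"""Diagnostic modelling of the transplant cohort.

One row per patient-biopsy pair: biopsy outcome labels (rejection and its
subtype; any histological lesion), clinical covariates (eGFR,
donor-specific antibodies, collection tube type) and the per-marker
cfDNA methylation levels expressed as a percentage of the albumin
internal control.

The modelling surface follows the Model / Results idiom: a
:class:`DiagnosticModel` is built from a cohort table and
``fit()`` returns a :class:`DiagnosticResults` carrying coefficients,
odds ratios with Wald 95% confidence intervals and p-values, and a
``summary()`` table.  Higher-level operations — the per-predictor
univariate screen, the epigenetic signature (a logistic score over the
markers univariately associated with the outcome), ROC/AUC and the
standard model comparison (clinical + signature vs clinical vs signature
alone) — are functions built on those two objects.

Marker levels are right-skewed with zeros, so they enter models as
log10(x + delta) with delta defaulting to half the smallest nonzero level
of that marker.  All reported AUCs are apparent (in-sample); k-fold
cross-validation is available but off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ModelConfig",
    "DiagnosticModel",
    "DiagnosticResults",
    "SignatureModel",
    "ROCResult",
    "fit_logistic",
    "univariate_screen",
    "build_signature",
    "roc_auc",
    "compare_models",
    "cross_validated_auc",
    "transform_marker",
    "read_cohort",
    "write_cohort",
    "COHORT_COLUMNS",
]

REJECTION_SUBTYPES = ("ABMR", "TCMR", "mixed", "none")
TUBE_TYPES = ("EDTA", "PAXgene")

COHORT_COLUMNS = [
    "patient_id", "tube_type", "biopsy_context", "rejection",
    "rejection_subtype", "any_banff_lesion", "egfr", "dsa",
]


@dataclass(frozen=True)
class ModelConfig:
    """Fitting options shared across the diagnostic models."""

    alpha: float = 0.05                  # univariate-screen significance level
    delta: float | None = None           # log10 offset; None -> half min nonzero
    maxiter: int = 100
    tol: float = 1e-8
    separation_threshold: float = 15.0   # |coef| beyond this flags separation
    egfr_per_10: bool = True             # additionally report OR per 10 units


class SeparationWarningError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Cohort table I/O
# ---------------------------------------------------------------------------

def validate_cohort(df: pd.DataFrame, marker_columns: Sequence[str] | None = None) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing column(s): {missing}")
    bad = df.loc[df["rejection"].astype(bool) & (df["rejection_subtype"] == "none")]
    if len(bad):
        raise ValueError(
            f"rejection without subtype for patient(s): {list(bad['patient_id'])[:5]}"
        )
    bad = df.loc[~df["rejection"].astype(bool) & (df["rejection_subtype"] != "none")]
    if len(bad):
        raise ValueError(
            f"subtype without rejection for patient(s): {list(bad['patient_id'])[:5]}"
        )
    if (df["egfr"] <= 0).any():
        raise ValueError("egfr must be positive")
    if marker_columns:
        absent = [m for m in marker_columns if m not in df.columns]
        if absent:
            raise ValueError(f"marker column(s) absent: {absent}")


def read_cohort(path: str | Path, marker_columns: Sequence[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    for col in ("rejection", "any_banff_lesion", "dsa"):
        df[col] = df[col].astype(int).astype(bool)
    validate_cohort(df, marker_columns)
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col in ("rejection", "any_banff_lesion", "dsa"):
        out[col] = out[col].astype(int)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Predictor transforms
# ---------------------------------------------------------------------------

def transform_marker(x: pd.Series | np.ndarray, delta: float | None = None) -> np.ndarray:
    """log10(x + delta); delta defaults to half the smallest nonzero level."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("marker levels must be non-negative")
    if delta is None:
        nonzero = arr[arr > 0]
        if len(nonzero) == 0:
            raise ValueError("all marker levels zero: transform undefined")
        delta = float(nonzero.min()) / 2.0
    if delta == 0 and np.any(arr == 0):
        raise ValueError("delta=0 with zero levels: log undefined")
    return np.log10(arr + delta)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class DiagnosticModel:
    """Logistic model of a binary biopsy outcome on clinical + marker predictors.

    Parameters
    ----------
    data
        Cohort table, one row per patient-biopsy.
    outcome
        Boolean/0-1 column name (e.g. ``rejection`` or ``any_banff_lesion``).
    predictors
        Columns entering untransformed (booleans are cast to 0/1).
    marker_predictors
        Columns entering as log10(x + delta).
    config
        Fitting options.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str,
        predictors: Sequence[str] = (),
        marker_predictors: Sequence[str] = (),
        config: ModelConfig | None = None,
    ) -> None:
        self.config = config or ModelConfig()
        self.outcome = outcome
        self.predictors = list(predictors)
        self.marker_predictors = list(marker_predictors)
        if not self.predictors and not self.marker_predictors:
            raise ValueError("no predictors given")

        cols = [outcome] + self.predictors + self.marker_predictors
        df = data[cols].dropna()
        self.n_used = len(df)
        y = df[outcome].astype(float).to_numpy()
        if y.sum() < 1 or (1 - y).sum() < 1:
            raise ValueError(
                f"outcome {outcome!r} needs at least one event and one non-event"
            )
        X = pd.DataFrame(index=df.index)
        self.marker_deltas: dict[str, float] = {}
        for c in self.predictors:
            X[c] = df[c].astype(float)
        for c in self.marker_predictors:
            delta = self.config.delta
            if delta is None:
                nz = df[c][df[c] > 0]
                if len(nz) == 0:
                    raise ValueError(f"marker {c!r}: all levels zero")
                delta = float(nz.min()) / 2.0
            self.marker_deltas[c] = delta
            X[f"log10_{c}"] = transform_marker(df[c], delta)
        const = [c for c in X.columns if X[c].nunique() <= 1]
        if const:
            raise ValueError(f"constant predictor(s): {const}")
        self._y = y
        self._X = sm.add_constant(X, has_constant="add")

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        outcome: str,
        predictors: Sequence[str] = (),
        marker_predictors: Sequence[str] = (),
        config: ModelConfig | None = None,
    ) -> "DiagnosticModel":
        return cls(data, outcome, predictors, marker_predictors, config)

    @property
    def exog_names(self) -> list[str]:
        return list(self._X.columns)

    def fit(self) -> "DiagnosticResults":
        """Maximum-likelihood fit (Newton/IRLS, tol on parameter change)."""
        import warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        model = sm.Logit(self._y, self._X)
        converged = True
        separation_warned = False
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                res = model.fit(
                    method="newton",
                    maxiter=self.config.maxiter,
                    tol=self.config.tol,
                    disp=0,
                    warn_convergence=False,
                )
                converged = bool(res.mle_retvals.get("converged", True))
            except Exception:
                # fall back to BFGS for hard cases (near-separation)
                res = model.fit(method="bfgs", maxiter=500, disp=0)
                converged = bool(res.mle_retvals.get("converged", False))
        separation_warned = any(
            issubclass(w.category, PerfectSeparationWarning) for w in caught
        )
        thr = self.config.separation_threshold
        slope_names = [n for n in self.exog_names if n != "const"]
        separated = [n for n in slope_names if abs(res.params[n]) > thr]
        if separation_warned and not separated:
            separated = slope_names
        return DiagnosticResults(
            model=self,
            _smres=res,
            converged=converged and not separated,
            separated_predictors=separated,
        )


@dataclass
class DiagnosticResults:
    """Fitted diagnostic logistic model.

    Coefficients, Wald standard errors and p-values come from the
    maximum-likelihood fit; odds ratios are exp(coefficient) with 95%
    confidence intervals.  When quasi-complete separation is detected
    (a slope beyond the configured threshold) the fit is flagged
    unreliable and interval estimates are suppressed.
    """

    model: DiagnosticModel
    _smres: object
    converged: bool
    separated_predictors: list[str]

    # -- estimates ---------------------------------------------------------
    @property
    def params(self) -> pd.Series:
        return pd.Series(self._smres.params, index=self.model.exog_names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self._smres.bse, index=self.model.exog_names)

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(self._smres.pvalues, index=self.model.exog_names)

    @property
    def llf(self) -> float:
        return float(self._smres.llf)

    @property
    def n_used(self) -> int:
        return self.model.n_used

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.params)

    def or_conf_int(self) -> pd.DataFrame:
        """95% CI on the odds ratios (NaN when separation was flagged)."""
        ci = np.exp(pd.DataFrame(
            np.asarray(self._smres.conf_int()),
            index=self.model.exog_names,
            columns=["ci95_low", "ci95_high"],
        ))
        for name in self.separated_predictors:
            ci.loc[name] = np.nan
        return ci

    # -- scoring -----------------------------------------------------------
    def _design(self, data: pd.DataFrame | None) -> pd.DataFrame:
        if data is None:
            return self.model._X
        X = pd.DataFrame(index=data.index)
        for c in self.model.predictors:
            X[c] = data[c].astype(float)
        for c in self.model.marker_predictors:
            X[f"log10_{c}"] = transform_marker(data[c], self.model.marker_deltas[c])
        return sm.add_constant(X, has_constant="add")[self.model.exog_names]

    def linear_score(self, data: pd.DataFrame | None = None) -> np.ndarray:
        """Linear predictor (log-odds) per record."""
        X = self._design(data)
        return X.to_numpy() @ self.params.to_numpy()

    def predict(self, data: pd.DataFrame | None = None) -> np.ndarray:
        """Predicted outcome probability per record."""
        return 1.0 / (1.0 + np.exp(-self.linear_score(data)))

    def roc(self, data: pd.DataFrame | None = None) -> "ROCResult":
        if data is None:
            y = self.model._y.astype(bool)
            s = self.linear_score(None)
        else:
            y = data[self.model.outcome].astype(bool).to_numpy()
            s = self.linear_score(data)
        return roc_auc(s, y)

    # -- reporting ---------------------------------------------------------
    def table(self) -> pd.DataFrame:
        ci = self.or_conf_int()
        tab = pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "odds_ratio": self.odds_ratios,
                "or_ci95_low": ci["ci95_low"],
                "or_ci95_high": ci["ci95_high"],
                "p_value": self.pvalues,
            }
        )
        return tab

    def summary(self) -> str:
        lines = [
            f"Diagnostic logistic model: outcome = {self.model.outcome}",
            f"n = {self.n_used}, log-likelihood = {self.llf:.3f}, "
            f"converged = {self.converged}",
        ]
        if self.separated_predictors:
            lines.append(
                "WARNING: possible complete separation for "
                f"{self.separated_predictors}; estimates unreliable, CIs suppressed"
            )
        tab = self.table()
        lines.append(tab.to_string(float_format=lambda v: f"{v:.4g}"))
        if self.config_reports_egfr_per_10():
            orow = self.params.get("egfr")
            if orow is not None:
                or10 = math.exp(10 * orow)
                lines.append(f"eGFR odds ratio per 10 mL/min/1.73m2: {or10:.3f}")
        return "\n".join(lines)

    def config_reports_egfr_per_10(self) -> bool:
        return self.model.config.egfr_per_10 and "egfr" in self.model.exog_names


def fit_logistic(
    records: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str] = (),
    marker_predictors: Sequence[str] = (),
    config: ModelConfig | None = None,
) -> DiagnosticResults:
    """Functional wrapper: build a :class:`DiagnosticModel` and fit it."""
    return DiagnosticModel(records, outcome, predictors, marker_predictors, config).fit()


# ---------------------------------------------------------------------------
# Univariate screen & signature
# ---------------------------------------------------------------------------

def univariate_screen(
    records: pd.DataFrame,
    outcome: str,
    candidates: Sequence[str],
    marker_candidates: Sequence[str] = (),
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """One single-predictor logistic fit per candidate; table sorted by p.

    Raw (uncorrected) p-values, as conventional for exploratory biomarker
    association tables.  Per-predictor failures are recorded in the table's
    ``error`` column, never fatal.
    """
    rows = []
    all_c = [(c, False) for c in candidates] + [(c, True) for c in marker_candidates]
    for name, is_marker in all_c:
        row: dict = {"predictor": name, "is_marker": is_marker}
        try:
            res = fit_logistic(
                records, outcome,
                predictors=() if is_marker else (name,),
                marker_predictors=(name,) if is_marker else (),
                config=config,
            )
            coef_name = f"log10_{name}" if is_marker else name
            ci = res.or_conf_int()
            row.update(
                odds_ratio=res.odds_ratios[coef_name],
                or_ci95_low=ci.loc[coef_name, "ci95_low"],
                or_ci95_high=ci.loc[coef_name, "ci95_high"],
                p_value=res.pvalues[coef_name],
                n_used=res.n_used,
                converged=res.converged,
                error="",
            )
        except Exception as exc:  # recorded in-table
            row.update(
                odds_ratio=np.nan, or_ci95_low=np.nan, or_ci95_high=np.nan,
                p_value=np.nan, n_used=np.nan, converged=False, error=str(exc),
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values("p_value", na_position="last").reset_index(drop=True)


@dataclass
class SignatureModel:
    """Epigenetic signature: a logistic score over the selected markers.

    Members are the markers univariately associated with the outcome at
    level alpha; coefficients come from one joint logistic fit of the
    members only.  The score is the fitted linear predictor.
    """

    members: list[str]
    intercept: float
    coefficients: pd.Series       # indexed log10_<marker>
    deltas: dict[str, float]
    outcome: str
    alpha: float
    fit: DiagnosticResults

    def score(self, data: pd.DataFrame) -> np.ndarray:
        s = np.full(len(data), self.intercept, dtype=float)
        for m in self.members:
            s += self.coefficients[f"log10_{m}"] * transform_marker(
                data[m], self.deltas[m]
            )
        return s


def build_signature(
    records: pd.DataFrame,
    outcome: str,
    markers: Sequence[str],
    alpha: float = 0.05,
    config: ModelConfig | None = None,
) -> SignatureModel:
    """Select markers with univariate p < alpha and fit the joint score.

    alpha = 1.0 includes every marker (the "include-all" variant).
    """
    screen = univariate_screen(records, outcome, (), markers, config)
    ok = screen[(screen["error"] == "") & (screen["p_value"] < alpha)]
    members = [m for m in markers if m in set(ok["predictor"])]
    if not members:
        raise ValueError(
            f"no marker univariately associated with {outcome!r} at alpha={alpha}; "
            "consider a signature-free model"
        )
    res = fit_logistic(records, outcome, marker_predictors=members, config=config)
    params = res.params
    return SignatureModel(
        members=members,
        intercept=float(params["const"]),
        coefficients=params.drop("const"),
        deltas=dict(res.model.marker_deltas),
        outcome=outcome,
        alpha=alpha,
        fit=res,
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    """ROC curve (threshold sweep over unique scores) and its AUC.

    The AUC is computed by Mann-Whitney pair counting with ties counted
    one half; it equals the trapezoidal area of the stored curve.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> ROCResult:
    """ROC by threshold sweep; AUC by rank (Mann-Whitney) statistics."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC needs both classes present")

    # Mann-Whitney with ties counted 1/2 via midranks
    from scipy.stats import rankdata

    ranks = rankdata(s)
    auc = (ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    # operating points: predict positive when score >= threshold
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    uniq_mask = np.append(np.diff(s_sorted) != 0, True)
    tp = np.cumsum(y_sorted)[uniq_mask]
    fp = np.cumsum(~y_sorted)[uniq_mask]
    thresholds = np.concatenate(([np.inf], s_sorted[uniq_mask]))
    sens = np.concatenate(([0.0], tp / n1))
    spec = np.concatenate(([1.0], 1.0 - fp / n0))
    return ROCResult(
        thresholds=thresholds, sensitivity=sens, specificity=spec, auc=float(auc)
    )


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

@dataclass
class ModelComparison:
    """Apparent AUCs of the standard predictor combinations."""

    outcome: str
    aucs: dict[str, float]
    curves: dict[str, ROCResult]
    fits: dict[str, DiagnosticResults]
    signature: SignatureModel | None

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"model": list(self.aucs), "auc": list(self.aucs.values())}
        )


def compare_models(
    records: pd.DataFrame,
    outcome: str,
    markers: Sequence[str],
    config: ModelConfig | None = None,
    signature_alpha: float = 0.05,
) -> ModelComparison:
    """Fit and compare the standard diagnostic models in-sample.

    Always: (a) eGFR + DSA + signature, (b) eGFR + DSA, (c) signature
    alone.  For the any-lesion outcome additionally (d) all markers joint
    and (e) DSA alone.
    """
    cfg = config or ModelConfig()
    signature = build_signature(records, outcome, markers, signature_alpha, cfg)
    data = records.copy()
    data["signature_score"] = signature.score(records)

    fits: dict[str, DiagnosticResults] = {}
    fits["egfr_dsa_signature"] = fit_logistic(
        data, outcome, predictors=("egfr", "dsa", "signature_score"), config=cfg
    )
    fits["egfr_dsa"] = fit_logistic(data, outcome, predictors=("egfr", "dsa"), config=cfg)
    fits["signature"] = fit_logistic(
        data, outcome, predictors=("signature_score",), config=cfg
    )
    if outcome == "any_banff_lesion":
        fits["markers_only"] = fit_logistic(
            data, outcome, marker_predictors=markers, config=cfg
        )
        fits["dsa_only"] = fit_logistic(data, outcome, predictors=("dsa",), config=cfg)

    y = data[outcome].astype(bool).to_numpy()
    curves = {
        name: roc_auc(res.linear_score(data), y) for name, res in fits.items()
    }
    aucs = {name: c.auc for name, c in curves.items()}
    return ModelComparison(
        outcome=outcome, aucs=aucs, curves=curves, fits=fits, signature=signature
    )


def cross_validated_auc(
    records: pd.DataFrame,
    outcome: str,
    predictors: Sequence[str] = (),
    marker_predictors: Sequence[str] = (),
    k: int = 5,
    seed: int = 0,
    config: ModelConfig | None = None,
) -> float:
    """Optional k-fold cross-validated AUC (pooled out-of-fold scores)."""
    rng = np.random.default_rng(seed)
    n = len(records)
    idx = rng.permutation(n)
    folds = np.array_split(idx, k)
    scores = np.full(n, np.nan)
    data = records.reset_index(drop=True)
    for fold in folds:
        train = data.drop(index=fold)
        res = fit_logistic(train, outcome, predictors, marker_predictors, config)
        scores[fold] = res.linear_score(data.iloc[fold])
    y = data[outcome].astype(bool).to_numpy()
    return roc_auc(scores, y).auc
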