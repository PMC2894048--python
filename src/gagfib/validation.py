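"""Robustness tests of the predictive model: subsampling bootstrap and jackknife.

The bootstrap here is repeated random subsampling without replacement: each
replicate partitions the dataset into a training set of 2/3 of the entries and
a disjoint test set of the remaining 1/3 (26/13 for a 39-entry table), refits
the predictive-equation specification on the training set, predicts the test
set, and records the Pearson correlation between predicted and observed G.
The jackknife refits on every leave-one-out subset and regresses the n
out-of-sample predictions on the observed values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DatasetEntry, entries_to_frame
from .exceptions import InsufficientDataError, SingularDesignError
from .multivariate import PREDICTIVE_SPEC, ModelSpec, build_design, ols_fit

__all__ = [
    "BootstrapReplicate",
    "ValidationReport",
    "bootstrap_validate",
    "jackknife_validate",
    "prediction_report",
]

MAX_REDRAWS = 100


@dataclass
class BootstrapReplicate:
    """One training/test split with its fit and out-of-sample correlation."""

    train_index: np.ndarray
    test_index: np.ndarray
    training_model_p: float
    test_r: float
    test_p: float


@dataclass
class ValidationReport:
    """Summary of a bootstrap or jackknife validation run."""

    method: str
    replicates: list[BootstrapReplicate] = field(default_factory=list)
    mean_R: float | None = None
    se_R: float | None = None
    n_redraws: int = 0
    # jackknife / prediction-report fields
    predicted: np.ndarray | None = None
    observed: np.ndarray | None = None
    r: float | None = None
    r2: float | None = None
    p: float | None = None
    slope: float | None = None
    intercept: float | None = None
    residual_mean: float | None = None
    residual_sd: float | None = None


def _design_all(entries, spec: ModelSpec):
    X, y = build_design(entries, spec)
    return X, y


def bootstrap_validate(
    entries: Sequence[DatasetEntry] | pd.DataFrame,
    spec: ModelSpec = PREDICTIVE_SPEC,
    n_rep: int = 100,
    train_frac: float = 2.0 / 3.0,
    seed: int = 0,
) -> ValidationReport:
    """Repeated 2/3–1/3 subsampling validation of the model specification.

    Each replicate draws a training set of ``round(n * train_frac)`` entries
    without replacement (26 of 39 at the defaults), fits ``spec`` on it, and
    correlates the predictions on the disjoint test set with the observed G.
    The report carries the per-replicate records and the mean ± standard error
    of the test-set Pearson coefficients. Replicates with a singular training
    design are redrawn (counted in ``n_redraws``).
    """
    X, y = _design_all(entries, spec)
    n = len(y)
    n_train = int(round(n * train_frac))
    k = X.shape[1]
    if n_train < k + 2:
        raise InsufficientDataError(
            f"training size {n_train} too small for {k} parameters"
        )
    rng = np.random.default_rng(seed)
    Xv = X.to_numpy(float)
    yv = y.to_numpy(float)
    reps: list[BootstrapReplicate] = []
    redraws = 0
    while len(reps) < n_rep:
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        try:
            if np.linalg.matrix_rank(Xv[tr]) < k:
                raise SingularDesignError("singular training design")
            beta, *_ = np.linalg.lstsq(Xv[tr], yv[tr], rcond=None)
            fit = ols_fit(X.iloc[tr], yv[tr], spec=spec)
        except SingularDesignError:
            redraws += 1
            if redraws > MAX_REDRAWS:
                raise
            continue
        pred = Xv[te] @ beta
        if np.ptp(pred) == 0 or np.ptp(yv[te]) == 0:
            redraws += 1
            if redraws > MAX_REDRAWS:
                raise SingularDesignError("degenerate test set: constant values")
            continue
        r, p = stats.pearsonr(pred, yv[te])
        reps.append(
            BootstrapReplicate(
                train_index=tr, test_index=te,
                training_model_p=fit.model_p,
                test_r=float(r), test_p=float(p),
            )
        )
    rs = np.array([rep.test_r for rep in reps])
    return ValidationReport(
        method="bootstrap",
        replicates=reps,
        mean_R=float(rs.mean()),
        se_R=float(rs.std(ddof=1) / np.sqrt(len(rs))),
        n_redraws=redraws,
    )


def jackknife_validate(
    entries: Sequence[DatasetEntry] | pd.DataFrame,
    spec: ModelSpec = PREDICTIVE_SPEC,
) -> ValidationReport:
    """Leave-one-out validation: n refits, n out-of-sample predictions.

    The summary is the R² (and p) of the ordinary regression of predicted on
    observed G, matching how leave-one-out scatter plots are usually analysed,
    not the squared correlation around a forced identity line.
    """
    X, y = _design_all(entries, spec)
    n, k = X.shape
    if n < k + 3:
        raise InsufficientDataError(f"n = {n} too small for {k} parameters + 3")
    Xv, yv = X.to_numpy(float), y.to_numpy(float)
    predicted = np.full(n, np.nan)
    for i in range(n):
        keep = np.arange(n) != i
        if np.linalg.matrix_rank(Xv[keep]) < k:
            continue  # prediction stays missing for this entry
        beta, *_ = np.linalg.lstsq(Xv[keep], yv[keep], rcond=None)
        predicted[i] = Xv[i] @ beta
    ok = np.isfinite(predicted)
    if ok.sum() < 3:
        raise InsufficientDataError("fewer than 3 jackknife predictions succeeded")
    res = stats.linregress(yv[ok], predicted[ok])
    return ValidationReport(
        method="jackknife",
        predicted=predicted,
        observed=yv,
        r=float(res.rvalue),
        r2=float(res.rvalue**2),
        p=float(res.pvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
    )


def prediction_report(
    entries: Sequence[DatasetEntry] | pd.DataFrame,
    model,
) -> ValidationReport:
    """Predicted-versus-observed regression and residuals for a fitted model.

    ``model`` is a :class:`gagfib.multivariate.PredictiveModel`; predictions
    use only the sulfation state, solute molarity and protein:GAG molar ratio.
    """
    frame = entries if isinstance(entries, pd.DataFrame) else entries_to_frame(entries)
    observed = frame["G"].to_numpy(float)
    predicted = model.predict(
        frame["sulfates_per_disaccharide"].to_numpy(float),
        frame["solute_molarity"].to_numpy(float),
        frame["protein_gag_molar_ratio"].to_numpy(float),
    )
    ok = np.isfinite(predicted) & np.isfinite(observed)
    if ok.sum() < 3:
        raise InsufficientDataError("fewer than 3 complete entries to compare")
    res = stats.linregress(observed[ok], predicted[ok])
    residuals = observed[ok] - predicted[ok]
    return ValidationReport(
        method="prediction",
        predicted=predicted,
        observed=observed,
        r=float(res.rvalue),
        r2=float(res.rvalue**2),
        p=float(res.pvalue),
        slope=float(res.slope),
        intercept=float(res.intercept),
        residual_mean=float(residuals.mean()),
        residual_sd=float(residuals.std(ddof=1)),
    )
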