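"""Model/Results facade for the GAG-acceleration analysis.

:class:`GagAccelerationModel` is built from a curated entry table (a list of
:class:`~gagfib.data_model.DatasetEntry`, a flattened DataFrame, or a TSV
file); ``fit()`` returns a :class:`GagAccelerationResults` carrying the
coefficient estimates, their standard errors and p-values, the fit diagnostics
(adjusted R², overall F, VIF, Breusch–Pagan), and ``summary()``. Validation
(bootstrap, jackknife), prediction and plotting hang off the results object.

Example
-------
>>> from gagfib import GagAccelerationModel, load_demo_dataset
>>> model = GagAccelerationModel(load_demo_dataset())
>>> res = model.fit()            # the linear-quadratic predictive equation
>>> res.params["sulfates_per_disaccharide"]  # doctest: +SKIP
0.3...
>>> print(res.summary())         # doctest: +SKIP
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import univariate, validation
from .data_model import DatasetEntry, dataset_summary, entries_to_frame, load_dataset
from .multivariate import (
    PREDICTIVE_SPEC,
    ModelSpec,
    PredictiveModel,
    RegressionFit,
    build_design,
    ols_fit,
    optimal_molar_ratio,
    select_model,
)

__all__ = ["GagAccelerationModel", "GagAccelerationResults"]


class GagAccelerationModel:
    """Regression model of the GAG acceleration statistic G on its descriptors."""

    def __init__(
        self,
        data: Sequence[DatasetEntry] | pd.DataFrame,
        spec: ModelSpec = PREDICTIVE_SPEC,
    ):
        self.entries = None if isinstance(data, pd.DataFrame) else list(data)
        self.data = data if isinstance(data, pd.DataFrame) else entries_to_frame(data)
        self.spec = spec

    @classmethod
    def from_tsv(cls, path: str | Path, spec: ModelSpec = PREDICTIVE_SPEC) -> "GagAccelerationModel":
        return cls(load_dataset(path), spec=spec)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, spec: ModelSpec = PREDICTIVE_SPEC) -> "GagAccelerationModel":
        return cls(frame, spec=spec)

    def fit(self, spec: ModelSpec | None = None) -> "GagAccelerationResults":
        """Ordinary least squares on the configured specification."""
        spec = spec or self.spec
        X, y = build_design(self.data, spec)
        return GagAccelerationResults(self, ols_fit(X, y, spec=spec))

    def fit_selected(
        self, universe: ModelSpec | None = None,
        method: Literal["best_subset", "stepwise"] = "best_subset",
    ) -> "GagAccelerationResults":
        """Model selection under the five acceptance criteria, then fit."""
        fit, spec = select_model(self.data, universe, method=method)
        return GagAccelerationResults(self, fit)

    # light-weight passthroughs used by the CLI ---------------------------
    def correlate(self, x_variable: str, **kw) -> univariate.CorrelationResult:
        return univariate.correlate(self.data, x_variable, **kw)

    def summary_counts(self) -> dict:
        return dataset_summary(self.entries) if self.entries is not None else {
            "n_entries": len(self.data),
            "n_proteins": self.data["protein"].nunique(),
            "n_gags": self.data["gag"].nunique(),
        }


class GagAccelerationResults:
    """Fitted coefficients, diagnostics and downstream analyses."""

    def __init__(self, model: GagAccelerationModel, fit: RegressionFit):
        self.model = model
        self.fit = fit

    # statsmodels-flavoured accessors -------------------------------------
    @property
    def params(self) -> pd.Series:
        return self.fit.params

    @property
    def bse(self) -> pd.Series:
        return self.fit.bse

    @property
    def pvalues(self) -> pd.Series:
        return self.fit.pvalues

    @property
    def rsquared(self) -> float:
        return self.fit.r2

    @property
    def rsquared_adj(self) -> float:
        return self.fit.r2_adj

    @property
    def f_pvalue(self) -> float:
        return self.fit.model_p

    @property
    def resid(self) -> np.ndarray:
        return self.fit.residuals

    def as_predictive_model(self) -> PredictiveModel:
        """The coefficient set of the linear-quadratic predictive equation."""
        return PredictiveModel.from_fit(self.fit)

    def predict(self, P_S, P_B, P_MR):
        return self.as_predictive_model().predict(P_S, P_B, P_MR)

    def optimal_molar_ratio(self, P_S: float = 0.0, P_B: float = 0.0):
        return optimal_molar_ratio(self.as_predictive_model(), P_S, P_B)

    # validation -----------------------------------------------------------
    def bootstrap(self, n_rep: int = 100, seed: int = 0) -> validation.ValidationReport:
        return validation.bootstrap_validate(
            self.model.data, self.fit.spec, n_rep=n_rep, seed=seed
        )

    def jackknife(self) -> validation.ValidationReport:
        return validation.jackknife_validate(self.model.data, self.fit.spec)

    def prediction_report(self) -> validation.ValidationReport:
        return validation.prediction_report(self.model.data, self.as_predictive_model())

    # presentation ----------------------------------------------------------
    def summary(self) -> str:
        f = self.fit
        ok, failures = f.meets_criteria()
        lines = [
            "GAG acceleration model (OLS)",
            "=" * 64,
            f"n = {f.nobs}    R2 = {f.r2:.3f}    adj R2 = {f.r2_adj:.3f}    "
            f"model p = {f.model_p:.3g}",
            f"Breusch-Pagan p = {f.heteroscedasticity_p:.3f}    "
            f"criteria: {'all met' if ok else '; '.join(failures)}",
            "-" * 64,
            f"{'term':<32}{'coef':>10}{'se':>9}{'p':>10}{'VIF':>6}",
        ]
        for name in f.params.index:
            vif = f.vif.get(name, float("nan"))
            vif_s = f"{vif:>6.1f}" if np.isfinite(vif) else "     -"
            lines.append(
                f"{name:<32}{f.params[name]:>10.4g}{f.bse[name]:>9.3g}"
                f"{f.pvalues[name]:>10.2g}{vif_s}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)

    def plot_prediction(self, ax=None):
        """Predicted-vs-observed G scatter with the line of best fit."""
        import matplotlib.pyplot as plt

        report = self.prediction_report()
        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4.5))
        obs, pred = report.observed, report.predicted
        ax.scatter(obs, pred, s=22, color="#30509c", alpha=0.8)
        xs = np.linspace(np.nanmin(obs), np.nanmax(obs), 50)
        ax.plot(xs, report.intercept + report.slope * xs, color="k", lw=1)
        ax.set_xlabel("observed G")
        ax.set_ylabel("predicted G")
        ax.set_title(f"r = {report.r:.2f}, p = {report.p:.1e}")
        return ax

    def plot_residuals(self, ax=None):
        """Residuals against observed G, with the residual mean marked."""
        import matplotlib.pyplot as plt

        report = self.prediction_report()
        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 3.2))
        resid = report.observed - report.predicted
        ax.scatter(report.observed, resid, s=22, color="#9c3050", alpha=0.8)
        ax.axhline(np.nanmean(resid), color="k", lw=1)
        ax.set_xlabel("observed G")
        ax.set_ylabel("observed - predicted")
        return ax
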