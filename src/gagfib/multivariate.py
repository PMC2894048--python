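"""Multivariate regression of G: design building, OLS diagnostics, model selection.

G is regressed on descriptors of the GAG, the protein and the experimental
conditions. Candidate designs may contain dummy-coded dichotomous descriptors,
interaction terms involving at least one dummy, and quadratic terms for
continuous descriptors (a square may only enter together with its linear term).
A model is *acceptable* when it satisfies five criteria simultaneously:

1. every non-intercept coefficient significant (p < 0.05),
2. the overall model significant (F-test p < 0.05),
3. adjusted R² as close to 1 as possible (the selection objective),
4. no collinearity (all variance inflation factors below 10, flagged above 5),
5. homoscedastic residuals (Breusch–Pagan p > 0.05).

The selected specification on the curated database is the linear–quadratic
predictive equation

    G = y0 + a·P_S + b·P_B + c·P_MR + c'·P_MR²

with P_S the sulfates per disaccharide unit, P_B the total solute molarity in
mM and P_MR the protein:GAG molar ratio.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .data_model import DatasetEntry, encode_dummies, entries_to_frame
from .exceptions import DomainError, NoModelError, SingularDesignError

__all__ = [
    "ModelSpec",
    "RegressionFit",
    "PredictiveModel",
    "PREDICTIVE_SPEC",
    "CONTINUOUS_PREDICTORS",
    "DUMMY_VARIABLES",
    "build_design",
    "ols_fit",
    "select_model",
    "predict_G",
    "optimal_molar_ratio",
    "default_candidate_universe",
]

#: continuous descriptors available as predictors of G
CONTINUOUS_PREDICTORS = [
    "sulfates_per_disaccharide",   # P_S
    "charges_per_disaccharide",
    "gag_molecular_weight",
    "protein_length",
    "protein_net_charge",
    "protein_lys_arg",
    "solute_molarity",             # P_B
    "protein_gag_molar_ratio",     # P_MR
]

#: dichotomous descriptors recoded into dummies
DUMMY_VARIABLES = [
    "uronic_acid",
    "sulfation_position",
    "folding_status",
    "disease_related",
]

VIF_REJECT = 10.0
VIF_FLAG = 5.0
COEF_ALPHA = 0.05
MODEL_ALPHA = 0.05
BP_ALPHA = 0.05


@dataclass
class ModelSpec:
    """Which columns enter a candidate design.

    ``predictors`` are continuous descriptor names or dummy columns
    (``"variable=level"``); ``interactions`` are (dummy, other) pairs, at least
    one member a dummy; ``quadratics`` lists continuous predictors whose square
    is added (only together with the linear term).
    """

    predictors: list[str] = field(default_factory=list)
    interactions: list[tuple[str, str]] = field(default_factory=list)
    quadratics: list[str] = field(default_factory=list)

    def validate(self) -> None:
        for q in self.quadratics:
            if "=" in q:
                raise DomainError(f"quadratic term for dummy column {q!r} not allowed")
            if q not in self.predictors:
                raise DomainError(
                    f"quadratic of {q!r} requires its linear term in the spec"
                )
        for a, b in self.interactions:
            if "=" not in a and "=" not in b:
                raise DomainError(
                    f"interaction ({a!r}, {b!r}) must involve at least one dummy"
                )

    def column_names(self) -> list[str]:
        cols = list(self.predictors)
        cols += [f"{q}^2" for q in self.quadratics]
        cols += [f"{a}:{b}" for a, b in self.interactions]
        return cols


#: the published predictive-equation specification
PREDICTIVE_SPEC = ModelSpec(
    predictors=[
        "sulfates_per_disaccharide",
        "solute_molarity",
        "protein_gag_molar_ratio",
    ],
    quadratics=["protein_gag_molar_ratio"],
)


@dataclass
class RegressionFit:
    """An OLS fit with the diagnostics the acceptance criteria use."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    r2: float
    r2_adj: float
    model_p: float
    vif: pd.Series
    #: VIF after excluding each column's own polynomial partners (x vs x^2, a
    #: term vs its interaction). Collinearity between *different* descriptors
    #: is a modelling defect; the structural collinearity of a variable with
    #: its own square is inherent to a quadratic fit and is not penalized.
    vif_between_variables: pd.Series
    residuals: np.ndarray
    fitted: np.ndarray
    heteroscedasticity_p: float
    nobs: int

    @property
    def coef_names(self) -> list[str]:
        return [c for c in self.params.index if c != "const"]

    def meets_criteria(self) -> tuple[bool, list[str]]:
        """Check the five model-acceptance criteria; returns (ok, failures)."""
        failures = []
        bad = [c for c in self.coef_names if self.pvalues[c] >= COEF_ALPHA]
        if bad:
            failures.append(f"coefficients not significant: {bad}")
        if not self.model_p < MODEL_ALPHA:
            failures.append(f"model p = {self.model_p:.3g} >= {MODEL_ALPHA}")
        high = self.vif_between_variables[self.vif_between_variables >= VIF_REJECT]
        if len(high):
            failures.append(f"VIF >= {VIF_REJECT}: {dict(high.round(1))}")
        if not self.heteroscedasticity_p > BP_ALPHA:
            failures.append(
                f"Breusch-Pagan p = {self.heteroscedasticity_p:.3g} <= {BP_ALPHA}"
            )
        return (not failures, failures)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
                "vif": self.vif.reindex(self.params.index),
            }
        )


def build_design(
    entries: Sequence[DatasetEntry] | pd.DataFrame,
    spec: ModelSpec,
    dropna: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble the design matrix (with intercept) and the G response vector.

    Dummy columns come from :func:`gagfib.data_model.encode_dummies`; quadratic
    columns are raw squares; entries missing any needed predictor are dropped
    (pairwise-complete analysis). Columns appear in deterministic order:
    intercept, predictors as listed, squares, interactions.
    """
    spec.validate()
    frame = entries if isinstance(entries, pd.DataFrame) else entries_to_frame(entries)
    dummy_vars = sorted(
        {name.split("=", 1)[0] for name in _dummy_names(spec)}
    )
    dummies = encode_dummies(frame, dummy_vars) if dummy_vars else pd.DataFrame(index=frame.index)

    cols: dict[str, np.ndarray] = {}
    for name in spec.predictors:
        cols[name] = _column(frame, dummies, name)
    for q in spec.quadratics:
        cols[f"{q}^2"] = _column(frame, dummies, q) ** 2
    for a, b in spec.interactions:
        cols[f"{a}:{b}"] = _column(frame, dummies, a) * _column(frame, dummies, b)

    X = pd.DataFrame(cols, index=frame.index)
    y = frame["G"].astype(float)
    if dropna:
        keep = X.notna().all(axis=1) & y.notna()
        X, y = X[keep], y[keep]
    if len(X) == 0:
        raise SingularDesignError("every entry lacks at least one required predictor")
    X = sm.add_constant(X, prepend=True, has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy(float)) < X.shape[1]:
        raise SingularDesignError(
            f"design with columns {list(X.columns)} is rank deficient"
        )
    return X, y


def _dummy_names(spec: ModelSpec) -> list[str]:
    names = [p for p in spec.predictors if "=" in p]
    for a, b in spec.interactions:
        names += [t for t in (a, b) if "=" in t]
    return names


def _column(frame: pd.DataFrame, dummies: pd.DataFrame, name: str) -> np.ndarray:
    if "=" in name:
        if name not in dummies.columns:
            raise SingularDesignError(f"dummy column {name!r} not present in data")
        return dummies[name].to_numpy(float)
    if name not in frame.columns:
        raise SingularDesignError(f"predictor {name!r} not present in data")
    return frame[name].to_numpy(float)


def ols_fit(design: pd.DataFrame, y: pd.Series | np.ndarray,
            spec: ModelSpec | None = None) -> RegressionFit:
    """Ordinary least squares with SEs, overall F, adjusted R², VIF and BP test.

    ``design`` must contain a ``const`` column (as produced by
    :func:`build_design`) and have full column rank.
    """
    X = design
    yv = np.asarray(y, float)
    n, k = X.shape
    if n <= k:
        raise SingularDesignError(f"n = {n} observations for {k} columns")
    Xv = X.to_numpy(float)
    if np.linalg.matrix_rank(Xv) < k:
        raise SingularDesignError("rank-deficient design")
    res = sm.OLS(yv, Xv).fit()

    names = list(X.columns)
    non_const = [i for i, c in enumerate(names) if c != "const"]

    def _bases(col: str) -> set[str]:
        return {part.split("=", 1)[0] for part in col.replace("^2", "").split(":")}

    vif_vals = {}
    vif_between = {}
    for i in non_const:
        vif_vals[names[i]] = (
            1.0 if len(non_const) == 1 else float(variance_inflation_factor(Xv, i))
        )
        # VIF against columns of *other* variables only: drop the column's own
        # polynomial/interaction partners before regressing
        unrelated = [
            j for j in non_const
            if j != i and not (_bases(names[i]) & _bases(names[j]))
        ]
        if not unrelated:
            vif_between[names[i]] = 1.0
        else:
            sub = Xv[:, [names.index("const")] + unrelated + [i]]
            vif_between[names[i]] = float(
                variance_inflation_factor(sub, sub.shape[1] - 1)
            )
    # Breusch-Pagan needs at least one regressor beyond the intercept; on a
    # numerically exact fit the residuals are rounding noise and the test is
    # meaningless, so report no evidence of heteroscedasticity
    tss = float(np.sum((yv - yv.mean()) ** 2))
    exact_fit = tss > 0 and float(np.sum(res.resid**2)) < 1e-12 * tss
    if not non_const:
        bp_p = 1.0
    elif exact_fit:
        bp_p = 1.0
    else:
        _, bp_p, _, _ = het_breuschpagan(res.resid, Xv)
    model_p = float(res.f_pvalue) if non_const else 1.0
    if non_const and exact_fit:
        model_p = 0.0
    return RegressionFit(
        spec=spec or ModelSpec(predictors=[c for c in names if c != "const"]),
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        tvalues=pd.Series(res.tvalues, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        r2=float(res.rsquared),
        r2_adj=float(res.rsquared_adj),
        model_p=model_p,
        vif=pd.Series(vif_vals, dtype=float),
        vif_between_variables=pd.Series(vif_between, dtype=float),
        residuals=np.asarray(res.resid),
        fitted=np.asarray(res.fittedvalues),
        heteroscedasticity_p=float(bp_p),
        nobs=n,
    )


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

MAX_BEST_SUBSET_COLUMNS = 12
P_ENTER = 0.05
P_REMOVE = 0.10


def default_candidate_universe(include_dummies: bool = True) -> ModelSpec:
    """The full candidate predictor set for selection on a curated table."""
    predictors = list(CONTINUOUS_PREDICTORS)
    if include_dummies:
        predictors += [
            "uronic_acid=iduronic",
            "sulfation_position=N",
            "folding_status=natively_unfolded",
            "disease_related=True",
        ]
    return ModelSpec(
        predictors=predictors,
        quadratics=["solute_molarity", "protein_gag_molar_ratio"],
    )


def _spec_from_columns(universe: ModelSpec, columns: tuple[str, ...]) -> ModelSpec:
    preds = [c for c in columns if "^2" not in c and ":" not in c]
    quads = [c[:-2] for c in columns if c.endswith("^2")]
    inters = [tuple(c.split(":", 1)) for c in columns if ":" in c]
    return ModelSpec(predictors=preds, interactions=inters, quadratics=quads)


def _usable_columns(entries, universe: ModelSpec) -> list[str]:
    """Prune candidate columns that are constant or mostly missing."""
    frame = entries if isinstance(entries, pd.DataFrame) else entries_to_frame(entries)
    usable = []
    for name in universe.column_names():
        base = name.replace("^2", "")
        parts = base.split(":")
        ok = True
        for part in parts:
            var = part.split("=", 1)[0]
            if var not in frame.columns:
                ok = False
                break
            col = frame[var]
            if col.notna().sum() < 5:
                ok = False
                break
            if col.nunique(dropna=True) < 2:
                ok = False
                break
        if ok:
            usable.append(name)
    return usable


def _hierarchy_ok(columns: tuple[str, ...]) -> bool:
    cols = set(columns)
    for c in cols:
        if c.endswith("^2") and c[:-2] not in cols:
            return False
    return True


def select_model(
    entries: Sequence[DatasetEntry] | pd.DataFrame,
    universe: ModelSpec | None = None,
    method: Literal["best_subset", "stepwise"] = "best_subset",
) -> tuple[RegressionFit, ModelSpec]:
    """Choose the model maximizing adjusted R² among those meeting all criteria.

    ``best_subset`` enumerates every subset of the (pruned) candidate columns,
    honouring the hierarchy that a squared term requires its linear term;
    ``stepwise`` runs forward selection (p-to-enter 0.05) with backward
    pruning (p-to-remove 0.10) and then criterion-checks the result. Ties in
    adjusted R² break toward fewer predictors, then lexicographic column order.
    """
    universe = universe or default_candidate_universe()
    universe.validate()
    candidates = _usable_columns(entries, universe)
    if len(candidates) > MAX_BEST_SUBSET_COLUMNS:
        raise DomainError(
            f"{len(candidates)} candidate columns exceed the enumeration cap "
            f"of {MAX_BEST_SUBSET_COLUMNS}; prune the universe"
        )
    if method == "best_subset":
        return _best_subset(entries, universe, candidates)
    if method == "stepwise":
        return _stepwise(entries, universe, candidates)
    raise DomainError(f"unknown selection method {method!r}")


def _try_fit(entries, universe, columns) -> RegressionFit | None:
    spec = _spec_from_columns(universe, tuple(columns))
    try:
        X, y = build_design(entries, spec)
        return ols_fit(X, y, spec=spec)
    except (SingularDesignError, DomainError):
        return None


def _best_subset(entries, universe, candidates):
    best = None  # (r2_adj, n_cols, cols, fit)
    near_misses = []
    for size in range(1, len(candidates) + 1):
        for cols in itertools.combinations(candidates, size):
            if not _hierarchy_ok(cols):
                continue
            fit = _try_fit(entries, universe, cols)
            if fit is None:
                continue
            ok, failures = fit.meets_criteria()
            if not ok:
                if fit.model_p < MODEL_ALPHA:
                    near_misses.append((cols, fit.r2_adj, failures))
                continue
            key = (-fit.r2_adj, len(cols), cols)
            if best is None or key < best[0]:
                best = (key, fit)
    if best is None:
        near_misses.sort(key=lambda t: -t[1])
        raise NoModelError(
            "no candidate subset satisfies all five model criteria",
            near_misses=near_misses[:10],
        )
    fit = best[1]
    return fit, fit.spec


def _stepwise(entries, universe, candidates):
    current: list[str] = []
    while True:
        # forward step: add the most significant admissible column
        best_add = None
        for c in candidates:
            if c in current or not _hierarchy_ok(tuple(current + [c])):
                continue
            fit = _try_fit(entries, universe, current + [c])
            if fit is None:
                continue
            p = fit.pvalues[c]
            if p < P_ENTER and (best_add is None or p < best_add[0]):
                best_add = (p, c, fit)
        if best_add is None:
            break
        current.append(best_add[1])
        # backward step: drop anything whose p has drifted above p-to-remove,
        # never orphaning a square
        while True:
            fit = _try_fit(entries, universe, current)
            removable = [
                c for c in current
                if fit.pvalues[c] >= P_REMOVE
                and _hierarchy_ok(tuple(x for x in current if x != c))
            ]
            if not removable:
                break
            worst = max(removable, key=lambda c: fit.pvalues[c])
            current.remove(worst)
    if not current:
        raise NoModelError("stepwise selection admitted no predictor")
    fit = _try_fit(entries, universe, current)
    ok, failures = fit.meets_criteria()
    if not ok:
        raise NoModelError(
            f"stepwise model {current} fails criteria: {failures}",
            near_misses=[(tuple(current), fit.r2_adj, failures)],
        )
    return fit, fit.spec


# ---------------------------------------------------------------------------
# The predictive equation
# ---------------------------------------------------------------------------

@dataclass
class PredictiveModel:
    """Coefficients of the linear–quadratic predictive equation for G.

    ``G = y0 + a*P_S + b*P_B + c*P_MR + c_prime*P_MR**2`` with P_S the GAG
    sulfates per disaccharide unit, P_B the solute molarity in mM and P_MR the
    protein:GAG molar ratio.
    """

    y0: float
    a: float
    b: float
    c: float
    c_prime: float
    se_y0: float | None = None
    se_a: float | None = None
    se_b: float | None = None
    se_c: float | None = None
    se_c_prime: float | None = None

    @classmethod
    def published(cls) -> "PredictiveModel":
        """The coefficient set reported for the curated 39-entry database."""
        return cls(
            y0=2.0, a=0.30, b=-0.016, c=0.11, c_prime=-0.0020,
            se_y0=0.7, se_a=0.05, se_b=0.004, se_c=0.03, se_c_prime=0.0005,
        )

    @classmethod
    def from_fit(cls, fit: RegressionFit) -> "PredictiveModel":
        p, s = fit.params, fit.bse
        return cls(
            y0=p["const"],
            a=p["sulfates_per_disaccharide"],
            b=p["solute_molarity"],
            c=p["protein_gag_molar_ratio"],
            c_prime=p["protein_gag_molar_ratio^2"],
            se_y0=s["const"],
            se_a=s["sulfates_per_disaccharide"],
            se_b=s["solute_molarity"],
            se_c=s["protein_gag_molar_ratio"],
            se_c_prime=s["protein_gag_molar_ratio^2"],
        )

    def coefficients(self) -> np.ndarray:
        return np.array([self.y0, self.a, self.b, self.c, self.c_prime])

    def predict(self, P_S, P_B, P_MR):
        return predict_G(self, P_S, P_B, P_MR)

    def to_json(self, path: str | Path, provenance: dict | None = None) -> None:
        payload = {
            "coefficients": {
                "y0": self.y0, "a": self.a, "b": self.b,
                "c": self.c, "c_prime": self.c_prime,
            },
            "standard_errors": {
                "y0": self.se_y0, "a": self.se_a, "b": self.se_b,
                "c": self.se_c, "c_prime": self.se_c_prime,
            },
            "provenance": provenance or {},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PredictiveModel":
        payload = json.loads(Path(path).read_text())
        co, se = payload["coefficients"], payload.get("standard_errors", {})
        return cls(
            y0=co["y0"], a=co["a"], b=co["b"], c=co["c"], c_prime=co["c_prime"],
            se_y0=se.get("y0"), se_a=se.get("a"), se_b=se.get("b"),
            se_c=se.get("c"), se_c_prime=se.get("c_prime"),
        )


def predict_G(model: PredictiveModel, P_S, P_B, P_MR):
    """Evaluate the predictive equation; vectorized over array inputs."""
    P_S = np.asarray(P_S, float)
    P_B = np.asarray(P_B, float)
    P_MR = np.asarray(P_MR, float)
    if np.any(P_S < 0) or np.any(P_B < 0):
        raise DomainError("P_S and P_B must be non-negative")
    if np.any(P_MR <= 0):
        raise DomainError("P_MR must be positive")
    out = model.y0 + model.a * P_S + model.b * P_B + model.c * P_MR + model.c_prime * P_MR**2
    return float(out) if out.ndim == 0 else out


def optimal_molar_ratio(
    model: PredictiveModel, P_S: float = 0.0, P_B: float = 0.0
) -> tuple[float, float]:
    """Protein:GAG molar ratio maximizing predicted G, and the G value there.

    The quadratic vertex is ``-c / (2 c')``, which requires a concave ratio
    dependence (``c' < 0``). With the published coefficients the vertex sits at
    27.5; note the source analysis verbally estimated the optimum as ~10 from
    the same data, a discrepancy we report rather than hide — the closed form
    follows from the printed coefficients.
    """
    if model.c_prime >= 0:
        raise DomainError(
            f"no interior maximum: quadratic coefficient {model.c_prime} >= 0"
        )
    vertex = -model.c / (2.0 * model.c_prime)
    g_at = model.y0 + model.a * P_S + model.b * P_B + model.c * vertex + model.c_prime * vertex**2
    return float(vertex), float(g_at)
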