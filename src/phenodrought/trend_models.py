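"""Trend regressions with pairwise interactions and backward selection.

Three analyses are run on the simulated outputs:

1. budbreak timing:   doy ~ year + model + site + species_class + scenario
2. monthly drought:   spei ~ year + model + site + scenario  (per month)
3. anomaly coupling:  doy_anomaly ~ spei_anomaly + site + model + scenario
                                    + year + species_class

each with all pairwise interactions among the main terms, reduced by
stepwise backward selection on an information criterion (AIC by default,
BIC optional) under the marginality constraint: a main effect is never
dropped while a retained interaction contains it.  Ties in the criterion
are broken by dropping the lexicographically last candidate, so selection
traces are deterministic.

The selection-plus-fit step is exposed as a scikit-learn-style regressor,
:class:`BackwardSelectedOLS`; the underlying least-squares fits delegate
to statsmodels OLS on patsy-built design matrices.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

_TIE_EPS = 1e-9


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one regression.

    ``categorical`` lists variables to treatment-code; if None, object,
    category and bool dtypes are treated as categorical.  Reference level
    is the alphabetically first level (pandas/patsy default).
    """

    response: str
    main_terms: tuple
    categorical: tuple | None = None
    include_pairwise_interactions: bool = True
    selection: str = "backward"  # backward | none
    criterion: str = "aic"  # aic | bic

    def __post_init__(self) -> None:
        if self.response in self.main_terms:
            raise ValueError("response must not appear among main_terms")
        if self.selection not in ("backward", "none"):
            raise ValueError(f"unknown selection {self.selection!r}")
        if self.criterion not in ("aic", "bic"):
            raise ValueError(f"unknown criterion {self.criterion!r}")


@dataclass
class Design:
    """A realized design: response vector, full model matrix, term map."""

    response: str
    y: np.ndarray
    X: pd.DataFrame = field(repr=False)
    term_slices: dict = field(repr=False)  # term label -> column slice
    main_labels: tuple = ()
    interaction_labels: tuple = ()
    parents: dict = field(default_factory=dict)  # interaction -> {mains}
    design_info: object = field(default=None, repr=False)

    @property
    def all_terms(self) -> tuple:
        return self.main_labels + self.interaction_labels

    def columns_for(self, terms) -> list[int]:
        cols = list(range(self.term_slices["Intercept"].start,
                          self.term_slices["Intercept"].stop))
        for t in self.all_terms:  # preserve design order
            if t in terms:
                sl = self.term_slices[t]
                cols.extend(range(sl.start, sl.stop))
        return cols


@dataclass
class FitResult:
    """One fitted (possibly selection-reduced) OLS model."""

    response: str
    retained_terms: tuple
    coefficients: dict  # column name -> (estimate, standard error)
    r_squared: float
    n_obs: int
    criterion: str
    criterion_value: float
    selection_trace: tuple = ()  # ((dropped term, criterion after drop), ...)


def _is_categorical(series: pd.Series) -> bool:
    return (
        series.dtype == object
        or isinstance(series.dtype, pd.CategoricalDtype)
        or series.dtype == bool
    )


def build_design(data: pd.DataFrame, spec: ModelSpec) -> Design:
    """Build the full treatment-coded design matrix for a ModelSpec.

    Main-effect labels are the variable names (categoricals wrapped as
    ``C(var)``); interaction labels join two main labels with ``:`` for
    every unordered pair of main terms.
    """
    missing = [v for v in (spec.response,) + tuple(spec.main_terms)
               if v not in data.columns]
    if missing:
        raise ValueError(f"variables missing from data: {missing}")

    cat = set(spec.categorical) if spec.categorical is not None else {
        v for v in spec.main_terms if _is_categorical(data[v])
    }
    for v in cat:
        if data[v].nunique() < 2:
            raise ValueError(f"categorical variable {v!r} has a single level")

    labels = {v: (f"C({v})" if v in cat else v) for v in spec.main_terms}
    mains = tuple(labels[v] for v in spec.main_terms)
    interactions: tuple = ()
    parents: dict = {}
    if spec.include_pairwise_interactions:
        pairs = []
        for a, b in itertools.combinations(spec.main_terms, 2):
            lab = f"{labels[a]}:{labels[b]}"
            pairs.append(lab)
            parents[lab] = {labels[a], labels[b]}
        interactions = tuple(pairs)

    formula = " + ".join(mains + interactions) or "1"
    y_df, X = patsy.dmatrices(
        f"{spec.response} ~ {formula}", data, return_type="dataframe"
    )
    term_slices = dict(X.design_info.term_name_slices)
    for lab in mains + interactions:
        if lab not in term_slices:
            raise AssertionError(f"term {lab!r} missing from design: "
                                 f"{list(term_slices)}")
    Xv = X.to_numpy()
    if Xv.shape[0] <= Xv.shape[1]:
        raise ValueError(
            f"n_obs {Xv.shape[0]} must exceed n_columns {Xv.shape[1]}"
        )
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return Design(
        response=spec.response,
        y=np.asarray(y_df).ravel(),
        X=X,
        term_slices=term_slices,
        main_labels=mains,
        interaction_labels=interactions,
        parents=parents,
        design_info=X.design_info,
    )


def _ols(design: Design, terms) -> sm.regression.linear_model.RegressionResults:
    cols = design.columns_for(set(terms))
    X = design.X.iloc[:, cols]
    return sm.OLS(design.y, X).fit()


def criterion_value(design: Design, terms, criterion: str = "aic") -> float:
    res = _ols(design, terms)
    return float(res.aic if criterion == "aic" else res.bic)


def fit_ols(design: Design, terms=None, criterion: str = "aic",
            trace=()) -> FitResult:
    """Ordinary least squares on a term subset of a design (all terms by
    default); coefficients, standard errors and R^2 from statsmodels."""
    terms = tuple(design.all_terms) if terms is None else tuple(terms)
    res = _ols(design, terms)
    coefs = {
        name: (float(est), float(se))
        for name, est, se in zip(res.model.exog_names, res.params, res.bse)
    }
    return FitResult(
        response=design.response,
        retained_terms=terms,
        coefficients=coefs,
        r_squared=float(res.rsquared),
        n_obs=int(res.nobs),
        criterion=criterion,
        criterion_value=float(res.aic if criterion == "aic" else res.bic),
        selection_trace=tuple(trace),
    )


def _removable(design: Design, current: set) -> list[str]:
    out = []
    for t in current:
        if t in design.parents:  # interaction: always removable
            out.append(t)
        else:
            blocked = any(
                t in design.parents[i] for i in current if i in design.parents
            )
            if not blocked:
                out.append(t)
    return out


def backward_select(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Stepwise backward elimination under the marginality constraint.

    At each step the candidate whose removal most lowers the criterion is
    dropped (main effects stay while any retained interaction contains
    them); selection stops when no removal improves the criterion.  The
    full trace of (dropped term, criterion value) is recorded.
    """
    design = build_design(data, spec)
    if spec.selection == "none":
        return fit_ols(design, criterion=spec.criterion)
    current = set(design.all_terms)
    best = criterion_value(design, current, spec.criterion)
    trace = []
    while True:
        candidates = _removable(design, current)
        if not candidates:
            break
        scored = [
            (criterion_value(design, current - {t}, spec.criterion), t)
            for t in candidates
        ]
        lowest = min(c for c, _ in scored)
        if lowest >= best - _TIE_EPS:
            break
        tied = [t for c, t in scored if c <= lowest + _TIE_EPS]
        drop = sorted(tied)[-1]  # lexicographically last among ties
        current -= {drop}
        best = [c for c, t in scored if t == drop][0]
        trace.append((drop, best))
    # keep design order in the retained tuple
    retained = tuple(t for t in design.all_terms if t in current)
    return fit_ols(design, retained, criterion=spec.criterion, trace=trace)


class BackwardSelectedOLS(RegressorMixin, BaseEstimator):
    """OLS with pairwise interactions and backward selection (sklearn API).

    ``fit`` takes a DataFrame of predictor columns and a response vector;
    the design (treatment coding, pairwise interactions) and the
    marginality-constrained backward elimination follow the module-level
    :func:`backward_select`.

    Parameters
    ----------
    main_terms : columns of X to use (default: all columns).
    include_pairwise_interactions : include every unordered pair.
    selection : "backward" or "none".
    criterion : "aic" or "bic".

    Attributes
    ----------
    result_ : the :class:`FitResult`.
    design_info_ : patsy design info, reused to encode new data in
        ``predict``.
    """

    def __init__(self, main_terms=None, include_pairwise_interactions=True,
                 selection="backward", criterion="aic"):
        self.main_terms = main_terms
        self.include_pairwise_interactions = include_pairwise_interactions
        self.selection = selection
        self.criterion = criterion

    def fit(self, X: pd.DataFrame, y):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a pandas DataFrame of named predictors")
        mains = tuple(self.main_terms) if self.main_terms else tuple(X.columns)
        data = X.copy()
        data["_response_"] = np.asarray(y, dtype=float)
        spec = ModelSpec(
            response="_response_",
            main_terms=mains,
            include_pairwise_interactions=self.include_pairwise_interactions,
            selection=self.selection,
            criterion=self.criterion,
        )
        design = build_design(data, spec)
        if self.selection == "none":
            self.result_ = fit_ols(design, criterion=self.criterion)
        else:
            self.result_ = backward_select(data, spec)
        self._design = design
        self._cols = design.columns_for(set(self.result_.retained_terms))
        res = _ols(design, self.result_.retained_terms)
        self._params = res.params
        self.design_info_ = design.design_info
        return self

    def predict(self, X: pd.DataFrame):
        check_is_fitted(self, "result_")
        (mat,) = patsy.build_design_matrices([self.design_info_], X)
        return np.asarray(mat)[:, self._cols] @ np.asarray(self._params)

    def score(self, X, y):  # R^2, as sklearn regressors define it
        y = np.asarray(y, dtype=float)
        resid = y - self.predict(X)
        return 1.0 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))


@dataclass
class TrendAnalyses:
    """Bundle of the three trend analyses."""

    budbreak_trend: FitResult
    spei_trends: dict  # month -> FitResult
    spei_trend_pooled: FitResult
    anomaly: FitResult


def run_trend_analyses(
    budbreak: pd.DataFrame,
    spei: pd.DataFrame,
    anomalies: pd.DataFrame,
    criterion: str = "aic",
    spei_months=tuple(range(1, 9)),
) -> TrendAnalyses:
    """Run the three analyses on simulated outputs.

    ``budbreak`` must carry year, site, model, scenario, species_class,
    doy (not-reached rows removed beforehand or flagged -1, which are
    dropped here); ``spei`` must carry year, month, site, model, scenario,
    spei; ``anomalies`` the anomaly table.  SPEI trends are fitted per
    calendar month (January-August by default) plus one pooled fit with
    month as an additional factor.
    """
    bb = budbreak[budbreak["doy"] >= 0]
    if bb.empty or spei.empty or anomalies.empty:
        raise ValueError("empty input table")
    m1 = backward_select(
        bb,
        ModelSpec(
            response="doy",
            main_terms=("year", "model", "site", "species_class", "scenario"),
            criterion=criterion,
        ),
    )
    spei_spec = ModelSpec(
        response="spei",
        main_terms=("year", "model", "site", "scenario"),
        criterion=criterion,
    )
    m2 = {
        int(month): backward_select(
            spei[spei["month"] == month], spei_spec
        )
        for month in spei_months
    }
    m2_pooled = backward_select(
        spei[spei["month"].isin(spei_months)],
        ModelSpec(
            response="spei",
            main_terms=("year", "model", "site", "scenario", "month"),
            categorical=("model", "site", "scenario", "month"),
            criterion=criterion,
        ),
    )
    m3 = backward_select(
        anomalies,
        ModelSpec(
            response="doy_anomaly",
            main_terms=(
                "spei_anomaly", "site", "model", "scenario", "year",
                "species_class",
            ),
            criterion=criterion,
        ),
    )
    return TrendAnalyses(
        budbreak_trend=m1, spei_trends=m2, spei_trend_pooled=m2_pooled, anomaly=m3
    )
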