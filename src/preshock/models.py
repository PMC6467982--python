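"""Pre-shock risk models.

The primary model is a lasso-regularized logistic regression on normalized
features: regularization strength is chosen by 10-fold cross validation with
folds split by patient (never by row, to avoid within-patient leakage), the
model is refit at the chosen strength, and odds ratios with 95% confidence
bounds are reported from an unpenalized refit on the selected features
(post-selection Wald intervals -- no selective-inference correction, which
is the conventional presentation for this kind of model and is documented
as such). A gradient-boosting adapter and a lasso Cox proportional-hazards
comparator (events = shock onset, censoring = end of observation; Efron tie
handling) honor the same ``predict_risk`` contract, so the detection stage
treats all three identically.

All estimators follow scikit-learn conventions: ``fit`` / ``predict_proba``
/ ``get_params``, fitted attributes with trailing underscores.
"""

from __future__ import annotations

import json
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


def _check_binary(y) -> np.ndarray:
    y = np.asarray(y).astype(int)
    classes = np.unique(y)
    if len(classes) != 2 or not np.array_equal(classes, [0, 1]):
        raise ValueError(f"need a binary 0/1 target with both classes present, got classes {classes}")
    return y


class PreShockGLM(ClassifierMixin, BaseEstimator):
    """Lasso-regularized logistic pre-shock classifier.

    Parameters
    ----------
    n_folds : cross-validation folds for choosing the l1 strength (by patient
        when ``groups`` is passed to :meth:`fit`).
    Cs : number of points (or explicit grid) on the inverse-regularization path.
    selection : 'min_deviance' picks the strength minimizing CV deviance;
        '1se' picks the strongest penalty within one standard error of it.
    """

    def __init__(self, n_folds: int = 10, Cs=10, selection: str = "min_deviance",
                 random_state: int = 0, max_iter: int = 2000):
        self.n_folds = n_folds
        self.Cs = Cs
        self.selection = selection
        self.random_state = random_state
        self.max_iter = max_iter

    def fit(self, X, y, groups=None):
        X = _as_frame(X)
        y = _check_binary(y)
        if len(y) < self.n_folds:
            raise ValueError(f"need at least n_folds={self.n_folds} rows, got {len(y)}")
        if self.selection not in ("min_deviance", "1se"):
            raise ValueError("selection must be 'min_deviance' or '1se'")

        if groups is not None:
            cv = list(GroupKFold(n_splits=self.n_folds).split(X, y, groups))
        else:
            cv = list(
                StratifiedKFold(
                    n_splits=self.n_folds, shuffle=True, random_state=self.random_state
                ).split(X, y)
            )
        import warnings as _warnings

        with _warnings.catch_warnings():
            # sklearn is migrating the penalty spelling; the l1 path itself is stable
            _warnings.simplefilter("ignore", FutureWarning)
            search = LogisticRegressionCV(
                Cs=self.Cs,
                cv=cv,
                penalty="l1",
                solver="liblinear",
                scoring="neg_log_loss",
                refit=True,
                random_state=self.random_state,
                max_iter=self.max_iter,
            ).fit(X.to_numpy(), y)

        scores = search.scores_[1]  # folds x Cs, per-fold neg log-loss
        mean = scores.mean(axis=0)
        if self.selection == "min_deviance":
            c_idx = int(np.argmax(mean))
            final = search
        else:
            se = scores.std(axis=0, ddof=1) / np.sqrt(scores.shape[0])
            best = int(np.argmax(mean))
            admissible = np.nonzero(mean >= mean[best] - se[best])[0]
            # Cs ascend, so the first admissible index is the strongest penalty
            c_idx = int(admissible[0])
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", FutureWarning)
                _warnings.filterwarnings("ignore", message=".*penalty.*", category=UserWarning)
                final = LogisticRegression(
                    penalty="l1",
                    C=float(_cs_grid(search)[c_idx]),
                    solver="liblinear",
                    random_state=self.random_state,
                    max_iter=self.max_iter,
                ).fit(X.to_numpy(), y)

        self.C_ = float(_cs_grid(search)[c_idx])
        self.cv_deviance_path_ = -2.0 * mean  # mean CV deviance per C
        self.Cs_grid_ = _cs_grid(search)
        self.coef_ = np.asarray(final.coef_[0], dtype=float)
        self.intercept_ = float(np.asarray(final.intercept_).ravel()[0])
        self.classes_ = np.array([0, 1])
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.selected_features_ = [
            c for c, b in zip(X.columns, self.coef_) if abs(b) > 1e-10
        ]
        self.coefficients_ = self._post_selection_inference(X, y)
        return self

    def _post_selection_inference(self, X: pd.DataFrame, y: np.ndarray) -> pd.DataFrame:
        """Unpenalized refit on the selected features; Wald 95% CIs."""
        import statsmodels.api as sm

        cols = self.selected_features_
        if not cols:
            return pd.DataFrame(
                columns=["coef", "exp_coef", "ci_low", "ci_high", "exp_ci_low", "exp_ci_high"]
            )
        design = sm.add_constant(X[cols].to_numpy(), has_constant="add")
        try:
            with np.errstate(all="ignore"):
                res = sm.Logit(y, design).fit(disp=0, maxiter=200)
            if not res.mle_retvals.get("converged", True):
                raise RuntimeError("refit did not converge")
            params = res.params[1:]
            ci = res.conf_int(alpha=0.05)[1:]
        except Exception as exc:  # separable or ill-conditioned refits
            logger.warning("post-selection refit failed (%s); reporting penalized coefficients", exc)
            params = np.array([self.coef_[list(self.feature_names_in_).index(c)] for c in cols])
            ci = np.column_stack([np.full(len(cols), np.nan)] * 2)
        out = pd.DataFrame(
            {
                "coef": params,
                "exp_coef": np.exp(params),
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "exp_ci_low": np.exp(ci[:, 0]),
                "exp_ci_high": np.exp(ci[:, 1]),
            },
            index=pd.Index(cols, name="feature"),
        )
        return out

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = _as_frame(X)[list(self.feature_names_in_)]
        return self.intercept_ + X.to_numpy() @ self.coef_

    def predict_proba(self, X) -> np.ndarray:
        z = self.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def predict_risk(self, X) -> np.ndarray:
        """Risk score z in [0, 1]: the logistic of the linear predictor."""
        return self.predict_proba(X)[:, 1]

    # -- artifact serialization (JSON, text-only) ---------------------------

    def to_json(self) -> str:
        check_is_fitted(self, "coef_")
        return json.dumps(
            {
                "kind": "glm",
                "features": list(self.feature_names_in_),
                "coef": list(map(float, self.coef_)),
                "intercept": self.intercept_,
                "C": self.C_,
                "selected_features": list(self.selected_features_),
                "coefficients": self.coefficients_.reset_index().to_dict(orient="list"),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, payload: str) -> "PreShockGLM":
        obj = json.loads(payload)
        if obj.get("kind") != "glm":
            raise ValueError("not a GLM artifact")
        model = cls()
        model.feature_names_in_ = np.asarray(obj["features"], dtype=object)
        model.coef_ = np.asarray(obj["coef"], dtype=float)
        model.intercept_ = float(obj["intercept"])
        model.C_ = float(obj["C"])
        model.classes_ = np.array([0, 1])
        model.selected_features_ = list(obj["selected_features"])
        model.coefficients_ = pd.DataFrame(obj["coefficients"]).set_index("feature")
        return model


def _cs_grid(search: LogisticRegressionCV) -> np.ndarray:
    cs = np.asarray(search.Cs_)
    return cs if cs.ndim == 1 else cs[0]


class XGBoostRiskModel(ClassifierMixin, BaseEstimator):
    """Gradient-boosting adapter honoring the risk-model contract.

    The tree machinery is delegated to xgboost; this wrapper only pins the
    deterministic single-thread configuration and the ``predict_risk``
    surface shared with the GLM.
    """

    def __init__(self, n_estimators: int = 150, max_depth: int = 3,
                 learning_rate: float = 0.1, random_state: int = 0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.random_state = random_state

    def fit(self, X, y, groups=None):
        from xgboost import XGBClassifier

        X = _as_frame(X)
        y = _check_binary(y)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.model_ = XGBClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            random_state=self.random_state,
            n_jobs=1,
            tree_method="hist",
            eval_metric="logloss",
        ).fit(X.to_numpy(), y)
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = _as_frame(X)[list(self.feature_names_in_)]
        return self.model_.predict_proba(X.to_numpy())

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def predict_risk(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]


class CoxRiskModel(BaseEstimator):
    """Lasso-regularized Cox proportional-hazards comparator.

    Each row is a (features, time-to-onset, event) sample: the event is
    septic shock onset and non-shock rows are right-censored at the end of
    observation. The penalizer is chosen by patient-grouped cross-validated
    partial likelihood over a small grid; ties use the Efron approximation
    (the lifelines default). The per-row risk score is the linear predictor,
    which preserves the ROC ordering of the hazard.
    """

    def __init__(self, penalizers: Sequence[float] = (1e-4, 1e-3, 1e-2, 1e-1),
                 l1_ratio: float = 1.0, n_folds: int = 5, random_state: int = 0):
        self.penalizers = penalizers
        self.l1_ratio = l1_ratio
        self.n_folds = n_folds
        self.random_state = random_state

    def fit(self, X, durations, events, groups=None):
        from lifelines import CoxPHFitter

        X = _as_frame(X)
        durations = np.asarray(durations, dtype=float)
        events = np.asarray(events).astype(int)
        if events.sum() == 0:
            raise ValueError("all rows are censored: cannot fit a Cox model with no events")
        if np.any(durations <= 0):
            raise ValueError("durations must be > 0")

        df = X.copy()
        df["_duration"] = durations
        df["_event"] = events

        def _fit(frame, penalizer):
            return CoxPHFitter(penalizer=penalizer, l1_ratio=self.l1_ratio).fit(
                frame, duration_col="_duration", event_col="_event"
            )

        penalizers = list(self.penalizers)
        if len(penalizers) > 1 and len(df) > self.n_folds:
            if groups is not None:
                splits = list(GroupKFold(n_splits=self.n_folds).split(df, events, groups))
            else:
                splits = list(
                    StratifiedKFold(
                        n_splits=self.n_folds, shuffle=True, random_state=self.random_state
                    ).split(df, events)
                )
            cv_ll = []
            for p in penalizers:
                lls = []
                for tr, te in splits:
                    if events[tr].sum() == 0 or events[te].sum() == 0:
                        continue
                    try:
                        f = _fit(df.iloc[tr], p)
                        lls.append(f.score(df.iloc[te], scoring_method="log_likelihood"))
                    except Exception:
                        continue
                cv_ll.append(np.mean(lls) if lls else -np.inf)
            self.penalizer_ = float(penalizers[int(np.argmax(cv_ll))])
            self.cv_log_likelihood_ = np.asarray(cv_ll)
        else:
            self.penalizer_ = float(penalizers[0])

        self.fitter_ = _fit(df, self.penalizer_)
        self.params_ = self.fitter_.params_.copy()
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.selected_features_ = [c for c in X.columns if abs(self.params_[c]) > 1e-8]
        return self

    def predict_risk(self, X) -> np.ndarray:
        """Linear predictor (log partial hazard) per row."""
        check_is_fitted(self, "params_")
        X = _as_frame(X)[list(self.feature_names_in_)]
        return X.to_numpy() @ self.params_.to_numpy()


# -- spec-surface functional wrappers ---------------------------------------


def fit_glm_lasso(training, n_folds: int = 10, seed: int = 0, selection: str = "min_deviance") -> PreShockGLM:
    """Fit the lasso GLM on a :class:`~preshock.features.TrainingSet`."""
    model = PreShockGLM(n_folds=n_folds, random_state=seed, selection=selection)
    return model.fit(training.X, training.y, groups=training.groups)


def fit_xgboost(training, seed: int = 0, **kwargs) -> XGBoostRiskModel:
    return XGBoostRiskModel(random_state=seed, **kwargs).fit(training.X, training.y)


def fit_cox_comparator(X, durations, events, groups=None, seed: int = 0) -> CoxRiskModel:
    """Fit the lasso Cox comparator on (features, time-to-onset, censoring) rows."""
    return CoxRiskModel(random_state=seed).fit(X, durations, events, groups=groups)


def predict_risk(model, X) -> np.ndarray:
    """Per-row risk score under any fitted risk model (the shared contract)."""
    return model.predict_risk(X)


def build_cox_inputs(matrix, Z: pd.DataFrame, observation_end: Mapping[str, float]):
    """Per-row survival samples for the Cox comparator.

    Duration is time from the row to shock onset (shock patients) or to the
    end of observation (censored); rows with non-positive duration are
    dropped. Returns ``(Z_rows, durations, events, groups)``.
    """
    pids = matrix.patient_ids
    times = matrix.times
    durations = np.empty(len(pids))
    events = np.zeros(len(pids), dtype=int)
    for i, (p, t) in enumerate(zip(pids, times)):
        t_o = matrix.shock_onset.get(p)
        if t_o is not None:
            durations[i] = t_o - t
            events[i] = 1
        else:
            durations[i] = observation_end[p] - t
    keep = durations > 0
    return Z.loc[keep].reset_index(drop=True), durations[keep], events[keep], pids[keep]
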