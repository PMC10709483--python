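"""Forecasting the daily number of emergency inpatient admissions.

Emergency arrivals per medical department are modeled as a daily regression
target driven by calendar structure (weekday, season, holidays), weather
(temperature, air pressure, humidity, wind, precipitation), local events and
the previous day's admissions.  The pipeline is:

1. :func:`build_feature_table` -- assemble one row per day;
2. :func:`pcc_screen` -- drop one member of every feature pair with
   ``|Pearson correlation| >= threshold`` (default 0.7) to curb
   multicollinearity;
3. :func:`shadow_feature_importance` -- Boruta-style selection: each round
   appends a randomly permuted "shadow" copy of every feature, fits a random
   forest, and a real feature scores a hit when its permutation importance
   beats the best shadow; a binomial test over rounds confirms or rejects;
4. :func:`fit_forecaster` / :func:`predict` -- eight methods: a per-weekday
   historical-average baseline, two seasonal time-series forecasters
   (Holt-Winters triple exponential smoothing, SARIMA chosen by unit-root
   tests and AIC), four regularized regressions (ridge, lasso, elastic net,
   group lasso) and a multilayer perceptron;
5. :func:`evaluate_rmse` -- accuracy on held-out days;
6. :func:`anticipate_emergencies` -- turn per-day forecasts into anticipated
   patient stubs for the bed-assignment model.

Counts are treated as real-valued targets throughout and only clipped at
zero on prediction and rounded when anticipation stubs are created.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.linear_model import ElasticNetCV, LassoCV, RidgeCV
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler

from .domain import ANTICIPATED, EMERGENCY, Instance, Patient

SEASONAL_PERIOD = 7  # strong weekday dependence of admissions

METHODS = ("baseline_avg", "holt_winters", "sarima", "ridge", "lasso",
           "elastic_net", "group_lasso", "ann")

#: factor blocks of the metadata table; also the group-lasso group structure
FEATURE_BLOCKS = {
    "weekday": ["WD_Mon", "WD_Tue", "WD_Wed", "WD_Thu", "WD_Fri", "WD_Sat", "WD_Sun"],
    "season": ["Q1", "Q2", "Q3", "Q4"],
    "holiday": ["Hol_School", "Holiday", "WD_postholiday"],
    "temperature": ["T_mean", "T_min", "T_max", "T_dif"],
    "air_pressure": ["AP_mean", "AP_min", "AP_max", "AP_dif"],
    "humidity": ["H_mean", "H_min", "H_max", "H_dif"],
    "wind": ["W_mean", "W_min", "W_max", "W_dif", "G_max"],
    "precipitation": ["Rain", "Snow", "Hail", "S_cov", "Storm"],
    "events": ["Fair", "SportEvent"],
    "occupancy": ["PrevAdmin"],
}


# ---------------------------------------------------------------------------
# feature engineering
# ---------------------------------------------------------------------------

def build_feature_table(raw: pd.DataFrame, arrivals: pd.Series) -> pd.DataFrame:
    """One row per day: calendar one-hots, weather aggregates, lag-1 target.

    `raw` needs a daily DatetimeIndex and (at least) columns T_min, T_max,
    plus any of AP/H/W min-max pairs and the binary flags; `arrivals` is the
    per-day admission count of one department, aligned by date.
    """
    if not raw.index.equals(arrivals.index):
        raise ValueError("metadata and arrivals must share one daily date index")
    diffs = raw.index.to_series().diff().dropna()
    gaps = diffs[diffs != pd.Timedelta(days=1)]
    if len(gaps):
        raise ValueError(f"missing dates in metadata: gaps after {list(gaps.index.date)}")
    if (raw["T_max"] < raw["T_min"]).any():
        bad = raw.index[raw["T_max"] < raw["T_min"]][0].date()
        raise ValueError(f"T_max < T_min on {bad}")
    out = pd.DataFrame(index=raw.index)
    dow = raw.index.dayofweek
    for i, name in enumerate(FEATURE_BLOCKS["weekday"]):
        out[name] = (dow == i).astype(float)
    quarter = raw.index.quarter
    for qi in range(1, 5):
        out[f"Q{qi}"] = (quarter == qi).astype(float)
    for flag in ("Hol_School", "Holiday"):
        out[flag] = raw.get(flag, 0.0)
    holiday = out["Holiday"].to_numpy()
    post = np.zeros(len(out))
    post[1:] = (holiday[:-1] == 1) & (dow[1:] < 5)
    out["WD_postholiday"] = post
    for prefix in ("T", "AP", "H", "W"):
        lo, hi = f"{prefix}_min", f"{prefix}_max"
        if lo in raw and hi in raw:
            out[f"{prefix}_mean"] = raw.get(f"{prefix}_mean", (raw[lo] + raw[hi]) / 2.0)
            out[lo] = raw[lo]
            out[hi] = raw[hi]
            out[f"{prefix}_dif"] = raw[hi] - raw[lo]
    for flag in ("G_max", "Rain", "Snow", "Hail", "S_cov", "Storm", "Fair", "SportEvent"):
        if flag in raw:
            out[flag] = raw[flag]
    out["PrevAdmin"] = arrivals.shift(1).fillna(0.0)
    out["arrivals"] = arrivals.astype(float)
    return out


def train_test_split_by_date(table: pd.DataFrame, train_years: int = 2):
    """Chronological split: first `train_years` calendar years train, rest test."""
    cutoff_year = table.index[0].year + train_years
    train = table[table.index.year < cutoff_year]
    test = table[table.index.year >= cutoff_year]
    return train, test


def pcc_screen(table: pd.DataFrame, threshold: float = 0.7,
               target: str = "arrivals"):
    """Greedy multicollinearity screen.

    Features are visited in column order; one is dropped when it correlates
    at ``|PCC| >= threshold`` with an already-retained feature (so in a chain
    a~b, b~c only the middle member b is dropped).  Constant features cannot
    be screened (their PCC is undefined) and are flagged separately.
    """
    features = [c for c in table.columns if c != target]
    constant = [c for c in features if table[c].nunique() <= 1]
    screenable = [c for c in features if c not in constant]
    corr = table[screenable].corr().abs()
    retained, dropped_pairs = [], []
    for col in screenable:
        partner = next((r for r in retained if corr.loc[col, r] >= threshold), None)
        if partner is None:
            retained.append(col)
        else:
            dropped_pairs.append((partner, col))
    return retained, dropped_pairs, constant


# ---------------------------------------------------------------------------
# shadow-feature (Boruta-style) importance
# ---------------------------------------------------------------------------

@dataclass
class ImportanceResult:
    decisions: dict            # feature -> "confirmed" | "rejected" | "tentative"
    hits: dict                 # feature -> rounds beating the best shadow
    n_rounds: int
    mean_importance: dict

    def confirmed(self):
        return [f for f, d in self.decisions.items() if d == "confirmed"]


def shadow_feature_importance(table: pd.DataFrame, target: str = "arrivals",
                              n_estimators: int = 40, max_rounds: int = 20,
                              seed: int = 0, alpha: float = 0.05,
                              n_repeats: int = 3, burn_in: int = 5) -> ImportanceResult:
    """Shadow-variable feature selection with a random-forest regressor.

    Each round appends a randomly permuted "shadow" copy of every still-active
    feature, fits a random forest on [active | shadows] and computes
    permutation importances on a held-out third of the rows (out-of-sample,
    so a memorised continuous noise feature cannot look important); an active
    feature scores a hit when it beats the maximum shadow importance.  From
    round `burn_in` on, features whose hit count is already binomially
    significantly below the fair coin are rejected and removed, shrinking
    the shadow pool the survivors compete against.  After `max_rounds`, a
    feature is confirmed (rejected) when its hits over the rounds it
    participated in are significantly above (below) the fair-coin null at
    level `alpha`; the rest stay tentative.
    """
    if len(table) < 30:
        raise ValueError("need at least 30 rows for shadow-feature importance")
    y = table[target].to_numpy(float)
    if np.ptp(y) == 0:
        raise ValueError("target is constant; importance undefined")
    features = [c for c in table.columns if c != target]
    x_full = table[features].to_numpy(float)
    rng = np.random.default_rng(seed)
    hits = {f: 0 for f in features}
    rounds_in = {f: 0 for f in features}
    imp_sum = {f: 0.0 for f in features}
    decisions = {}
    active = list(features)
    for rnd in range(max_rounds):
        if not active:
            break
        cols = [features.index(f) for f in active]
        x = x_full[:, cols]
        shadow = x.copy()
        for j in range(shadow.shape[1]):
            rng.shuffle(shadow[:, j])
        both = np.hstack([x, shadow])
        holdout = rng.permutation(len(y)) < len(y) // 3
        forest = RandomForestRegressor(
            n_estimators=n_estimators, random_state=int(rng.integers(2 ** 31)),
            n_jobs=1, max_features=1.0)
        forest.fit(both[~holdout], y[~holdout])
        perm = permutation_importance(
            forest, both[holdout], y[holdout], n_repeats=n_repeats,
            random_state=int(rng.integers(2 ** 31)), n_jobs=1)
        real_imp = perm.importances_mean[: len(active)]
        shadow_max = perm.importances_mean[len(active):].max()
        for j, f in enumerate(active):
            rounds_in[f] += 1
            imp_sum[f] += real_imp[j]
            if real_imp[j] > shadow_max:
                hits[f] += 1
        if rnd + 1 >= burn_in:
            for f in list(active):
                p_low = stats.binomtest(hits[f], rounds_in[f], 0.5,
                                        alternative="less").pvalue
                if p_low < alpha:
                    decisions[f] = "rejected"
                    active.remove(f)
    for f in features:
        if f in decisions:
            continue
        k, n = hits[f], rounds_in[f]
        if stats.binomtest(k, n, 0.5, alternative="greater").pvalue < alpha:
            decisions[f] = "confirmed"
        elif stats.binomtest(k, n, 0.5, alternative="less").pvalue < alpha:
            decisions[f] = "rejected"
        else:
            decisions[f] = "tentative"
    return ImportanceResult(
        decisions=decisions, hits=hits, n_rounds=max_rounds,
        mean_importance={f: imp_sum[f] / max(1, rounds_in[f]) for f in features})


# ---------------------------------------------------------------------------
# group lasso (block-coordinate proximal gradient)
# ---------------------------------------------------------------------------

class GroupLasso:
    """Linear regression with a group-l2 penalty
    ``(1/2n)||y - Xb||^2 + lam * sum_g sqrt(p_g) ||b_g||_2``,
    fit by proximal gradient descent on standardized features."""

    def __init__(self, groups: Sequence[Sequence[int]], lam: float = 0.1,
                 max_iter: int = 500, tol: float = 1e-6):
        self.groups = [np.asarray(g, dtype=int) for g in groups]
        self.lam = lam
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        n, p = x.shape
        self.x_mean_, self.x_scale_ = x.mean(0), x.std(0)
        self.x_scale_[self.x_scale_ == 0] = 1.0
        xs = (x - self.x_mean_) / self.x_scale_
        self.y_mean_ = y.mean()
        yc = y - self.y_mean_
        lips = np.linalg.norm(xs, 2) ** 2 / n  # largest eigenvalue of X'X/n
        step = 1.0 / max(lips, 1e-12)
        beta = np.zeros(p)
        weights = [np.sqrt(len(g)) for g in self.groups]
        for _ in range(self.max_iter):
            grad = xs.T @ (xs @ beta - yc) / n
            new = beta - step * grad
            for g, w in zip(self.groups, weights):
                norm = np.linalg.norm(new[g])
                thresh = step * self.lam * w
                new[g] = 0.0 if norm <= thresh else new[g] * (1 - thresh / norm)
            if np.max(np.abs(new - beta)) < self.tol:
                beta = new
                break
            beta = new
        self.coef_ = beta
        return self

    def predict(self, x):
        xs = (np.asarray(x, float) - self.x_mean_) / self.x_scale_
        return xs @ self.coef_ + self.y_mean_


def _group_lasso_cv(x, y, groups, seed, n_folds=10, n_lambdas=12):
    n = len(y)
    xs = StandardScaler().fit_transform(x)
    yc = y - y.mean()
    lam_max = max(np.linalg.norm(xs[:, g].T @ yc) / (n * np.sqrt(len(g)))
                  for g in groups)
    lams = np.geomspace(lam_max, lam_max * 1e-3, n_lambdas)
    rng = np.random.default_rng(seed)
    folds = rng.permutation(n) % n_folds
    errors = np.zeros(len(lams))
    for f in range(n_folds):
        tr, te = folds != f, folds == f
        for i, lam in enumerate(lams):
            model = GroupLasso(groups, lam=lam, max_iter=300).fit(x[tr], y[tr])
            errors[i] += np.sum((model.predict(x[te]) - y[te]) ** 2)
    best = lams[int(np.argmin(errors))]
    return GroupLasso(groups, lam=best).fit(x, y)


# ---------------------------------------------------------------------------
# forecasters
# ---------------------------------------------------------------------------

@dataclass
class Forecaster:
    method: str
    model: object = None
    feature_names: list = field(default_factory=list)
    weekday_means: Optional[np.ndarray] = None
    last_date: Optional[pd.Timestamp] = None
    metadata: dict = field(default_factory=dict)


def _xy(table: pd.DataFrame, target: str):
    features = [c for c in table.columns if c != target]
    return table[features].to_numpy(float), table[target].to_numpy(float), features


def fit_forecaster(method: str, train: pd.DataFrame, target: str = "arrivals",
                   seed: int = 0, config: Optional[dict] = None) -> Forecaster:
    config = config or {}
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    y = train[target].to_numpy(float)
    fc = Forecaster(method=method, last_date=train.index[-1])

    if method == "baseline_avg":
        dow = train.index.dayofweek.to_numpy()
        fc.weekday_means = np.array([
            y[dow == d].mean() if (dow == d).any() else y.mean() for d in range(7)])
        return fc

    if method in ("holt_winters", "sarima"):
        if len(y) < 2 * SEASONAL_PERIOD:
            raise ValueError("need at least two weekly cycles of history")
        from statsmodels.tsa.holtwinters import ExponentialSmoothing
        from statsmodels.tsa.statespace.sarimax import SARIMAX
        from statsmodels.tsa.stattools import adfuller
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if method == "holt_winters":
                seasonal = "add" if np.ptp(y) > 0 else None
                fc.model = ExponentialSmoothing(
                    y, trend="add", seasonal=seasonal,
                    seasonal_periods=SEASONAL_PERIOD if seasonal else None,
                    initialization_method="estimated").fit(optimized=True)
                return fc
            # SARIMA: unit-root test picks d, small AIC grid picks the rest
            try:
                d = 1 if adfuller(y, autolag="AIC")[1] > 0.05 else 0
            except Exception:
                d = 0
            best = (np.inf, None)
            max_pq = config.get("max_pq", 1)
            for p in range(max_pq + 1):
                for q in range(max_pq + 1):
                    for sp in range(2):
                        for sq in range(2):
                            if p == q == sp == sq == 0:
                                continue
                            try:
                                res = SARIMAX(
                                    y, order=(p, d, q),
                                    seasonal_order=(sp, 0, sq, SEASONAL_PERIOD),
                                ).fit(disp=False)
                                if res.aic < best[0]:
                                    best = (res.aic, res)
                            except Exception:
                                continue
            if best[1] is None:
                raise RuntimeError("no SARIMA candidate converged")
            fc.model = best[1]
            fc.metadata["aic"] = best[0]
        return fc

    x, yv, features = _xy(train, target)
    fc.feature_names = features
    if method == "ridge":
        fc.model = RidgeCV(alphas=np.geomspace(1e-3, 1e3, 25), cv=10).fit(x, yv)
    elif method == "lasso":
        fc.model = LassoCV(cv=10, random_state=seed, max_iter=5000).fit(x, yv)
    elif method == "elastic_net":
        # l1 ratio searched between 0 and 1 in 0.025 steps
        fc.model = ElasticNetCV(l1_ratio=np.arange(0.025, 1.0001, 0.025),
                                cv=10, random_state=seed, max_iter=5000).fit(x, yv)
    elif method == "group_lasso":
        groups, idx = [], {f: i for i, f in enumerate(features)}
        for block in FEATURE_BLOCKS.values():
            g = [idx[f] for f in block if f in idx]
            if g:
                groups.append(g)
        grouped = {i for g in groups for i in g}
        groups.extend([[i] for i in range(len(features)) if i not in grouped])
        fc.model = _group_lasso_cv(x, yv, groups, seed)
    elif method == "ann":
        scaler = StandardScaler().fit(x)
        xs = scaler.transform(x)
        # narrow deep tails (…4:2) can die under ReLU; keep the best of a
        # few seeded restarts by validation score
        best = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for restart in range(config.get("restarts", 3)):
                net = MLPRegressor(
                    hidden_layer_sizes=(32, 16, 8, 4, 2), activation="relu",
                    alpha=config.get("alpha", 1e-3),
                    max_iter=config.get("max_iter", 500),
                    early_stopping=True, n_iter_no_change=25,
                    validation_fraction=0.15, random_state=seed + restart)
                net.fit(xs, yv)
                score = net.best_validation_score_
                if best is None or score > best[0]:
                    best = (score, net)
        fc.model = best[1]
        fc.metadata["scaler"] = scaler
    return fc


def predict(fc: Forecaster, test: object, target: str = "arrivals") -> np.ndarray:
    """Daily non-negative forecasts.

    Time-series methods take an integer horizon or a date-indexed frame (its
    length sets the horizon); feature-based methods need the feature rows.
    """
    if fc.method == "baseline_avg":
        if isinstance(test, int):
            start = fc.last_date + pd.Timedelta(days=1)
            dows = pd.date_range(start, periods=test).dayofweek
        else:
            dows = test.index.dayofweek
        raw = fc.weekday_means[np.asarray(dows)]
    elif fc.method in ("holt_winters", "sarima"):
        steps = test if isinstance(test, int) else len(test)
        raw = np.asarray(fc.model.forecast(steps))
    else:
        if isinstance(test, int):
            raise ValueError(f"{fc.method} needs feature rows, not a horizon")
        missing = [f for f in fc.feature_names if f not in test.columns]
        if missing:
            raise ValueError(f"feature schema mismatch; missing {missing}")
        x = test[fc.feature_names].to_numpy(float)
        if fc.method == "ann":
            x = fc.metadata["scaler"].transform(x)
        raw = np.asarray(fc.model.predict(x))
    return np.clip(raw, 0.0, None)


def evaluate_rmse(fc: Forecaster, test: pd.DataFrame, target: str = "arrivals") -> float:
    if len(test) == 0:
        raise ValueError("empty test set")
    pred = predict(fc, test, target=target)
    return float(np.sqrt(np.mean((pred - test[target].to_numpy(float)) ** 2)))


# ---------------------------------------------------------------------------
# anticipation layer
# ---------------------------------------------------------------------------

def median_emergency_los(instance: Instance, department: int) -> int:
    los = sorted(p.los for p in instance.patients
                 if p.department == department and p.ptype == EMERGENCY)
    if not los:
        los = sorted(p.los for p in instance.patients) or [1]
    return int(los[len(los) // 2])


def anticipate_emergencies(forecasts: Mapping, instance: Instance,
                           rng: np.random.Generator,
                           id_base: int = 1_000_000) -> list:
    """Anticipated patient stubs from per-(department, day) forecasts.

    Each forecast is rounded to the nearest integer number of stubs; stubs
    carry the anticipated-patient weight, the department's median emergency
    LOS, and a gender drawn at the instance's gender ratio.
    """
    genders = [p.gender for p in instance.patients] or [1]
    female_share = float(np.mean([g == 1 for g in genders]))
    ages = [p.age for p in instance.patients] or [70]
    stubs = []
    for key in sorted(forecasts):
        dept, day = key
        if dept not in instance.departments:
            raise KeyError(f"unknown department {dept}")
        value = forecasts[key]
        if value < 0:
            raise ValueError("forecasts must be non-negative")
        count = int(np.floor(value + 0.5))  # round half up, deterministically
        for i in range(count):
            stubs.append(Patient(
                id=id_base + len(stubs),
                gender=1 if rng.random() < female_share else -1,
                age=int(rng.choice(ages)),
                department=dept,
                care_level=1.0,
                ptype=ANTICIPATED,
                registration_day=day,
                arrival_day=day,
                los=median_emergency_los(instance, dept),
            ))
    return stubs
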