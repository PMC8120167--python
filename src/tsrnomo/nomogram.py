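"""Points-based prognostic nomogram built from a Cox model.

A nomogram re-parameterizes a fitted proportional-hazards model as a score:
within each predictor, per-level points are the log-hazard distance from
that predictor's lowest-risk level, scaled so that the single largest
within-predictor span equals 100 points.  Summed points are therefore an
affine image of the linear predictor, and survival prediction from total
points is lossless:

    S(t | x) = S0(t) ^ exp(total_points / points_per_unit_beta + offset)

where the offset re-centres the score to the model's reference pattern.
Validation utilities: Harrell's C-index, a predicted-versus-observed
calibration table, paired ROC comparison (DeLong), and total-points risk
stratification into three groups via the two-cutpoint log-rank search.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import concordance_index
from scipy import stats as sps

from .cutpoint import TwoCutpointResult, optimal_two_cutpoints
from .stats import CoxModelResult

__all__ = [
    "Nomogram",
    "RiskStrata",
    "build_nomogram",
    "c_index",
    "delong_roc_compare",
]


@dataclass(frozen=True)
class RiskStrata:
    """Three-group risk stratification by total points (<=/> convention)."""

    cutoffs: tuple[float, float]
    labels: np.ndarray  # 'I' / 'II' / 'III' per patient
    search: TwoCutpointResult

    def assign(self, total_points: float | np.ndarray) -> np.ndarray | str:
        tp = np.asarray(total_points, dtype=float)
        c1, c2 = self.cutoffs
        out = np.where(tp <= c1, "I", np.where(tp <= c2, "II", "III"))
        return out.item() if out.ndim == 0 else out


@dataclass(frozen=True)
class Nomogram:
    """Per-predictor points map plus the survival inversion.

    ``points`` carries full-precision values; rendering rounds to one
    decimal.  ``offset`` is the linear-predictor value (versus the fitted
    model's reference levels) of the all-lowest-risk pattern, so that
    ``lp = total_points / points_per_unit_beta + offset``.
    """

    points: dict[str, dict[str, float]]
    points_per_unit_beta: float
    offset: float
    baseline_times: np.ndarray | None = None
    baseline_survival: np.ndarray | None = None
    horizon: float | None = None

    @property
    def max_total_points(self) -> float:
        return sum(max(v.values()) for v in self.points.values())

    def points_table(self, decimals: int = 1) -> pd.DataFrame:
        rows = [
            (cov, lvl, round(pts, decimals))
            for cov, levels in self.points.items()
            for lvl, pts in levels.items()
        ]
        return pd.DataFrame(rows, columns=["predictor", "level", "points"])

    def score(self, covariates: pd.Series | dict) -> float:
        """Total points of one covariate pattern (sum over predictors)."""
        total = 0.0
        for cov, levels in self.points.items():
            lvl = str(covariates[cov])
            if lvl not in levels:
                raise KeyError(f"unknown level {lvl!r} for predictor {cov!r}")
            total += levels[lvl]
        return total

    def score_table(self, df: pd.DataFrame) -> np.ndarray:
        return np.array([self.score(row) for _, row in df.iterrows()])

    def predict_survival(self, total_points: float, t: float) -> float:
        """Disease-free survival probability at t months for a total score."""
        if self.baseline_times is None:
            raise ValueError("nomogram carries no baseline survival")
        if t < 0 or (self.horizon is not None and t > self.horizon):
            raise ValueError(f"t={t} outside the supported horizon")
        idx = np.searchsorted(self.baseline_times, t, side="right") - 1
        s0 = 1.0 if idx < 0 else float(self.baseline_survival[idx])
        lp = total_points / self.points_per_unit_beta + self.offset
        return float(s0 ** np.exp(lp))

    def stratify(self, df: pd.DataFrame, duration_col="time_months",
                 event_col="event", min_group_frac: float = 0.10) -> RiskStrata:
        """Three risk groups from the optimal two-cutpoint total-points split."""
        tp = self.score_table(df)
        res = optimal_two_cutpoints(
            tp, df[duration_col].to_numpy(float), df[event_col].to_numpy(int),
            min_group_frac=min_group_frac,
        )
        c1, c2 = res.cutoffs
        labels = np.where(tp <= c1, "I", np.where(tp <= c2, "II", "III"))
        return RiskStrata(cutoffs=res.cutoffs, labels=labels, search=res)

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "points": self.points,
            "points_per_unit_beta": self.points_per_unit_beta,
            "offset": self.offset,
            "baseline_times": None if self.baseline_times is None else list(map(float, self.baseline_times)),
            "baseline_survival": None if self.baseline_survival is None else list(map(float, self.baseline_survival)),
            "horizon": self.horizon,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Nomogram":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(
            points=d["points"],
            points_per_unit_beta=d["points_per_unit_beta"],
            offset=d["offset"],
            baseline_times=None if d["baseline_times"] is None else np.asarray(d["baseline_times"]),
            baseline_survival=None if d["baseline_survival"] is None else np.asarray(d["baseline_survival"]),
            horizon=d["horizon"],
        )


def build_nomogram(
    model: CoxModelResult | dict[str, dict[str, float]],
    horizon: float | None = 60.0,
) -> Nomogram:
    """Scale a Cox model's per-level log-hazards into nomogram points.

    Accepts a fitted :class:`CoxModelResult` or a plain mapping
    covariate -> level -> log-hazard (e.g. the log of a published HR
    table).  Within each predictor the lowest-risk level gets 0 points and
    the largest within-predictor log-hazard span across all predictors is
    scaled to 100 points.
    """
    if isinstance(model, CoxModelResult):
        coeffs = model.coefficients
        baseline_times = model.baseline_times
        baseline_surv = model.baseline_survival
    else:
        coeffs = model
        baseline_times = baseline_surv = None

    shifted: dict[str, dict[str, float]] = {}
    offset = 0.0
    for cov, levels in coeffs.items():
        low = min(levels.values())
        shifted[cov] = {lvl: b - low for lvl, b in levels.items()}
        offset += low
    span = max(max(v.values()) for v in shifted.values())
    if span <= 0:
        raise ValueError("degenerate model: no predictor has a nonzero log-hazard span")
    scale = 100.0 / span
    points = {cov: {lvl: scale * b for lvl, b in levels.items()} for cov, levels in shifted.items()}
    return Nomogram(
        points=points,
        points_per_unit_beta=scale,
        offset=offset,
        baseline_times=baseline_times,
        baseline_survival=baseline_surv,
        horizon=horizon,
    )


def c_index(scores, time, event) -> float:
    """Harrell's concordance: higher score => earlier event is concordant."""
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise ValueError("no comparable pairs: no events observed")
    # lifelines counts higher predicted value as longer survival
    return float(concordance_index(time, -scores, event))


def calibration(
    nomo: Nomogram,
    df: pd.DataFrame,
    t: float = 60.0,
    n_bins: int = 3,
    duration_col: str = "time_months",
    event_col: str = "event",
) -> pd.DataFrame:
    """Predicted-vs-observed survival at t, by equal-count predicted bins.

    Bins patients on predicted S(t), and per bin reports the mean
    prediction, the Kaplan-Meier estimate at t with Greenwood 95% CI, and
    a flag for bins where the observed estimate is undefined at t.
    """
    pred = np.array([nomo.predict_survival(nomo.score(r), t) for _, r in df.iterrows()])
    order = pd.qcut(pred, q=n_bins, labels=False, duplicates="drop")
    if pd.isna(order).all():  # constant predictions: a single usable bin
        order = np.zeros(len(pred))
    rows = []
    for b in sorted(pd.unique(order[~pd.isna(order)])):
        sel = order == b
        sub = df[sel]
        kmf = KaplanMeierFitter()
        kmf.fit(sub[duration_col], sub[event_col])
        km_at = float(kmf.survival_function_at_times(t).iloc[0])
        ci = kmf.confidence_interval_survival_function_
        idx = ci.index.searchsorted(t, side="right") - 1
        lo, hi = (ci.iloc[idx, 0], ci.iloc[idx, 1]) if idx >= 0 else (0.0, 1.0)
        usable = bool((sub[duration_col] >= t).any() or sub[event_col].any())
        rows.append({
            "bin": int(b), "n": int(sel.sum()), "predicted_mean": float(pred[sel].mean()),
            "observed_km": km_at, "km_lo95": float(lo), "km_hi95": float(hi),
            "usable": usable,
        })
    return pd.DataFrame(rows)


def _delong_components(scores: np.ndarray, y: np.ndarray):
    cases = scores[y == 1]
    controls = scores[y == 0]
    v10 = np.array([(np.sum(c > controls) + 0.5 * np.sum(c == controls)) / len(controls) for c in cases])
    v01 = np.array([(np.sum(cases > c) + 0.5 * np.sum(cases == c)) / len(cases) for c in controls])
    return v10, v01


def delong_roc_compare(score_a, score_b, time, event, horizon: float = 60.0) -> dict:
    """Paired AUC comparison at a fixed horizon by DeLong's test.

    The binary outcome is "event by ``horizon``"; patients censored before
    the horizon have unknown status and are excluded.  Returns empirical
    AUCs, the paired difference and its two-sided P.
    """
    score_a = np.asarray(score_a, dtype=float)
    score_b = np.asarray(score_b, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    known = (event == 1) & (time <= horizon) | (time >= horizon)
    y = ((event == 1) & (time <= horizon)).astype(int)[known]
    sa, sb = score_a[known], score_b[known]
    if y.min() == y.max():
        raise ValueError("outcome has a single class at the horizon")
    va10, va01 = _delong_components(sa, y)
    vb10, vb01 = _delong_components(sb, y)
    auc_a, auc_b = float(va10.mean()), float(vb10.mean())
    m, n = len(va10), len(va01)
    s10 = np.cov(np.vstack([va10, vb10]))
    s01 = np.cov(np.vstack([va01, vb01]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        p = float(2 * sps.norm.sf(abs(diff) / np.sqrt(var)))
    return {"auc_a": auc_a, "auc_b": auc_b, "difference": diff, "p": p,
            "n_cases": int(y.sum()), "n_controls": int((1 - y).sum())}
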