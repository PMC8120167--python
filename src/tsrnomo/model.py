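"""Model/Results facade over the survival and nomogram machinery.

`PrognosticModel` is constructed from a clinical table and a predictor
list; `fit()` runs the Cox partial-likelihood estimation (with the chosen
stepwise procedure) and returns a `PrognosticResults` object that carries
the coefficient table, the derived nomogram, and the validation utilities
(C-index, calibration, ROC comparison, risk stratification).

    >>> model = PrognosticModel.from_dataframe(df, predictors=[...])
    >>> res = model.fit(selection="backward")
    >>> print(res.summary())
    >>> res.c_index()
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import reference
from .cutpoint import categorize
from .nomogram import Nomogram, RiskStrata, build_nomogram, c_index, calibration, delong_roc_compare
from .stats import CoxModelResult, cox_fit, km_estimate

__all__ = ["PrognosticModel", "PrognosticResults", "DEFAULT_PREDICTORS", "DEFAULT_REFERENCES"]

DEFAULT_PREDICTORS = ["t_stage", "n_status", "grade", "er", "pr", "her2", "tsr_group"]

#: Reference (baseline-hazard) level per predictor, matching the published
#: multivariable table: T1, node-negative, grade I, ER-negative,
#: PR-negative, HER2 non-amplified, stroma-high.
DEFAULT_REFERENCES = {
    "t_stage": "T1",
    "n_status": "neg",
    "grade": "I",
    "er": "neg",
    "pr": "neg",
    "her2": "non-amp",
    "tsr_group": "high",
}


class PrognosticModel:
    """Cox proportional-hazards survival model on a clinical table.

    If ``tsr_group`` is requested as a predictor but absent from the table,
    it is derived by dichotomizing the continuous ``tsr`` column at
    ``tsr_cutoff`` (<= cutoff is stroma-low).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        predictors: list[str] | None = None,
        duration_col: str = "time_months",
        event_col: str = "event",
        references: dict[str, str] | None = None,
        tsr_cutoff: float = reference.TSR_CUTOFF,
    ):
        data = data.copy()
        predictors = list(predictors or DEFAULT_PREDICTORS)
        if "tsr_group" in predictors and "tsr_group" not in data.columns:
            if "tsr" not in data.columns:
                raise ValueError("neither tsr_group nor tsr present in the table")
            data["tsr_group"] = categorize(data["tsr"].to_numpy(float), tsr_cutoff)
        self.data = data
        self.predictors = predictors
        self.duration_col = duration_col
        self.event_col = event_col
        self.references = {**DEFAULT_REFERENCES, **(references or {})}
        self.tsr_cutoff = tsr_cutoff

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "PrognosticModel":
        return cls(df, **kwargs)

    def fit(
        self, selection: str = "enter", alpha: float = 0.10, ties: str = "breslow"
    ) -> "PrognosticResults":
        cox = cox_fit(
            self.data,
            self.predictors,
            duration_col=self.duration_col,
            event_col=self.event_col,
            selection=selection,
            alpha=alpha,
            references={k: v for k, v in self.references.items() if k in self.predictors},
            ties=ties,
        )
        return PrognosticResults(self, cox)


class PrognosticResults:
    """Fitted model: coefficient estimates, nomogram, and validation."""

    def __init__(self, model: PrognosticModel, cox: CoxModelResult):
        self.model = model
        self.cox = cox
        self.nomogram: Nomogram = build_nomogram(cox, horizon=float(model.data[model.duration_col].max()))

    # -- estimates ----------------------------------------------------------

    def summary(self) -> pd.DataFrame:
        """Coefficients, HRs with 95% CIs, Wald P and nomogram points."""
        tab = self.cox.summary()
        pts = []
        for _, r in tab.iterrows():
            lvl = r["level"].removesuffix(" (ref)")
            pts.append(round(self.nomogram.points[r["covariate"]][lvl], 1))
        tab["points"] = pts
        return tab

    def __repr__(self) -> str:
        events = int(self.model.data[self.model.event_col].sum())
        head = (
            f"PrognosticResults(n={len(self.model.data)}, events={events}, "
            f"selection={self.cox.selection!r}, ties={self.cox.ties_method!r})"
        )
        return head + "\n" + self.summary().to_string(index=False)

    # -- scoring and prediction --------------------------------------------

    def total_points(self, df: pd.DataFrame | None = None) -> np.ndarray:
        return self.nomogram.score_table(self._table(df))

    def predict_survival(self, covariates, t: float = 60.0) -> float:
        return self.nomogram.predict_survival(self.nomogram.score(covariates), t)

    # -- validation ---------------------------------------------------------

    def c_index(self, df: pd.DataFrame | None = None) -> float:
        df = self._table(df)
        return c_index(
            self.nomogram.score_table(df),
            df[self.model.duration_col],
            df[self.model.event_col],
        )

    def calibration(self, df: pd.DataFrame | None = None, t: float = 60.0, n_bins: int = 3):
        return calibration(
            self.nomogram, self._table(df), t=t, n_bins=n_bins,
            duration_col=self.model.duration_col, event_col=self.model.event_col,
        )

    def compare_roc(self, other_scores, df: pd.DataFrame | None = None, horizon: float = 60.0):
        """DeLong comparison of the nomogram score against another score."""
        df = self._table(df)
        return delong_roc_compare(
            self.nomogram.score_table(df), other_scores,
            df[self.model.duration_col], df[self.model.event_col], horizon=horizon,
        )

    def stratify(self, df: pd.DataFrame | None = None, min_group_frac: float = 0.10) -> RiskStrata:
        return self.nomogram.stratify(
            self._table(df), duration_col=self.model.duration_col,
            event_col=self.model.event_col, min_group_frac=min_group_frac,
        )

    # -- plotting -----------------------------------------------------------

    def plot_calibration(self, t: float = 60.0, n_bins: int = 3, ax=None):
        """Predicted-vs-observed survival at t with the identity line."""
        import matplotlib.pyplot as plt

        cal = self.calibration(t=t, n_bins=n_bins)
        if ax is None:
            _, ax = plt.subplots()
        ax.errorbar(
            cal["predicted_mean"], cal["observed_km"],
            yerr=[cal["observed_km"] - cal["km_lo95"], cal["km_hi95"] - cal["observed_km"]],
            fmt="o-", capsize=3, label="nomogram",
        )
        ax.plot([0, 1], [0, 1], color="grey", ls="--", label="ideal")
        ax.set_xlabel(f"predicted S({t:g})")
        ax.set_ylabel(f"observed S({t:g}) (Kaplan-Meier)")
        ax.legend()
        return ax

    def plot_km_by_stratum(self, min_group_frac: float = 0.10, ax=None):
        """Kaplan-Meier curves of the three total-points risk groups."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        strata = self.stratify(min_group_frac=min_group_frac)
        df = self.model.data
        for grp in ("I", "II", "III"):
            sel = strata.labels == grp
            if not sel.any():
                continue
            curve = km_estimate(df[self.model.duration_col][sel], df[self.model.event_col][sel])
            ax.step(curve.times, curve.survival, where="post", label=f"group {grp}")
        ax.set_xlabel("months")
        ax.set_ylabel("disease-free survival")
        ax.legend()
        return ax

    def _table(self, df: pd.DataFrame | None) -> pd.DataFrame:
        if df is None:
            return self.model.data
        df = df.copy()
        if "tsr_group" in self.model.predictors and "tsr_group" not in df.columns:
            df["tsr_group"] = categorize(df["tsr"].to_numpy(float), self.model.tsr_cutoff)
        return df
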