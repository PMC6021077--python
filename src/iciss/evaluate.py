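"""Discrimination and calibration of predicted mortality.

Discrimination is the AUROCC — identical to the Mann–Whitney
concordance probability: over all (death, survivor) pairs, the fraction
in which the death received the higher predicted mortality, ties
counting one half.

Calibration is summarised by an ordinary-least-squares line fitted to
observed versus predicted mortality, on two scales:

* *probability scale* — each patient's 0/1 outcome regressed on their
  predicted mortality (the default headline slope/intercept);
* *decile-means scale* — observed decile mortality regressed on mean
  predicted decile mortality, the quantity a decile calibration plot
  displays.

Slope 1 / intercept 0 indicates perfect calibration; slope well below 1
means the score overestimates mortality risk.  A logistic-recalibration
(logit-scale) slope is available as a labelled extra.

Confidence intervals are percentile bootstrap: (prediction, outcome)
pairs resampled jointly with replacement, sample size preserved, 95%
interval from the 2.5th/97.5th percentiles of the draw distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .errors import DegenerateMetricError, ValidationError


def _as_arrays(predictions, outcomes) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape or p.ndim != 1:
        raise ValidationError("predictions and outcomes must be 1-D and equal-length")
    if not np.all((y == 0) | (y == 1)):
        raise ValidationError("outcomes must be binary 0/1")
    return p, y


def auroc(predictions: Sequence[float], outcomes: Sequence[int]) -> float:
    """Area under the ROC curve of predicted mortality against death.

    Requires at least one death and one survivor; equals the tie-aware
    Mann–Whitney concordance probability.
    """
    p, y = _as_arrays(predictions, outcomes)
    if y.min() == y.max():
        raise DegenerateMetricError(
            "AUROCC undefined: outcomes contain a single class"
        )
    return float(roc_auc_score(y, p))


def calibration_line(
    predictions: Sequence[float],
    outcomes: Sequence[int],
    scale: Literal["probability", "decile_means"] = "probability",
) -> tuple[float, float]:
    """OLS calibration (slope, intercept) of observed on predicted mortality."""
    p, y = _as_arrays(predictions, outcomes)
    if scale == "decile_means":
        table = decile_table(p, y)
        x, obs = table["mean_predicted"].to_numpy(), table["observed"].to_numpy()
    elif scale == "probability":
        x, obs = p, y
    else:
        raise ValidationError(f"unknown calibration scale {scale!r}")
    if len(x) < 2 or np.ptp(x) == 0:
        raise DegenerateMetricError(
            "calibration line undefined: constant predictions"
        )
    fit = stats.linregress(x, obs)
    return float(fit.slope), float(fit.intercept)


def logistic_recalibration_slope(
    predictions: Sequence[float], outcomes: Sequence[int]
) -> tuple[float, float]:
    """Logit-scale calibration: logistic fit of outcome on logit(prediction).

    A labelled extra; the headline slope is the probability-scale OLS.
    """
    from sklearn.linear_model import LogisticRegression

    p, y = _as_arrays(predictions, outcomes)
    if y.min() == y.max():
        raise DegenerateMetricError("single-class outcomes")
    eps = 1e-6
    logit = np.log(np.clip(p, eps, 1 - eps) / (1 - np.clip(p, eps, 1 - eps)))
    if np.ptp(logit) == 0:
        raise DegenerateMetricError("constant predictions")
    model = LogisticRegression(penalty=None, solver="lbfgs", max_iter=1000)
    model.fit(logit.reshape(-1, 1), y)
    return float(model.coef_[0, 0]), float(model.intercept_[0])


def decile_table(
    predictions: Sequence[float], outcomes: Sequence[int], n_bins: int = 10
) -> pd.DataFrame:
    """Equal-count risk deciles with tied predictions kept together.

    Returns a frame with columns ``decile, mean_predicted, observed, n``
    ordered by predicted mortality.  When ties make exact equal counts
    impossible the bin boundary shifts forward past the tie run; fully
    degenerate input (a single distinct prediction) raises.
    """
    p, y = _as_arrays(predictions, outcomes)
    if len(p) < n_bins:
        raise ValidationError(
            f"need at least {n_bins} observations for {n_bins} bins; "
            "use fewer bins"
        )
    order = np.argsort(p, kind="stable")
    ps, ys = p[order], y[order]
    n = len(ps)
    rows = []
    start = 0
    for b in range(n_bins):
        if start >= n:
            break
        # ideal boundary, then extend past any tie run straddling it
        end = round(n * (b + 1) / n_bins)
        end = max(end, start + 1)
        while end < n and ps[end] == ps[end - 1]:
            end += 1
        rows.append(
            {
                "decile": len(rows) + 1,
                "mean_predicted": float(ps[start:end].mean()),
                "observed": float(ys[start:end].mean()),
                "n": int(end - start),
            }
        )
        start = end
    if len(rows) < 2:
        raise DegenerateMetricError(
            "predictions are too heavily tied to form risk deciles"
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BootstrapCI:
    point: float
    lower: float
    upper: float
    n_draws: int
    n_redraws: int
    seed: int

    def overlaps(self, other: "BootstrapCI") -> bool:
        return self.lower <= other.upper and other.lower <= self.upper

    def as_dict(self) -> dict:
        return {
            "point": self.point,
            "lower": self.lower,
            "upper": self.upper,
        }


def bootstrap_ci(
    metric: Callable[[np.ndarray, np.ndarray], float],
    predictions: Sequence[float],
    outcomes: Sequence[int],
    n_draws: int = 1000,
    seed: int = 0,
) -> BootstrapCI:
    """Percentile bootstrap 95% CI for one metric.

    Pairs are resampled jointly with replacement at the original sample
    size.  Draws on which the metric is undefined (e.g. a single-class
    resample) are redrawn so the interval always rests on exactly
    ``n_draws`` valid statistics; if more than half of all attempts are
    undefined the bootstrap aborts.
    """
    if n_draws < 1:
        raise ValidationError("n_draws must be >= 1")
    p, y = _as_arrays(predictions, outcomes)
    point = metric(p, y)  # raises if undefined on the full sample
    rng = np.random.default_rng(seed)
    n = len(p)
    values = np.empty(n_draws)
    got = 0
    redraws = 0
    attempts = 0
    while got < n_draws:
        idx = rng.integers(0, n, size=n)
        attempts += 1
        try:
            values[got] = metric(p[idx], y[idx])
        except DegenerateMetricError:
            redraws += 1
            if attempts > 2 * n_draws and redraws > attempts / 2:
                raise DegenerateMetricError(
                    f"metric undefined on {redraws}/{attempts} bootstrap draws"
                )
            continue
        got += 1
    lower, upper = np.percentile(values, [2.5, 97.5])
    return BootstrapCI(
        point=float(point),
        lower=float(lower),
        upper=float(upper),
        n_draws=n_draws,
        n_redraws=redraws,
        seed=seed,
    )


@dataclass
class PerformanceReport:
    """Discrimination and calibration of one score against one outcome."""

    outcome: str  # "m30d" | "m24h"
    score_label: str  # "ICISSm30d" | "ICISSm24h"
    auroc: BootstrapCI
    cal_slope: BootstrapCI  # probability-scale OLS
    cal_intercept: BootstrapCI
    decile_slope: float
    decile_intercept: float
    decile_table: pd.DataFrame
    n: int
    n_bootstrap: int
    seed: int

    def as_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "score": self.score_label,
            "n": self.n,
            "auroc": self.auroc.as_dict(),
            "cal_slope": self.cal_slope.as_dict(),
            "cal_intercept": self.cal_intercept.as_dict(),
            "decile_slope": self.decile_slope,
            "decile_intercept": self.decile_intercept,
            "decile_table": self.decile_table.to_dict(orient="records"),
            "n_bootstrap": self.n_bootstrap,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PerformanceReport":
        def ci(x):
            return BootstrapCI(
                point=x["point"],
                lower=x["lower"],
                upper=x["upper"],
                n_draws=d["n_bootstrap"],
                n_redraws=0,
                seed=d["seed"],
            )

        return cls(
            outcome=d["outcome"],
            score_label=d["score"],
            auroc=ci(d["auroc"]),
            cal_slope=ci(d["cal_slope"]),
            cal_intercept=ci(d["cal_intercept"]),
            decile_slope=d["decile_slope"],
            decile_intercept=d["decile_intercept"],
            decile_table=pd.DataFrame(d["decile_table"]),
            n=d["n"],
            n_bootstrap=d["n_bootstrap"],
            seed=d["seed"],
        )


def evaluate_performance(
    predictions: Sequence[float],
    outcomes: Sequence[int],
    outcome: str = "m30d",
    score_label: str = "ICISSm30d",
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> PerformanceReport:
    """Full report: AUROCC + calibration with bootstrap 95% CIs.

    One joint resampling loop serves all three bootstrapped metrics, so
    their CIs come from the same draws (and one RNG stream).
    """
    p, y = _as_arrays(predictions, outcomes)
    point_auroc = auroc(p, y)
    point_slope, point_intercept = calibration_line(p, y, "probability")
    dec_slope, dec_intercept = calibration_line(p, y, "decile_means")
    dec_tab = decile_table(p, y)

    rng = np.random.default_rng(seed)
    n = len(p)
    draws = np.empty((n_bootstrap, 3))
    got = 0
    redraws = 0
    attempts = 0
    while got < n_bootstrap:
        idx = rng.integers(0, n, size=n)
        attempts += 1
        yb = y[idx]
        pb = p[idx]
        if yb.min() == yb.max() or np.ptp(pb) == 0:
            redraws += 1
            if attempts > 2 * n_bootstrap and redraws > attempts / 2:
                raise DegenerateMetricError(
                    f"metrics undefined on {redraws}/{attempts} bootstrap draws"
                )
            continue
        draws[got, 0] = roc_auc_score(yb, pb)
        fit = stats.linregress(pb, yb)
        draws[got, 1] = fit.slope
        draws[got, 2] = fit.intercept
        got += 1
    los, his = np.percentile(draws, [2.5, 97.5], axis=0)

    def ci(point, j):
        return BootstrapCI(
            point=float(point),
            lower=float(los[j]),
            upper=float(his[j]),
            n_draws=n_bootstrap,
            n_redraws=redraws,
            seed=seed,
        )

    return PerformanceReport(
        outcome=outcome,
        score_label=score_label,
        auroc=ci(point_auroc, 0),
        cal_slope=ci(point_slope, 1),
        cal_intercept=ci(point_intercept, 2),
        decile_slope=dec_slope,
        decile_intercept=dec_intercept,
        decile_table=dec_tab,
        n=n,
        n_bootstrap=n_bootstrap,
        seed=seed,
    )


def evaluate_matrix(
    scores: dict[str, Sequence[float]],
    outcomes: dict[str, Sequence[int]],
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> dict[tuple[str, str], PerformanceReport]:
    """The 2×2 score-by-outcome grid of performance reports.

    ``scores`` maps score label (e.g. ``ICISSm30d``) to predicted
    mortality per patient; ``outcomes`` maps outcome name to the
    corresponding 0/1 deaths over the same patients in the same order.
    Each cell gets its own derived seed so reports are independent and
    reproducible.
    """
    reports: dict[tuple[str, str], PerformanceReport] = {}
    for i, (out_name, y) in enumerate(sorted(outcomes.items())):
        for j, (label, p) in enumerate(sorted(scores.items())):
            reports[(out_name, label)] = evaluate_performance(
                p,
                y,
                outcome=out_name,
                score_label=label,
                n_bootstrap=n_bootstrap,
                seed=(seed * 7919 + i * 2 + j) % (2**31 - 1),
            )
    return reports
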