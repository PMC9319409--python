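"""Internal and external QSAR validation metrics and threshold verdicts.

Implements the Golbraikh–Tropsha / Roy metric family used to judge 3D-QSAR
models: through-origin slopes k and k′, the through-origin determination
coefficients r0² and r′0², the r_m² pair and its summary (Δr_m², r̄_m²),
error measures (χ², RMSE, MAE, RSS), and for external test sets the
predictive statistics r_pred² = Q_F1², Q_F2², Q_F3² and Lin's concordance
correlation coefficient Q_ccc.

Conventions (several variants circulate in the literature; these are fixed
here and used consistently):

* k  = Σ y·ŷ / Σ ŷ²,  k′ = Σ y·ŷ / Σ y²
* r0²  = 1 − Σ(y − k ŷ)² / Σ(y − ȳ)²   (observed regressed through origin on
  predicted); r′0² mirrors with roles swapped
* r_m² = r² (1 − sqrt(max(r² − r0², 0))); r′_m² analogous with r′0²;
  the radicand is clipped at zero so adversarial inputs cannot produce
  complex numbers
* χ²  = Σ (y_i − ŷ_i)² / |ŷ_i|
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

# Published acceptance thresholds for field-based QSAR models.
THRESHOLDS: Mapping[str, str] = {
    "q2": "> 0.5",
    "r2": "> 0.6",
    "r_pred2": "> 0.6",
    "q_f1": "> 0.6",
    "k": "0.85–1.15",
    "k_prime": "0.85–1.15",
    "r02_diff": "< 0.3",
    "rel_r02": "< 0.1",
    "rel_r02_prime": "< 0.1",
    "rm2": "> 0.5",
    "rm2_prime": "> 0.5",
    "rm2_bar": "> 0.5",
    "chi2": "< 1.0",
    "rmse": "< 0.5",
}


@dataclass
class ValidationReport:
    """Flat name → value map of validation metrics plus threshold verdicts."""

    metrics: dict[str, float] = field(default_factory=dict)
    verdicts: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.metrics[key]

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps({"metrics": self.metrics, "verdicts": self.verdicts}, indent=2)
        if path is not None:
            Path(path).write_text(doc)
        return doc

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "metric": k,
                "value": v,
                "threshold": THRESHOLDS.get(k, ""),
                "verdict": self.verdicts.get(k, ""),
            }
            for k, v in self.metrics.items()
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = []
        for k, v in self.metrics.items():
            verdict = self.verdicts.get(k, "")
            lines.append(f"{k:>14s} = {v:8.3f}  {verdict}")
        return "\n".join(lines)


def _check_pair(y_obs: np.ndarray, y_pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape or y_obs.ndim != 1:
        raise ValueError("observed and predicted must be 1-D vectors of equal length")
    if y_obs.size < 3:
        raise ValueError("need at least 3 paired values")
    if not (np.all(np.isfinite(y_obs)) and np.all(np.isfinite(y_pred))):
        raise ValueError("non-finite values in observed/predicted vectors")
    if np.ptp(y_obs) == 0 or np.ptp(y_pred) == 0:
        raise ValueError("zero variance in observed or predicted vector")
    return y_obs, y_pred


def rm2_summary(rm2: float, rm2_prime: float) -> tuple[float, float]:
    """(r̄_m², Δr_m²) = ((r_m² + r′_m²)/2, |r_m² − r′_m²|)."""
    return (rm2 + rm2_prime) / 2.0, abs(rm2 - rm2_prime)


def regression_metrics(y_obs, y_pred) -> ValidationReport:
    """The internal validation block for one observed/predicted pairing."""
    y, yh = _check_pair(y_obs, y_pred)
    n = y.size
    resid = y - yh
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_pred = float(((yh - yh.mean()) ** 2).sum())
    rss = float((resid ** 2).sum())
    r = float(stats.pearsonr(y, yh)[0])
    r2 = r * r

    syh2 = float((yh ** 2).sum())
    sy2 = float((y ** 2).sum())
    if syh2 == 0 or sy2 == 0:
        raise ValueError("through-origin slope undefined (zero sum of squares)")
    k = float((y * yh).sum()) / syh2
    k_prime = float((y * yh).sum()) / sy2
    r02 = 1.0 - float(((y - k * yh) ** 2).sum()) / ss_tot
    r02_prime = 1.0 - float(((yh - k_prime * y) ** 2).sum()) / ss_pred

    rm2 = r2 * (1.0 - math.sqrt(max(r2 - r02, 0.0)))
    rm2_prime = r2 * (1.0 - math.sqrt(max(r2 - r02_prime, 0.0)))
    rm2_bar, rm2_diff = rm2_summary(rm2, rm2_prime)

    with np.errstate(divide="ignore"):
        chi2 = float(np.sum(resid ** 2 / np.abs(yh)))
    rmse = float(np.sqrt(rss / n))
    mae = float(np.abs(resid).mean())

    metrics = {
        "r2": r2,
        "k": k,
        "k_prime": k_prime,
        "r02": r02,
        "r02_prime": r02_prime,
        "r02_diff": abs(r02 - r02_prime),
        "rel_r02": (r2 - r02) / r2 if r2 != 0 else float("nan"),
        "rel_r02_prime": (r2 - r02_prime) / r2 if r2 != 0 else float("nan"),
        "rm2": rm2,
        "rm2_prime": rm2_prime,
        "delta_rm2": rm2_diff,
        "rm2_bar": rm2_bar,
        "chi2": chi2,
        "rmse": rmse,
        "mae": mae,
        "rss": rss,
    }
    report = ValidationReport(metrics=metrics)
    report.verdicts = {k_: v for k_, v in threshold_check(report)}
    return report


def external_metrics(y_train, y_test, y_pred_test) -> ValidationReport:
    """External predictivity block: r_pred²/Q_F1², Q_F2², Q_F3² and Q_ccc.

    r_pred² = Q_F1² = 1 − Σ_test(y−ŷ)² / Σ_test(y−ȳ_train)²;
    Q_F2² replaces ȳ_train by ȳ_test in the denominator;
    Q_F3² = 1 − [Σ_test(y−ŷ)²/n_test] / [Σ_train(y−ȳ_train)²/n_train];
    Q_ccc = 2 Σ(y−ȳ)(ŷ−ŷ̄) / [Σ(y−ȳ)² + Σ(ŷ−ŷ̄)² + n(ȳ−ŷ̄)²] over the test
    set (Lin's concordance correlation coefficient).
    """
    y_train = np.asarray(y_train, dtype=float)
    y, yh = _check_pair(y_test, y_pred_test)
    ss_train = float(((y_train - y_train.mean()) ** 2).sum())
    if ss_train <= 0:
        raise ValueError("zero variance in training activities")
    press = float(((y - yh) ** 2).sum())
    qf1 = 1.0 - press / float(((y - y_train.mean()) ** 2).sum())
    qf2 = 1.0 - press / float(((y - y.mean()) ** 2).sum())
    qf3 = 1.0 - (press / y.size) / (ss_train / y_train.size)
    n = y.size
    sxy = float(((y - y.mean()) * (yh - yh.mean())).sum())
    ccc = 2.0 * sxy / (
        float(((y - y.mean()) ** 2).sum())
        + float(((yh - yh.mean()) ** 2).sum())
        + n * (y.mean() - yh.mean()) ** 2
    )
    metrics = {
        "r_pred2": qf1,
        "q_f1": qf1,
        "q_f2": qf2,
        "q_f3": qf3,
        "q_ccc": ccc,
    }
    report = ValidationReport(metrics=metrics)
    report.verdicts = {k: v for k, v in threshold_check(report)}
    return report


def threshold_check(report: ValidationReport) -> list[tuple[str, str]]:
    """Per-metric pass/fail against the published acceptance thresholds.

    Metrics without a published threshold, or absent from the report, come
    back as "not evaluated"; the overall verdict (key ``overall``) is "pass"
    only when every checked metric passes.
    """
    m = report.metrics

    def have(key):
        return key in m and np.isfinite(m[key])

    verdicts: list[tuple[str, str]] = []
    checks = {
        "q2": lambda v: v > 0.5,
        "r2": lambda v: v > 0.6,
        "r_pred2": lambda v: v > 0.6,
        "q_f1": lambda v: v > 0.6,
        "k": lambda v: 0.85 <= v <= 1.15,
        "k_prime": lambda v: 0.85 <= v <= 1.15,
        "r02_diff": lambda v: v < 0.3,
        "rel_r02": lambda v: v < 0.1,
        "rel_r02_prime": lambda v: v < 0.1,
        "rm2": lambda v: v > 0.5,
        "rm2_prime": lambda v: v > 0.5,
        "rm2_bar": lambda v: v > 0.5,
        "chi2": lambda v: v < 1.0,
        "rmse": lambda v: v < 0.5,
    }
    all_pass = True
    any_checked = False
    for key, fn in checks.items():
        if not have(key):
            if key in m:
                verdicts.append((key, "not evaluated"))
            continue
        ok = bool(fn(m[key]))
        any_checked = True
        all_pass &= ok
        verdicts.append((key, "pass" if ok else "fail"))
    for key in m:
        if key not in checks:
            verdicts.append((key, "not evaluated"))
    verdicts.append(("overall", "pass" if (any_checked and all_pass) else
                     ("fail" if any_checked else "not evaluated")))
    return verdicts
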