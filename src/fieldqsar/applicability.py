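"""Leverage-based applicability domain (Williams plot).

A compound lies inside the model's applicability domain when its leverage in
the latent-score space does not exceed the warning leverage
h* = 3(p + 1)/n_train (p = number of latent components) and its standardized
residual stays within ±3.  Leverages are hat-values of the training score
matrix extended with an intercept:

    h_i = 1/n_train + t_iᵀ (TᵀT)⁻¹ t_i

with T the mean-centered training scores; test compounds are projected
through the training rotation and evaluated against the same T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qsar_model import PLSModel


@dataclass
class ADReport:
    """Williams-plot data: per-compound leverage, standardized residual,
    role, and the in-domain flag; ``h_star`` is the warning leverage and
    ``s`` the degrees-of-freedom-corrected training residual scale."""

    frame: pd.DataFrame
    h_star: float
    s: float

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @property
    def n_outliers(self) -> int:
        return int((~self.frame["in_domain"]).sum())


def leverages(model: PLSModel, X_rows: np.ndarray | None = None) -> np.ndarray:
    """Hat-values for raw descriptor rows (default: the training set).

    Computed in score space: rows are centered/scaled/rotated exactly as in
    training, so training-compound leverages sum to ONC + 1.
    """
    T = model.scores
    G = T.T @ T
    cond = np.linalg.cond(G)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError("degenerate training scores (singular TᵀT)")
    Ginv = np.linalg.inv(G)
    t = T if X_rows is None else model.project_rows(X_rows)
    return 1.0 / model.n_train + np.einsum("ij,jk,ik->i", t, Ginv, t)


def warning_leverage(n_train: int, n_components: int) -> float:
    """h* = 3(p + 1)/n: e.g. 15/26 for a 26-compound, 4-component model."""
    return 3.0 * (n_components + 1) / n_train


def williams_data(
    model: PLSModel,
    X_train: np.ndarray | None = None,
    y_train: np.ndarray | None = None,
    X_test: np.ndarray | None = None,
    y_test: np.ndarray | None = None,
    ids_train: list[str] | None = None,
    ids_test: list[str] | None = None,
) -> ADReport:
    """Assemble Williams-plot data for the training set and an optional
    test set.

    Standardized residual = (y − ŷ)/s with s = sqrt(RSS_train/(n − p − 1));
    in_domain ⇔ h ≤ h* and |std. residual| ≤ 3.  Training rows default to
    the data stored in the fitted model.
    """
    if y_train is None:
        y_train = model.y_train
    if y_train is None:
        raise ValueError("training activities unavailable")
    n, p = model.n_train, model.n_components
    dof = n - p - 1
    if dof <= 0:
        raise ValueError("no residual degrees of freedom for standardization")
    s = float(np.sqrt(model.rss / dof))
    if s <= 1e-10 * max(1.0, float(np.abs(y_train).max())):
        s = np.inf  # perfect fit: all standardized residuals are zero
    h_star = warning_leverage(n, p)

    if X_train is None:
        h_tr = leverages(model)
        yhat_tr = _train_predictions(model)
    else:
        h_tr = leverages(model, X_train)
        yhat_tr = model.predict_rows(X_train)
    if ids_train is None:
        ids_train = model.ids_train
    rows = _rows(ids_train, "train", np.asarray(y_train, float), yhat_tr, h_tr, s, h_star)
    if X_test is not None:
        if y_test is None:
            raise ValueError("test activities required with test rows")
        h_te = leverages(model, X_test)
        yhat_te = model.predict_rows(X_test)
        rows += _rows(ids_test, "test", np.asarray(y_test, float), yhat_te, h_te, s, h_star)
    frame = pd.DataFrame(rows)
    return ADReport(frame=frame, h_star=h_star, s=s)


def _train_predictions(model: PLSModel) -> np.ndarray:
    # Exact PLS1 identity: training predictions are the projection of y−ȳ
    # onto the span of the (orthogonal) score columns, ŷ = ȳ + T(TᵀT)⁻¹Tᵀ(y−ȳ).
    y = model.y_train
    T = model.scores
    yc = y - model.y_mean
    coef = np.linalg.solve(T.T @ T, T.T @ yc)
    return model.y_mean + T @ coef


def _rows(ids, role, y, yhat, h, s, h_star):
    ids = ids if ids is not None else [f"{role}{i}" for i in range(len(y))]
    out = []
    for i in range(len(y)):
        std_resid = (y[i] - yhat[i]) / s if np.isfinite(s) else 0.0
        out.append(
            {
                "compound_id": ids[i],
                "role": role,
                "observed": float(y[i]),
                "predicted": float(yhat[i]),
                "leverage": float(h[i]),
                "std_residual": float(std_resid),
                "in_domain": bool(h[i] <= h_star and abs(std_resid) <= 3.0),
            }
        )
    return out


def plot_williams(report: ADReport, path) -> None:
    """Render the Williams plot (leverage vs standardized residual)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for role, marker in (("train", "o"), ("test", "s")):
        sub = report.frame[report.frame["role"] == role]
        if len(sub):
            ax.scatter(sub["leverage"], sub["std_residual"], marker=marker, label=role)
    ax.axhline(3.0, color="r", ls="--", lw=0.8)
    ax.axhline(-3.0, color="r", ls="--", lw=0.8)
    ax.axvline(report.h_star, color="r", ls="--", lw=0.8)
    ax.set_xlabel("leverage h")
    ax.set_ylabel("standardized residual")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
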