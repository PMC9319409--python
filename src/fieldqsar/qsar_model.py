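"""Partial least squares modelling of field descriptors against activity.

PLS1 via the NIPALS deflation scheme: X and y are mean-centered, columns are
*not* autoscaled within a field block (the raw kcal/mol or similarity scale
carries information), and when several field kinds enter one model each block
is divided by its overall standard deviation so that no kind dominates purely
by units.

Model selection follows the classical 3D-QSAR recipe: leave-one-out
cross-validation gives q²(a) = 1 − PRESS(a)/SS_tot per component count a, the
optimal number of components (ONC) is the argmax of q² capped at 6 with ties
broken toward fewer components, and the final model is refit at the ONC on
the full training set.  Column filtering is computed once on the full
training matrix and held fixed across LOO folds.  Bootstrap r² statistics
(mean and SD over row resamples) quantify fit stability.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grid_fields import (
    DescriptorMatrix,
    FieldBlock,
    FieldGrid,
    FieldSettings,
    build_descriptor_matrix,
    compute_field_blocks,
    descriptor_rows,
)
from .molio import AlignedMolecule

logger = logging.getLogger("fieldqsar")

MAX_COMPONENTS = 6  # standard ONC cap for congeneric-series PLS

MODEL_FORMAT_VERSION = 1


class RankError(ValueError):
    """Requested more latent components than the data support."""


def _as_xy(X, y):
    if isinstance(X, DescriptorMatrix):
        mat = X.X
        if y is None:
            y = X.y
    else:
        mat = np.asarray(X, dtype=float)
    if y is None:
        raise ValueError("no activity vector supplied")
    y = np.asarray(y, dtype=float)
    if mat.shape[0] != y.shape[0]:
        raise ValueError("X rows and y length differ")
    return mat, y


def _block_scales(X, col_kind) -> np.ndarray:
    """Per-column divisor implementing block scaling across field kinds."""
    p = X.shape[1]
    scales = np.ones(p)
    if col_kind is None:
        return scales
    kinds = pd.unique(col_kind)
    if len(kinds) < 2:
        return scales
    for k in kinds:
        sel = col_kind == k
        sd = float(X[:, sel].std(ddof=0))
        if sd > 0:
            scales[sel] = sd
    return scales


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_components: int, allow_fewer: bool = False):
    """Mean-centered PLS1.  Returns (W, P, T, q) with columns per component.

    Deflation: t = X w (w the normalized X–y covariance direction),
    p = Xᵀt/tᵀt, q = yᵀt/tᵀt, X ← X − t pᵀ, y ← y − q t.  With
    ``allow_fewer`` the decomposition stops early when the residual rank is
    exhausted instead of raising.
    """
    n, p = Xc.shape
    X = Xc.copy()
    y = yc.copy()
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    achieved = 0
    for a in range(n_components):
        w = X.T @ y
        nw = np.linalg.norm(w)
        exhausted = nw <= 1e-12 * max(1.0, float(np.abs(Xc).max()))
        if not exhausted:
            w = w / nw
            t = X @ w
            tt = float(t @ t)
            exhausted = tt <= 1e-12
        if exhausted:
            if allow_fewer:
                break
            raise RankError(
                f"descriptor matrix supports only {a} latent components "
                f"({n_components} requested)"
            )
        pvec = (X.T @ t) / tt
        qa = float(y @ t) / tt
        X -= np.outer(t, pvec)
        y -= qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, pvec, t, qa
        achieved = a + 1
    return W[:, :achieved], P[:, :achieved], T[:, :achieved], q[:achieved]


def _coefs_per_component(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> list[np.ndarray]:
    """Regression vectors B_a = W_a (P_aᵀ W_a)⁻¹ q_a for a = 1..A."""
    out = []
    for a in range(1, W.shape[1] + 1):
        Wa, Pa, qa = W[:, :a], P[:, :a], q[:a]
        out.append(Wa @ np.linalg.solve(Pa.T @ Wa, qa))
    return out


@dataclass
class PLSModel:
    """A fitted PLS model with its training statistics.

    Coefficients are stored both in the scaled/centered fit space
    (``coef_scaled``) and back-projected to the raw descriptor scale
    (``coef_raw``) so that field-space quantities (StDev*Coeff contributions)
    and latent-space predictions agree identically.
    """

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    scales: np.ndarray
    coef_scaled: np.ndarray
    coef_raw: np.ndarray
    rotation: np.ndarray  # R = W (PᵀW)⁻¹, projects centered rows to scores
    scores: np.ndarray  # training T
    r2: float
    see: float
    f_value: float
    rss: float
    q2: float | None = None
    sep: float | None = None
    q2_per_component: list[float] | None = None
    sep_per_component: list[float] | None = None
    bs_r2: float | None = None
    bs_sd: float | None = None
    field_kinds: tuple[str, ...] | None = None
    field_contributions: dict[str, float] | None = None
    template: DescriptorMatrix | None = None  # column layout for new molecules
    n_train: int = 0
    y_train: np.ndarray | None = None
    ids_train: list[str] | None = None

    def predict_rows(self, X_rows: np.ndarray) -> np.ndarray:
        """Predict activity from raw descriptor rows (active columns)."""
        X_rows = np.atleast_2d(np.asarray(X_rows, dtype=float))
        if X_rows.shape[1] != self.coef_scaled.size:
            raise ValueError(
                f"descriptor rows have {X_rows.shape[1]} columns; the model "
                f"({'+'.join(self.field_kinds or ())}) expects {self.coef_scaled.size}"
            )
        return self.y_mean + (X_rows / self.scales - self.x_mean) @ self.coef_scaled

    def project_rows(self, X_rows: np.ndarray) -> np.ndarray:
        """Latent scores of raw descriptor rows under the training rotation."""
        X_rows = np.atleast_2d(np.asarray(X_rows, dtype=float))
        return (X_rows / self.scales - self.x_mean) @ self.rotation

    def predict_molecules(self, mols: Sequence[AlignedMolecule]) -> np.ndarray:
        if self.template is None:
            raise ValueError("model carries no descriptor template")
        return self.predict_rows(descriptor_rows(mols, self.template))

    # -- persistence ------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        tpl = self.template
        doc = {
            "format_version": MODEL_FORMAT_VERSION,
            "n_components": self.n_components,
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "scales": self.scales.tolist(),
            "coef_scaled": self.coef_scaled.tolist(),
            "coef_raw": self.coef_raw.tolist(),
            "rotation": self.rotation.tolist(),
            "scores": self.scores.tolist(),
            "stats": {
                "r2": self.r2, "see": self.see, "f_value": self.f_value,
                "rss": self.rss, "q2": self.q2, "sep": self.sep,
                "bs_r2": self.bs_r2, "bs_sd": self.bs_sd,
            },
            "q2_per_component": self.q2_per_component,
            "sep_per_component": self.sep_per_component,
            "field_kinds": list(self.field_kinds) if self.field_kinds else None,
            "field_contributions": self.field_contributions,
            "n_train": self.n_train,
            "y_train": None if self.y_train is None else self.y_train.tolist(),
            "ids_train": self.ids_train,
            "template": None
            if tpl is None
            else {
                "field_kinds": list(tpl.field_kinds),
                "mask": tpl.mask.astype(int).tolist(),
                "col_kind": tpl.col_kind.tolist(),
                "col_point": tpl.col_point.tolist(),
                "impute_means": {str(k): v for k, v in tpl.impute_means.items()},
                "grid": {
                    "origin": list(tpl.grid.origin),
                    "spacing": tpl.grid.spacing,
                    "npoints": list(tpl.grid.npoints),
                },
                "settings": tpl.settings.__dict__,
            },
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "PLSModel":
        doc = json.loads(Path(path).read_text())
        if doc.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model file version")
        tpl = None
        if doc["template"] is not None:
            t = doc["template"]
            grid = FieldGrid(
                tuple(t["grid"]["origin"]), t["grid"]["spacing"], tuple(t["grid"]["npoints"])
            )
            settings = FieldSettings(**t["settings"])
            tpl = DescriptorMatrix(
                X=np.empty((0, len(t["col_kind"]))),
                field_kinds=tuple(t["field_kinds"]),
                col_kind=np.array(t["col_kind"]),
                col_point=np.array(t["col_point"], dtype=int),
                mask=np.array(t["mask"], dtype=bool),
                grid=grid,
                settings=settings,
                impute_means={int(k): v for k, v in t["impute_means"].items()},
            )
        s = doc["stats"]
        return cls(
            n_components=doc["n_components"],
            x_mean=np.array(doc["x_mean"]),
            y_mean=doc["y_mean"],
            scales=np.array(doc["scales"]),
            coef_scaled=np.array(doc["coef_scaled"]),
            coef_raw=np.array(doc["coef_raw"]),
            rotation=np.array(doc["rotation"]),
            scores=np.array(doc["scores"]),
            r2=s["r2"], see=s["see"], f_value=s["f_value"], rss=s["rss"],
            q2=s["q2"], sep=s["sep"], bs_r2=s["bs_r2"], bs_sd=s["bs_sd"],
            q2_per_component=doc["q2_per_component"],
            sep_per_component=doc["sep_per_component"],
            field_kinds=None if doc["field_kinds"] is None else tuple(doc["field_kinds"]),
            field_contributions=doc["field_contributions"],
            template=tpl,
            n_train=doc["n_train"],
            y_train=None if doc["y_train"] is None else np.array(doc["y_train"]),
            ids_train=doc["ids_train"],
        )


def fit_pls(X, y=None, n_components: int = 2) -> PLSModel:
    """Fit a PLS1 model with ``n_components`` latent components.

    ``X`` may be a :class:`DescriptorMatrix` (block scaling and the column
    template are taken from it) or a plain array.  r² = 1 − RSS/SS_tot,
    SEE = sqrt(RSS/(n − a − 1)), F = [r²/a] / [(1 − r²)/(n − a − 1)].
    """
    mat, yv = _as_xy(X, y)
    n = mat.shape[0]
    if n_components < 1:
        raise ValueError("need at least one latent component")
    if n < n_components + 2:
        raise RankError(
            f"n_train={n} too small for {n_components} components (need ≥ a+2)"
        )
    ssy = float(((yv - yv.mean()) ** 2).sum())
    if ssy <= 0:
        raise ValueError("zero-variance activity vector")
    col_kind = X.col_kind if isinstance(X, DescriptorMatrix) else None
    scales = _block_scales(mat, col_kind)
    Xs = mat / scales
    x_mean = Xs.mean(axis=0)
    y_mean = float(yv.mean())
    W, P, T, q = _nipals_pls1(Xs - x_mean, yv - y_mean, n_components)
    R = W @ np.linalg.inv(P.T @ W)
    coef_scaled = R @ q
    coef_raw = coef_scaled / scales
    yhat = y_mean + (Xs - x_mean) @ coef_scaled
    rss = float(((yv - yhat) ** 2).sum())
    r2 = 1.0 - rss / ssy
    dof = n - n_components - 1
    see = float(np.sqrt(rss / dof)) if dof > 0 else float("nan")
    f_value = (r2 / n_components) / ((1.0 - r2) / dof) if dof > 0 and r2 < 1 else float("inf")
    contributions = None
    if col_kind is not None:
        contributions = field_contribution_fractions(mat, coef_raw, col_kind)
    template = X if isinstance(X, DescriptorMatrix) else None
    return PLSModel(
        n_components=n_components,
        x_mean=x_mean,
        y_mean=y_mean,
        scales=scales,
        coef_scaled=coef_scaled,
        coef_raw=coef_raw,
        rotation=R,
        scores=T,
        r2=r2,
        see=see,
        f_value=f_value,
        rss=rss,
        field_kinds=tuple(X.field_kinds) if isinstance(X, DescriptorMatrix) else None,
        field_contributions=contributions,
        template=template,
        n_train=n,
        y_train=yv.copy(),
        ids_train=list(X.ids) if isinstance(X, DescriptorMatrix) and X.ids else None,
    )


def field_contribution_fractions(
    X: np.ndarray, coef_raw: np.ndarray, col_kind: np.ndarray
) -> dict[str, float]:
    """Relative field contributions: Σ|coef·stdev| per kind / grand total.

    This is the standard percentage decomposition printed alongside CoMFA and
    CoMSIA statistics (e.g. steric vs electrostatic share of the model).
    """
    sd = X.std(axis=0, ddof=0)
    weight = np.abs(coef_raw * sd)
    total = float(weight.sum())
    out: dict[str, float] = {}
    for k in pd.unique(col_kind):
        share = float(weight[col_kind == k].sum())
        out[str(k)] = 100.0 * share / total if total > 0 else 0.0
    return out


@dataclass
class LOOResult:
    """Per-component LOO cross-validation statistics and the selected ONC."""

    q2: np.ndarray  # (A,) q² for a = 1..A
    sep: np.ndarray
    press: np.ndarray
    onc: int

    @property
    def q2_onc(self) -> float:
        return float(self.q2[self.onc - 1])

    @property
    def sep_onc(self) -> float:
        return float(self.sep[self.onc - 1])


def loo_q2(X, y=None, max_components: int = MAX_COMPONENTS) -> LOOResult:
    """Leave-one-out cross-validation over 1..max_components components.

    PRESS(a) = Σ_i (y_i − ŷ_{−i,a})² with the model refit on the n−1
    remaining samples (column filtering and block scales held fixed from the
    full training matrix); q²(a) = 1 − PRESS(a)/SS_tot;
    SEP(a) = sqrt(PRESS(a)/(n − a − 1)).  ONC = argmax q², ties toward
    fewer components, capped at 6.
    """
    mat, yv = _as_xy(X, y)
    n = mat.shape[0]
    if n < 4:
        raise ValueError("LOO cross-validation needs at least 4 samples")
    A = int(min(max_components, MAX_COMPONENTS, n - 2))
    if A < 1:
        raise RankError("too few samples for any component")
    col_kind = X.col_kind if isinstance(X, DescriptorMatrix) else None
    scales = _block_scales(mat, col_kind)  # frozen from the full set
    Xs = mat / scales
    press = np.zeros(A)
    achieved = A
    fold_preds = np.full((n, A), np.nan)
    for i in range(n):
        keep = np.arange(n) != i
        Xi, yi = Xs[keep], yv[keep]
        xm = Xi.mean(axis=0)
        ym = float(yi.mean())
        W, P, T, q = _nipals_pls1(Xi - xm, yi - ym, A, allow_fewer=True)
        if W.shape[1] == 0:
            raise RankError(f"LOO fold {i}: descriptor matrix has no usable direction")
        achieved = min(achieved, W.shape[1])
        for a, B in enumerate(_coefs_per_component(W, P, q), start=1):
            fold_preds[i, a - 1] = ym + (Xs[i] - xm) @ B
    if achieved < A:
        logger.debug("LOO: component count capped at %d by fold rank", achieved)
        A = achieved
        fold_preds = fold_preds[:, :A]
    press = ((yv[:, None] - fold_preds) ** 2).sum(axis=0)
    ss = float(((yv - yv.mean()) ** 2).sum())
    q2 = 1.0 - press / ss
    dof = n - np.arange(1, A + 1) - 1
    sep = np.sqrt(press / dof)
    onc = int(np.argmax(q2)) + 1  # argmax takes the first (fewest) on ties
    return LOOResult(q2=q2, sep=sep, press=press, onc=onc)


def bootstrap_r2(
    X, y=None, n_components: int = 2, n_boot: int = 100, seed: int = 0
) -> tuple[float, float, int]:
    """Bootstrap the training r²: mean (BS-r²) and SD (BS-SD) over ``n_boot``
    row resamples with replacement.  Degenerate resamples (zero activity
    variance or rank collapse) are redrawn; the redraw count is returned.
    """
    mat, yv = _as_xy(X, y)
    rng = np.random.default_rng(seed)
    n = mat.shape[0]
    r2s = []
    redraws = 0
    while len(r2s) < n_boot:
        idx = rng.integers(0, n, size=n)
        ys = yv[idx]
        if np.ptp(ys) <= 0:
            redraws += 1
            continue
        try:
            m = fit_pls(mat[idx], ys, n_components)
        except RankError:
            redraws += 1
            continue
        r2s.append(m.r2)
    if redraws:
        logger.warning("bootstrap_r2: %d degenerate resamples redrawn", redraws)
    arr = np.array(r2s)
    return float(arr.mean()), float(arr.std(ddof=1)), redraws


def train_model(
    X: DescriptorMatrix,
    y: np.ndarray | None = None,
    max_components: int = MAX_COMPONENTS,
    n_boot: int = 100,
    seed: int = 0,
) -> PLSModel:
    """LOO component selection + final fit + bootstrap, in one call."""
    loo = loo_q2(X, y, max_components)
    model = fit_pls(X, y, loo.onc)
    model.q2 = loo.q2_onc
    model.sep = loo.sep_onc
    model.q2_per_component = loo.q2.tolist()
    model.sep_per_component = loo.sep.tolist()
    if n_boot > 0:
        bs_mean, bs_sd, _ = bootstrap_r2(X, y, loo.onc, n_boot=n_boot, seed=seed)
        model.bs_r2, model.bs_sd = bs_mean, bs_sd
    return model


def field_combination_search(
    mols: Sequence[AlignedMolecule],
    grid: FieldGrid,
    candidate_kinds: Sequence[str],
    y: np.ndarray | None = None,
    settings: FieldSettings = FieldSettings(),
    max_components: int = MAX_COMPONENTS,
    blocks: Mapping[str, FieldBlock] | None = None,
) -> pd.DataFrame:
    """Evaluate every non-empty subset of ``candidate_kinds`` by LOO q².

    Returns the full ranked table (columns: combination, n_fields, q2, onc,
    sep), best first; ties broken by fewer fields, then fewer components.
    Field blocks are computed once and shared across combinations.
    """
    candidate_kinds = list(candidate_kinds)
    if not candidate_kinds:
        raise ValueError("no candidate field kinds supplied")
    if y is None:
        y = np.array([m.pic50 for m in mols], dtype=float)
    if blocks is None:
        blocks = compute_field_blocks(mols, grid, candidate_kinds, settings)
    rows = []
    for r in range(1, len(candidate_kinds) + 1):
        for combo in itertools.combinations(candidate_kinds, r):
            try:
                dm = build_descriptor_matrix(
                    mols, grid, combo, settings, blocks={k: blocks[k] for k in combo}
                )
                loo = loo_q2(dm, y, max_components)
            except (ValueError, RankError) as exc:
                logger.warning("combination %s skipped: %s", "+".join(combo), exc)
                continue
            rows.append(
                {
                    "combination": "+".join(combo),
                    "n_fields": r,
                    "q2": loo.q2_onc,
                    "onc": loo.onc,
                    "sep": loo.sep_onc,
                }
            )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no field combination produced a usable model")
    df = df.sort_values(
        ["q2", "n_fields", "onc"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return df
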