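"""StDev*Coeff contour extraction and SAR region reporting.

The per-grid-point contribution of a fitted field model is the product of the
column's standard deviation over the training molecules and its
back-projected (raw-scale) PLS regression coefficient — the quantity
conventionally contoured to show where bulky/charged/hydrophobic substitution
is predicted to raise or lower activity.  Favored and disfavored regions are
cut at fixed percentiles of the positive- and negative-side contribution
distributions (80/20 by default, the customary display levels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid_fields import DescriptorMatrix, FieldGrid, write_dx
from .qsar_model import PLSModel


@dataclass
class ContourSet:
    """Favored/disfavored lattice points for one field kind.

    ``table`` lists every active grid point with its contribution;
    ``favored``/``disfavored`` are disjoint subsets of its rows.
    """

    field_kind: str
    table: pd.DataFrame  # columns: point, x, y, z, contribution
    favored_level: float
    disfavored_level: float
    favored: pd.DataFrame = field(default_factory=pd.DataFrame)
    disfavored: pd.DataFrame = field(default_factory=pd.DataFrame)


def stdev_coeff(model: PLSModel, X: DescriptorMatrix) -> pd.DataFrame:
    """Per-active-column contribution map: stdev(column) × raw coefficient.

    Returns a DataFrame with one row per active column (field_kind, flat
    grid point index, coordinates, contribution).
    """
    if X.p != model.coef_raw.size:
        raise ValueError("descriptor matrix does not match the model's columns")
    sd = X.X.std(axis=0, ddof=0)
    contrib = sd * model.coef_raw
    pts = X.grid.points()[X.col_point]
    return pd.DataFrame(
        {
            "field_kind": X.col_kind,
            "point": X.col_point,
            "x": pts[:, 0],
            "y": pts[:, 1],
            "z": pts[:, 2],
            "contribution": contrib,
        }
    )


def extract_contours(
    contrib: pd.DataFrame,
    favored_pct: float = 80.0,
    disfavored_pct: float = 20.0,
) -> dict[str, ContourSet]:
    """Cut each field kind's contribution map into favored/disfavored sets.

    Convention (linear-interpolation percentiles): the favored level is the
    ``favored_pct`` percentile of the strictly positive contributions and the
    favored set is every point at or above it; the disfavored level is the
    ``disfavored_pct`` percentile of the strictly negative contributions and
    the disfavored set is every point at or below it.  A kind with no
    positive (negative) mass gets an empty favored (disfavored) set.
    """
    if contrib.empty:
        raise ValueError("empty contribution map")
    out: dict[str, ContourSet] = {}
    for kind, sub in contrib.groupby("field_kind", sort=False):
        vals = sub["contribution"].to_numpy()
        pos = vals[vals > 0]
        neg = vals[vals < 0]
        fav_level = float(np.percentile(pos, favored_pct)) if pos.size else np.inf
        dis_level = float(np.percentile(neg, disfavored_pct)) if neg.size else -np.inf
        favored = sub[sub["contribution"] >= fav_level] if pos.size else sub.iloc[0:0]
        disfavored = sub[sub["contribution"] <= dis_level] if neg.size else sub.iloc[0:0]
        out[str(kind)] = ContourSet(
            field_kind=str(kind),
            table=sub.reset_index(drop=True),
            favored_level=fav_level if pos.size else float("nan"),
            disfavored_level=dis_level if neg.size else float("nan"),
            favored=favored.reset_index(drop=True),
            disfavored=disfavored.reset_index(drop=True),
        )
    return out


def export_contour_dx(contours: ContourSet, grid: FieldGrid, path) -> None:
    """Write the full contribution map of one field kind as an OpenDX grid
    (inactive lattice points carry 0)."""
    vals = np.zeros(grid.n_total)
    vals[contours.table["point"].to_numpy()] = contours.table["contribution"].to_numpy()
    write_dx(path, vals, grid, comment=f"StDev*Coeff {contours.field_kind}")


def export_contour_pdb(contours: ContourSet, path) -> int:
    """Write favored/disfavored points as PDB pseudo-atoms (residues FAV and
    DIS) for viewer overlay; returns the number of pseudo-atoms written."""
    lines = []
    serial = 0
    for resname, sub in (("FAV", contours.favored), ("DIS", contours.disfavored)):
        for _, row in sub.iterrows():
            serial += 1
            lines.append(
                f"HETATM{serial:5d}  DU  {resname} A{serial:4d}    "
                f"{row['x']:8.3f}{row['y']:8.3f}{row['z']:8.3f}"
                f"{1.00:6.2f}{row['contribution']:6.2f}          DU"
            )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return serial


def contour_summary(contours: dict[str, ContourSet]) -> pd.DataFrame:
    rows = []
    for kind, cs in contours.items():
        rows.append(
            {
                "field_kind": kind,
                "n_points": len(cs.table),
                "n_favored": len(cs.favored),
                "n_disfavored": len(cs.disfavored),
                "favored_level": cs.favored_level,
                "disfavored_level": cs.disfavored_level,
            }
        )
    return pd.DataFrame(rows)
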