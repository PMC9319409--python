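"""Binding-affinity post-processing over per-complex energy tables.

The simulation machinery that produces binding-energy components (end-state
MM-PB/GBSA terms, steered-pulling rupture forces, bound/unbound interaction
energies, alchemical estimates) lives upstream; this module implements the
arithmetic layered on top of those tables:

* experimental affinities: ΔG_EXP = −RT·ln10 · pIC50 (and its inverse),
* the linear interaction energy combination ΔG_LIE = ½ΔE_cou + ½ΔE_vdW over
  the bound→unbound change,
* the MM-PB/GBSA assembly ΔG = ΔE_vdW + ΔE_ELE + ΔE_GB + ΔE_SA − TΔS,
* experimental-vs-computed Pearson correlations with bootstrap standard
  errors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .molio import EnergyTable

logger = logging.getLogger("fieldqsar")

GAS_CONSTANT = 1.98720425e-3  # kcal/(mol·K)

MMPBSA_REQUIRED = ("e_vdw", "e_ele", "e_gb", "e_sa")


@dataclass(frozen=True)
class ThermoSettings:
    """Thermodynamic conversion settings.

    300 K is the customary simulation-thermostat target; at 300 K one pIC50
    log unit is RT·ln10 ≈ 1.3722 kcal/mol.
    """

    temperature: float = 300.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def rt_ln10(self) -> float:
        return GAS_CONSTANT * self.temperature * math.log(10.0)


def pic50_to_dg(pic50, thermo: ThermoSettings = ThermoSettings()):
    """ΔG_EXP (kcal/mol) from pIC50: ΔG = −RT·ln10 · pIC50."""
    return -thermo.rt_ln10 * np.asarray(pic50, dtype=float)


def dg_to_pic50(dg, thermo: ThermoSettings = ThermoSettings()):
    """Inverse of :func:`pic50_to_dg`; the round trip is exact."""
    return -np.asarray(dg, dtype=float) / thermo.rt_ln10


def lie_energy(e_bound: tuple[float, float], e_unbound: tuple[float, float]) -> float:
    """ΔG_LIE = ½ΔE_cou + ½ΔE_vdW with ΔE = E_unbound − E_bound.

    Inputs are (E_vdW, E_cou) pairs for the bound and unbound ligand states.
    """
    evdw_b, ecou_b = (float(v) for v in e_bound)
    evdw_u, ecou_u = (float(v) for v in e_unbound)
    for v in (evdw_b, ecou_b, evdw_u, ecou_u):
        if not math.isfinite(v):
            raise ValueError("non-finite LIE input term")
    return 0.5 * (ecou_u - ecou_b) + 0.5 * (evdw_u - evdw_b)


def mmpbsa_total(components: dict[str, float], t_ds: float = 0.0) -> float:
    """ΔG_MM-PB/GBSA = ΔE_vdW + ΔE_ELE + ΔE_GB + ΔE_SA − TΔS.

    ``components`` keys are case-insensitive (E_vdW, E_ELE, E_GB, E_SA).  The
    equivalent grouping ΔE_MM + ΔG_sol − TΔS (ΔE_MM = vdW + ELE,
    ΔG_sol = GB + SA) is cross-checked by construction.
    """
    comp = {k.lower(): float(v) for k, v in components.items()}
    missing = [k for k in MMPBSA_REQUIRED if k not in comp]
    if missing:
        raise KeyError(f"missing MM-PB/GBSA component(s): {missing}")
    e_mm = comp["e_vdw"] + comp["e_ele"]
    g_sol = comp["e_gb"] + comp["e_sa"]
    total = e_mm + g_sol - float(t_ds)
    term_sum = comp["e_vdw"] + comp["e_ele"] + comp["e_gb"] + comp["e_sa"] - float(t_ds)
    assert abs(total - term_sum) < 1e-9
    return total


@dataclass
class CorrelationResult:
    """Pearson correlation between two energy columns with a bootstrap SE."""

    x_name: str
    y_name: str
    n: int
    excluded: list[str]
    r: float
    se: float
    n_boot: int
    seed: int
    redraws: int = 0

    def __post_init__(self) -> None:
        assert -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12
        assert self.se >= 0


def correlate(
    table: EnergyTable,
    x: str,
    y: str,
    exclude: set[str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> CorrelationResult:
    """Pearson R between two columns with listwise missing-value removal.

    ``exclude`` names complexes left out of the analysis (e.g. a mutant
    receptor row when correlating wild-type affinities).  The bootstrap SE is
    the standard deviation of R over ``n_boot`` row resamples with
    replacement; resamples where either column degenerates to zero variance
    are redrawn and counted.
    """
    exclude = set(exclude or ())
    xs = table.column(x)
    ys = table.column(y)
    keep = [i for i in table.ids if i not in exclude]
    xv = xs.loc[keep].to_numpy(dtype=float)
    yv = ys.loc[keep].to_numpy(dtype=float)
    ok = np.isfinite(xv) & np.isfinite(yv)
    xv, yv = xv[ok], yv[ok]
    used = [k for k, o in zip(keep, ok) if o]
    n = xv.size
    if n < 3:
        raise ValueError(f"need at least 3 paired values for {x!r} vs {y!r} (got {n})")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError(f"zero variance in {x!r} or {y!r}")
    r = float(stats.pearsonr(xv, yv)[0])
    rng = np.random.default_rng(seed)
    rs = []
    redraws = 0
    while len(rs) < n_boot:
        idx = rng.integers(0, n, size=n)
        xb, yb = xv[idx], yv[idx]
        if np.ptp(xb) == 0 or np.ptp(yb) == 0:
            redraws += 1
            continue
        rs.append(float(stats.pearsonr(xb, yb)[0]))
    if redraws:
        logger.warning("correlate(%s, %s): %d degenerate resamples redrawn", x, y, redraws)
    se = float(np.std(rs, ddof=1)) if n_boot > 1 else 0.0
    return CorrelationResult(
        x_name=x, y_name=y, n=n, excluded=sorted(exclude), r=r, se=se,
        n_boot=n_boot, seed=seed, redraws=redraws,
    )


def correlation_report(
    table: EnergyTable,
    pairs: list[tuple[str, str]],
    exclude: set[str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Batch :func:`correlate` over column pairs into one report frame."""
    rows = []
    for x, y in pairs:
        res = correlate(table, x, y, exclude=exclude, n_boot=n_boot, seed=seed)
        rows.append(
            {
                "x": x, "y": y, "n": res.n, "r": res.r, "bootstrap_se": res.se,
                "n_boot": n_boot, "seed": seed,
                "excluded": ";".join(res.excluded),
            }
        )
    return pd.DataFrame(rows, columns=["x", "y", "n", "r", "bootstrap_se", "n_boot", "seed", "excluded"])
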