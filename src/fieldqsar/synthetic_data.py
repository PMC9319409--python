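"""Synthetic congeneric series with a planted field–activity relationship.

Every stage of the field-QSAR pipeline is testable without external data by
generating a controlled stand-in for a kinase-inhibitor analogue series: a
fixed planar pteridinone-like bicyclic scaffold with three substitution
sites (R1–R3), a small hand-built substituent library, and activities that
are by construction a linear function of Gaussian (CoMSIA-style) steric and
hydrophobic field values at designated probe points near the substitution
sites, affinely mapped to a target pIC50 span and perturbed with Gaussian
noise.

The library is deliberately structured so that steric and hydrophobic
information is not recoverable from the electrostatic pattern alone (e.g. a
chloro- and a fluoro-like group share their charge but differ in size;
methyl- and tert-butyl-like groups are both charge-neutral), which makes the
field-combination search a meaningful recovery problem.

Chemical realism is secondary to controlled field structure: geometries are
idealized, some heavy-atom hydrogens are omitted, and bond orders are
uniformly single.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .grid_fields import FieldSettings, comsia_at_points
from .molio import ActivityTable, AlignedMolecule, Atom, EnergyTable, assign_atom_params

logger = logging.getLogger("fieldqsar")

# ---------------------------------------------------------------------------
# Scaffold: planar fused 6-6 bicycle with a lactam-like carbonyl and three
# substitution sites, idealized 1.40 Å ring geometry in the z = 0 plane.
# ---------------------------------------------------------------------------
_SCAFFOLD_ATOMS: list[tuple[str, tuple[float, float, float], float]] = [
    ("C", (1.212, 0.700, 0.0), 0.10),    # 0: ring-fusion carbon
    ("N", (0.000, 1.400, 0.0), -0.30),   # 1
    ("C", (-1.212, 0.700, 0.0), 0.05),   # 2: R1 site
    ("C", (-1.212, -0.700, 0.0), 0.05),  # 3: R2 site
    ("N", (0.000, -1.400, 0.0), -0.30),  # 4
    ("C", (1.212, -0.700, 0.0), 0.10),   # 5: ring-fusion carbon
    ("N", (2.424, 1.400, 0.0), -0.30),   # 6
    ("C", (3.636, 0.700, 0.0), 0.40),    # 7: carbonyl carbon
    ("C", (3.636, -0.700, 0.0), 0.05),   # 8: R3 site
    ("N", (2.424, -1.400, 0.0), -0.25),  # 9: lactam nitrogen
    ("O", (4.720, 1.330, 0.0), -0.45),   # 10: carbonyl oxygen
    ("H", (2.424, -2.490, 0.0), 0.30),   # 11: lactam N–H
]
_SCAFFOLD_BONDS = [
    (0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0),
    (0, 6), (6, 7), (7, 8), (8, 9), (9, 5), (7, 10), (9, 11),
]

# Substitution sites: (scaffold atom index, outward unit vector in-plane).
_SITES: list[tuple[int, np.ndarray]] = [
    (2, np.array([-0.866, 0.500, 0.0])),   # R1
    (3, np.array([-0.866, -0.500, 0.0])),  # R2
    (8, np.array([0.866, -0.500, 0.0])),   # R3
]

# Substituent library: name -> list of (element, (u, v, w) local offsets Å,
# partial charge).  u points outward along the attachment vector, v is the
# in-plane perpendicular, w the out-of-plane axis.
SUBSTITUENT_LIBRARY: dict[str, list[tuple[str, tuple[float, float, float], float]]] = {
    "hydro": [("H", (1.09, 0.0, 0.0), 0.06)],
    "methyl": [
        ("C", (1.50, 0.0, 0.0), -0.18),
        ("H", (2.10, 0.90, 0.0), 0.06),
        ("H", (2.10, -0.45, 0.90), 0.06),
        ("H", (2.10, -0.45, -0.90), 0.06),
    ],
    # tbutyl/phosbutyl and chloro/phospho are hydrophobicity twins: identical
    # geometry, matched charges, near-equal vdW radii (C 1.70/P 1.80,
    # Cl 1.75/P 1.80 Å) and no donor/acceptor flags, but opposite-signed
    # hydrophobic weights — only the hydrophobic field separates each pair
    "tbutyl": [
        ("C", (1.50, 0.0, 0.0), 0.0),
        ("C", (2.20, 1.25, 0.0), 0.0),
        ("C", (2.20, -0.70, 1.10), 0.0),
        ("C", (2.20, -0.70, -1.10), 0.0),
    ],
    "phosbutyl": [
        ("P", (1.50, 0.0, 0.0), 0.0),
        ("P", (2.20, 1.25, 0.0), 0.0),
        ("P", (2.20, -0.70, 1.10), 0.0),
        ("P", (2.20, -0.70, -1.10), 0.0),
    ],
    "chloro": [("Cl", (1.75, 0.0, 0.0), -0.10)],
    "phospho": [("P", (1.80, 0.0, 0.0), -0.10)],
    "hydroxyl": [
        ("O", (1.40, 0.0, 0.0), -0.40),
        ("H", (1.95, 0.85, 0.0), 0.35),
    ],
    "amino": [
        ("N", (1.40, 0.0, 0.0), -0.50),
        ("H", (1.95, 0.85, 0.0), 0.28),
        ("H", (1.95, -0.55, 0.75), 0.28),
    ],
}

PLANTED_KINDS = ("comsia_S", "comsia_H")


def _probe_points() -> np.ndarray:
    """Two fixed probe positions per substitution site (6 total).

    One near probe (1.5 Å out along the attachment axis, saturated by the
    first substituent atom) and one far probe (4.0 Å out, sensing substituent
    extent) so the two positions report different aspects of the group.
    """
    pts = []
    for idx, u in _SITES:
        attach = np.array(_SCAFFOLD_ATOMS[idx][1])
        pts.append(attach + 1.5 * u)
        pts.append(attach + 4.0 * u)
    return np.array(pts)


@dataclass
class SeriesSpec:
    """Study conditions for the synthetic analogue series.

    Defaults emulate the real series this pipeline is designed for: ~35
    analogues of one scaffold, activities spanning three log units
    (pIC50 5.26–8.80), and residual noise of 0.3 log units around a linear
    steric+hydrophobic field–activity relationship.
    """

    n_compounds: int = 35
    noise_sigma: float = 0.3
    activity_span: tuple[float, float] = (5.26, 8.80)
    seed: int = 0
    coefficients: np.ndarray | None = None  # per (probe point × planted kind)
    substituents: Sequence[str] = tuple(SUBSTITUENT_LIBRARY)

    def __post_init__(self) -> None:
        if self.n_compounds < 10:
            raise ValueError("need at least 10 compounds")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        lo, hi = self.activity_span
        if not lo < hi:
            raise ValueError("activity span low must be below high")


@dataclass
class SplitSpec:
    """Activity-stratified train/test split conditions (default 26/9)."""

    n_test: int = 9
    seed: int = 0


@dataclass
class GroundTruth:
    """The planted generative model, for recovery tests."""

    probe_points: np.ndarray
    kinds: tuple[str, ...]
    coefficients: np.ndarray  # raw signal scale, per (kind, point) flattened
    mapped_coefficients: np.ndarray  # after the affine span mapping
    probe_features: np.ndarray  # compounds × (kind, point) field values
    signal: np.ndarray  # noiseless mapped activity per compound
    noise: np.ndarray
    patterns: list[tuple[str, str, str]]

    def to_json(self, path: str | Path) -> None:
        doc = {
            "probe_points": self.probe_points.tolist(),
            "kinds": list(self.kinds),
            "coefficients": self.coefficients.tolist(),
            "mapped_coefficients": self.mapped_coefficients.tolist(),
            "probe_features": self.probe_features.tolist(),
            "signal": self.signal.tolist(),
            "noise": self.noise.tolist(),
            "patterns": [list(p) for p in self.patterns],
        }
        Path(path).write_text(json.dumps(doc))


def _build_molecule(cid: str, pattern: Sequence[str]) -> AlignedMolecule:
    atoms = [Atom(el, pos, q) for el, pos, q in _SCAFFOLD_ATOMS]
    bonds = list(_SCAFFOLD_BONDS)
    for (site_idx, u), sub_name in zip(_SITES, pattern):
        attach = np.array(_SCAFFOLD_ATOMS[site_idx][1])
        v = np.array([-u[1], u[0], 0.0])
        w = np.array([0.0, 0.0, 1.0])
        frame = np.stack([u, v, w])
        first = len(atoms)
        for j, (el, local, q) in enumerate(SUBSTITUENT_LIBRARY[sub_name]):
            pos = attach + np.asarray(local) @ frame
            atoms.append(Atom(el, tuple(pos), q))
            bonds.append((site_idx if j == 0 else first, first + j))
    return AlignedMolecule(cid, atoms, bonds)


def generate_series(
    spec: SeriesSpec = SeriesSpec(),
) -> tuple[list[AlignedMolecule], ActivityTable, GroundTruth]:
    """Generate the synthetic series and its planted ground truth.

    Substitution patterns (one substituent per site) are sampled without
    replacement; the noiseless activity is a linear function of the steric
    and hydrophobic Gaussian field values at six fixed probe points, affinely
    mapped so the noiseless signal attains the target span exactly; Gaussian
    noise (``noise_sigma`` log units) is then added.  Fully reproducible from
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    subs = list(spec.substituents)
    all_patterns = list(itertools.product(subs, repeat=len(_SITES)))
    if len(all_patterns) < spec.n_compounds:
        raise ValueError(
            f"substituent library yields {len(all_patterns)} patterns, "
            f"fewer than n_compounds={spec.n_compounds}"
        )
    pick = rng.choice(len(all_patterns), size=spec.n_compounds, replace=False)
    patterns = [all_patterns[i] for i in sorted(pick)]

    mols = [
        assign_atom_params(_build_molecule(f"S{i + 1:02d}", pat))
        for i, pat in enumerate(patterns)
    ]

    probes = _probe_points()
    settings = FieldSettings()
    feats = np.zeros((len(mols), probes.shape[0] * len(PLANTED_KINDS)))
    for i, mol in enumerate(mols):
        vals = comsia_at_points(mol, probes, PLANTED_KINDS, settings)
        feats[i] = np.concatenate([vals[k] for k in PLANTED_KINDS])

    if spec.coefficients is not None:
        coefs = np.asarray(spec.coefficients, dtype=float)
        if coefs.shape != (feats.shape[1],):
            raise ValueError(f"need {feats.shape[1]} planted coefficients")
    else:
        coefs = rng.uniform(0.5, 1.5, size=feats.shape[1]) * rng.choice(
            [-1.0, 1.0], size=feats.shape[1]
        )
        # balance the planted kinds: rescale each kind's coefficients so the
        # kinds contribute equal signal variance (the field-contribution
        # split of the emulated models is close to 50/50)
        n_probe = probes.shape[0]
        for k in range(len(PLANTED_KINDS)):
            sl = slice(k * n_probe, (k + 1) * n_probe)
            sd_k = float((feats[:, sl] @ coefs[sl]).std())
            if sd_k > 0:
                coefs[sl] /= sd_k
    raw = feats @ coefs
    lo, hi = spec.activity_span
    if np.ptp(raw) <= 0:
        raise ValueError("planted signal is constant; cannot map to activity span")
    slope = (hi - lo) / np.ptp(raw)
    signal = lo + slope * (raw - raw.min())
    noise = rng.normal(0.0, spec.noise_sigma, size=len(mols))
    pic50 = signal + noise
    for mol, act in zip(mols, pic50):
        mol.pic50 = float(act)
    activities = ActivityTable([m.id for m in mols], pic50)
    truth = GroundTruth(
        probe_points=probes,
        kinds=PLANTED_KINDS,
        coefficients=coefs,
        mapped_coefficients=slope * coefs,
        probe_features=feats,
        signal=signal,
        noise=noise,
        patterns=patterns,
    )
    return mols, activities, truth


def split_train_test(
    activities: ActivityTable, spec: SplitSpec = SplitSpec()
) -> tuple[list[str], list[str]]:
    """Activity-stratified split: rank by pIC50, cut into low/medium/high
    tertiles, and draw test compounds from each tertile proportionally
    (remainders go to the largest tertiles), without replacement.
    """
    n = len(activities.ids)
    if not 0 < spec.n_test < n:
        raise ValueError("n_test must be strictly between 0 and n_compounds")
    if n < spec.n_test + 4:
        raise ValueError("too few compounds to leave a usable training set")
    rng = np.random.default_rng(spec.seed)
    order = np.argsort(activities.pic50, kind="stable")
    tertiles = np.array_split(order, 3)
    sizes = np.array([len(t) for t in tertiles], dtype=float)
    exact = spec.n_test * sizes / n
    counts = np.floor(exact).astype(int)
    # remainders to the largest tertiles (ties by lower activity segment)
    for _ in range(spec.n_test - counts.sum()):
        k = int(np.argmax(sizes - counts))
        counts[k] += 1
    test_idx: list[int] = []
    for t, c in zip(tertiles, counts):
        c = min(c, len(t))
        test_idx.extend(rng.choice(t, size=c, replace=False).tolist())
    if len(test_idx) < spec.n_test:  # an emptied tertile: reallocate
        logger.warning("split_train_test: reallocating %d test picks", spec.n_test - len(test_idx))
        remaining = [i for i in order if i not in set(test_idx)]
        extra = rng.choice(remaining, size=spec.n_test - len(test_idx), replace=False)
        test_idx.extend(extra.tolist())
    test_set = set(test_idx)
    test_ids = [activities.ids[i] for i in sorted(test_idx)]
    train_ids = [cid for i, cid in enumerate(activities.ids) if i not in test_set]
    return train_ids, test_ids


def generate_energy_table(
    n: int,
    target_r: float | Sequence[float] = 0.9,
    scales: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    columns: Sequence[str] = ("dg_mmpbsa",),
) -> EnergyTable:
    """Synthetic per-complex energy table with planted correlations.

    ``dg_exp`` and each computed column form bivariate-normal pairs with
    population correlation ``target_r`` (a scalar, or one value per computed
    column), affinely mapped to the per-column (mean, sd) in ``scales``.
    """
    if n < 4:
        raise ValueError("need at least 4 complexes")
    rs = np.broadcast_to(np.asarray(target_r, dtype=float), (len(columns),))
    if np.any(np.abs(rs) >= 1):
        raise ValueError("target correlations must lie strictly inside (-1, 1)")
    scales = scales or {}
    rng = np.random.default_rng(seed)
    z0 = rng.standard_normal(n)
    mean_x, sd_x = scales.get("dg_exp", (-10.0, 1.5))
    data = {"complex_id": [f"X{i + 1:03d}" for i in range(n)],
            "dg_exp": mean_x + sd_x * z0}
    for col, r in zip(columns, rs):
        e = rng.standard_normal(n)
        z = r * z0 + np.sqrt(1.0 - r * r) * e
        mean_y, sd_y = scales.get(col, (-27.0, 4.5))
        data[col] = mean_y + sd_y * z
    return EnergyTable(pd.DataFrame(data))
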