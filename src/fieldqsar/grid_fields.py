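"""Molecular interaction fields on a lattice and descriptor-matrix assembly.

Implements the two classical field families of ligand-based 3D-QSAR:

* CoMFA-style probe interaction energies — a Lennard-Jones steric field and a
  Coulomb electrostatic field with distance-dependent dielectric, evaluated by
  an sp³-carbon-like probe of radius 1.52 Å carrying +1 e, truncated at
  ±30 kcal/mol;
* CoMSIA-style Gaussian similarity indices — steric (S), electrostatic (E),
  hydrophobic (H), H-bond donor (D) and acceptor (A) fields
  A_k(q) = −Σ_i w_probe,k · w_ik · exp(−α r_iq²) with attenuation α = 0.3 Å⁻²
  and no distance cutoff.

The descriptor matrix stacks one block per field kind (molecules × grid
points), imputes electrostatic values at sterically excluded points with the
column mean, and drops near-constant columns below a per-kind standard
deviation floor (2.0 kcal/mol for CoMFA energies, 0.05 for similarity
indices).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .molio import AlignedMolecule

logger = logging.getLogger("fieldqsar")

COULOMB_CONSTANT = 332.0636  # kcal·Å/(mol·e²)

COMFA_KINDS = ("comfa_steric", "comfa_electrostatic")
COMSIA_KINDS = ("comsia_S", "comsia_E", "comsia_H", "comsia_D", "comsia_A")
ALL_KINDS = COMFA_KINDS + COMSIA_KINDS


class DegenerateMatrixError(ValueError):
    """All descriptor columns were filtered out."""


@dataclass(frozen=True)
class FieldGrid:
    """Rectilinear lattice: ``origin`` + ``spacing`` × index, x-fastest order."""

    origin: tuple[float, float, float]
    spacing: float
    npoints: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if any(n < 1 for n in self.npoints):
            raise ValueError("grid needs at least one point per axis")

    @property
    def n_total(self) -> int:
        nx, ny, nz = self.npoints
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """All lattice points, shape (n_total, 3), x index varying fastest."""
        nx, ny, nz = self.npoints
        ix = np.arange(nx)
        iy = np.arange(ny)
        iz = np.arange(nz)
        # x-fastest: flat index = ix + nx*(iy + ny*iz)
        gz, gy, gx = np.meshgrid(iz, iy, ix, indexing="ij")
        idx = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
        return np.asarray(self.origin) + self.spacing * idx


@dataclass(frozen=True)
class FieldSettings:
    """Probe and truncation parameters for field evaluation.

    Defaults follow the standard method settings: +1 e probe of vdW radius
    1.52 Å, ±30 kcal/mol energy truncation, distance-dependent dielectric
    ε(r) = r, Gaussian attenuation α = 0.3 Å⁻².  The probe's LJ well depth is
    the sp³-carbon value from the frozen element table.
    """

    probe_charge: float = 1.0
    probe_radius: float = 1.52
    probe_well_depth: float = 0.0860
    energy_cutoff: float = 30.0
    attenuation: float = 0.3
    sigma_min_comfa: float = 2.0
    sigma_min_comsia: float = 0.05

    def __post_init__(self) -> None:
        if self.energy_cutoff <= 0:
            raise ValueError("energy cutoff must be positive")
        if self.attenuation <= 0:
            raise ValueError("attenuation must be positive")

    def sigma_min(self, kind: str) -> float:
        return self.sigma_min_comfa if kind.startswith("comfa") else self.sigma_min_comsia


@dataclass
class FieldBlock:
    """Values of one field kind over molecules × grid points.

    For ``comfa_electrostatic``, ``excluded`` marks lattice points inside the
    steric envelope (untruncated steric energy above +cutoff) where the
    electrostatic value is meaningless and later imputed column-wise.
    """

    field_kind: str
    values: np.ndarray  # (n_molecules, n_points)
    grid: FieldGrid
    excluded: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in {self.field_kind} field block")


def build_grid(
    mols: Sequence[AlignedMolecule], spacing: float = 2.0, margin: float = 4.0
) -> FieldGrid:
    """Lattice enclosing all atom centres plus ``margin`` on every side.

    The origin is anchored at floor(min − margin) per axis so the grid is
    reproducible regardless of sub-Å jitter in the bounding box.
    """
    if not mols:
        raise ValueError("cannot build a grid for an empty molecule list")
    coords = np.vstack([m.coords for m in mols])
    lo = np.floor(coords.min(axis=0) - margin)
    hi = coords.max(axis=0) + margin
    npoints = tuple(int(np.ceil((hi[k] - lo[k]) / spacing)) + 1 for k in range(3))
    return FieldGrid(origin=tuple(lo), spacing=float(spacing), npoints=npoints)


# ---------------------------------------------------------------------------
# Field evaluation
# ---------------------------------------------------------------------------

def _distances(mol: AlignedMolecule, grid: FieldGrid) -> np.ndarray:
    """Atom–point distance matrix, shape (n_atoms, n_points)."""
    pts = grid.points()
    diff = mol.coords[:, None, :] - pts[None, :, :]
    return np.sqrt(np.sum(diff * diff, axis=2))


def comfa_fields(
    mol: AlignedMolecule, grid: FieldGrid, settings: FieldSettings = FieldSettings()
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lennard-Jones steric and Coulomb electrostatic probe energies.

    Returns ``(steric, electrostatic, excluded)`` rows over grid points.
    Steric: Σ_i ε_i* [(R_i*/r)¹² − 2 (R_i*/r)⁶] with R_i* = r_vdW,i + r_probe
    and ε_i* = sqrt(ε_i ε_probe), truncated to ±cutoff; a probe exactly on an
    atom centre counts as inside the atom (+cutoff).  Electrostatic:
    Σ_i 332.0636 q_i q_probe / r² (distance-dependent dielectric ε(r) = r),
    truncated to ±cutoff; at sterically excluded points the value is replaced
    downstream by the column mean.
    """
    r = _distances(mol, grid)
    cutoff = settings.energy_cutoff
    radii = np.array([a.vdw_radius for a in mol.atoms]) + settings.probe_radius
    eps = np.sqrt(np.array([a.well_depth for a in mol.atoms]) * settings.probe_well_depth)
    with np.errstate(divide="ignore", over="ignore"):
        ratio6 = (radii[:, None] / np.where(r > 0, r, np.inf)) ** 6
        steric_terms = eps[:, None] * (ratio6 * ratio6 - 2.0 * ratio6)
        steric_raw = steric_terms.sum(axis=0)
        on_center = (r == 0).any(axis=0)
        steric_raw = np.where(on_center, np.inf, steric_raw)
        elec_raw = (
            COULOMB_CONSTANT
            * settings.probe_charge
            * (mol.charges[:, None] / np.where(r > 0, r * r, np.inf)).sum(axis=0)
        )
        # a probe on an atom centre is sterically excluded; pin its
        # electrostatic value at the (signed) cap pending imputation
        elec_raw = np.where(on_center, np.sign(elec_raw) * cutoff, elec_raw)
    excluded = steric_raw > cutoff
    steric = np.clip(steric_raw, -cutoff, cutoff)
    elec = np.clip(elec_raw, -cutoff, cutoff)
    return steric, elec, excluded


_COMSIA_WEIGHTS = {
    "comsia_S": lambda a: a.steric_weight,
    "comsia_E": lambda a: a.partial_charge,
    "comsia_H": lambda a: a.hydrophobicity,
    "comsia_D": lambda a: 1.0 if a.is_donor else 0.0,
    "comsia_A": lambda a: 1.0 if a.is_acceptor else 0.0,
}


def comsia_at_points(
    mol: AlignedMolecule,
    points: np.ndarray,
    kinds: Sequence[str] = COMSIA_KINDS,
    settings: FieldSettings = FieldSettings(),
) -> dict[str, np.ndarray]:
    """Gaussian similarity indices at arbitrary probe positions."""
    for kind in kinds:
        if kind not in _COMSIA_WEIGHTS:
            raise ValueError(f"unknown CoMSIA field kind {kind!r}")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    diff = mol.coords[:, None, :] - pts[None, :, :]
    r2 = np.sum(diff * diff, axis=2)
    gauss = np.exp(-settings.attenuation * r2)
    out: dict[str, np.ndarray] = {}
    for kind in kinds:
        w = np.array([_COMSIA_WEIGHTS[kind](a) for a in mol.atoms])
        if not np.all(np.isfinite(w)):
            raise ValueError(f"missing atom parameters for CoMSIA kind {kind!r}")
        out[kind] = -(w[:, None] * gauss).sum(axis=0)
    return out


def comsia_fields(
    mol: AlignedMolecule,
    grid: FieldGrid,
    settings: FieldSettings = FieldSettings(),
    kinds: Sequence[str] = COMSIA_KINDS,
) -> dict[str, np.ndarray]:
    """Gaussian similarity indices A_k(q) = −Σ_i w_ik exp(−α r_iq²) over the
    lattice.

    Probe weights are +1 for every kind (the electrostatic probe carries
    +1 e); there is no distance cutoff.
    """
    return comsia_at_points(mol, grid.points(), kinds, settings)


def compute_field_blocks(
    mols: Sequence[AlignedMolecule],
    grid: FieldGrid,
    kinds: Sequence[str],
    settings: FieldSettings = FieldSettings(),
) -> dict[str, FieldBlock]:
    """Evaluate the requested field kinds for every molecule."""
    blocks: dict[str, np.ndarray] = {k: np.empty((len(mols), grid.n_total)) for k in kinds}
    excl = np.zeros((len(mols), grid.n_total), dtype=bool)
    want_comfa = [k for k in kinds if k in COMFA_KINDS]
    want_comsia = [k for k in kinds if k in COMSIA_KINDS]
    bad = set(kinds) - set(ALL_KINDS)
    if bad:
        raise ValueError(f"unknown field kind(s): {sorted(bad)}")
    for i, mol in enumerate(mols):
        if want_comfa:
            steric, elec, ex = comfa_fields(mol, grid, settings)
            if "comfa_steric" in blocks:
                blocks["comfa_steric"][i] = steric
            if "comfa_electrostatic" in blocks:
                blocks["comfa_electrostatic"][i] = elec
            excl[i] = ex
        if want_comsia:
            rows = comsia_fields(mol, grid, settings, want_comsia)
            for k, v in rows.items():
                blocks[k][i] = v
    out = {}
    for k in kinds:
        out[k] = FieldBlock(
            k, blocks[k], grid, excluded=excl.copy() if k == "comfa_electrostatic" else None
        )
    return out


# ---------------------------------------------------------------------------
# Descriptor matrix
# ---------------------------------------------------------------------------

@dataclass
class DescriptorMatrix:
    """Filtered molecules × (grid point × field kind) design matrix.

    ``X`` holds only surviving columns; ``col_kind``/``col_point`` map each
    active column back to its field kind and flat grid index; ``mask`` is the
    keep-flag over the unfiltered column layout (kind blocks concatenated in
    ``field_kinds`` order); ``impute_means`` stores, for electrostatic
    columns, the training column mean used at sterically excluded points.
    """

    X: np.ndarray
    field_kinds: tuple[str, ...]
    col_kind: np.ndarray  # (p_active,) str
    col_point: np.ndarray  # (p_active,) int flat grid index
    mask: np.ndarray  # (p_raw,) bool
    grid: FieldGrid
    settings: FieldSettings
    impute_means: dict[int, float] = dc_field(default_factory=dict)  # raw col -> mean
    y: np.ndarray | None = None
    ids: list[str] | None = None

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, row_idx: Sequence[int]) -> "DescriptorMatrix":
        idx = np.asarray(row_idx, dtype=int)
        return replace(
            self,
            X=self.X[idx],
            y=None if self.y is None else self.y[idx],
            ids=None if self.ids is None else [self.ids[i] for i in idx],
        )


def build_descriptor_matrix(
    mols: Sequence[AlignedMolecule],
    grid: FieldGrid,
    field_kinds: Sequence[str],
    settings: FieldSettings = FieldSettings(),
    blocks: Mapping[str, FieldBlock] | None = None,
    sigma_min: Mapping[str, float] | None = None,
) -> DescriptorMatrix:
    """Assemble and filter the design matrix for the given field kinds.

    Column operations, in order: (1) electrostatic entries at sterically
    excluded points are replaced by the column mean over non-excluded
    molecules (all-excluded columns fall back to 0 and are dropped by the
    variance filter); (2) columns with standard deviation below the per-kind
    floor are dropped.  Deterministic for fixed input.
    """
    field_kinds = tuple(field_kinds)
    if blocks is None:
        blocks = compute_field_blocks(mols, grid, field_kinds, settings)
    cols: list[np.ndarray] = []
    kinds_meta: list[str] = []
    points_meta: list[int] = []
    mask_parts: list[np.ndarray] = []
    impute: dict[int, float] = {}
    raw_offset = 0
    for kind in field_kinds:
        blk = blocks[kind]
        vals = blk.values.copy()
        if kind == "comfa_electrostatic" and blk.excluded is not None:
            ex = blk.excluded
            for j in np.flatnonzero(ex.any(axis=0)):
                ok = ~ex[:, j]
                mean = float(vals[ok, j].mean()) if ok.any() else 0.0
                vals[ex[:, j], j] = mean
                impute[raw_offset + j] = mean
        sd = vals.std(axis=0, ddof=0)
        keep = sd >= settings.sigma_min(kind) if sigma_min is None else sd >= sigma_min.get(
            kind, settings.sigma_min(kind)
        )
        mask_parts.append(keep)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.debug("field %s: filtered %d/%d columns", kind, n_drop, keep.size)
        cols.append(vals[:, keep])
        kinds_meta.extend([kind] * int(keep.sum()))
        points_meta.extend(np.flatnonzero(keep).tolist())
        raw_offset += vals.shape[1]
    X = np.hstack(cols) if cols else np.empty((len(mols), 0))
    if X.shape[1] == 0:
        raise DegenerateMatrixError(
            "no descriptor columns survive the variance filter"
        )
    pic50 = np.array([m.pic50 for m in mols], dtype=float) if all(
        m.pic50 is not None for m in mols
    ) else None
    return DescriptorMatrix(
        X=X,
        field_kinds=field_kinds,
        col_kind=np.array(kinds_meta),
        col_point=np.array(points_meta, dtype=int),
        mask=np.concatenate(mask_parts),
        grid=grid,
        settings=settings,
        impute_means=impute,
        y=pic50,
        ids=[m.id for m in mols],
    )


def descriptor_rows(
    mols: Sequence[AlignedMolecule], template: DescriptorMatrix
) -> np.ndarray:
    """Field rows for new molecules aligned to a training matrix's columns.

    Uses the template's grid, settings, field kinds and column mask; at
    sterically excluded electrostatic points the stored training column mean
    is imputed.
    """
    blocks = compute_field_blocks(
        mols, template.grid, template.field_kinds, template.settings
    )
    cols: list[np.ndarray] = []
    raw_offset = 0
    mask = template.mask
    for kind in template.field_kinds:
        blk = blocks[kind]
        vals = blk.values.copy()
        if kind == "comfa_electrostatic" and blk.excluded is not None:
            ex = blk.excluded
            for j in np.flatnonzero(ex.any(axis=0)):
                mean = template.impute_means.get(raw_offset + j, 0.0)
                vals[ex[:, j], j] = mean
        keep = mask[raw_offset : raw_offset + vals.shape[1]]
        cols.append(vals[:, keep])
        raw_offset += vals.shape[1]
    return np.hstack(cols)


# ---------------------------------------------------------------------------
# OpenDX export
# ---------------------------------------------------------------------------

def write_dx(path: str | Path, values: np.ndarray, grid: FieldGrid, comment: str = "") -> None:
    """Write one scalar field over the grid as an OpenDX file for viewers.

    ``values`` is a flat vector in the package's x-fastest point order; DX
    stores z-fastest, so the data are transposed on output.
    """
    values = np.asarray(values, dtype=float)
    if values.size != grid.n_total:
        raise ValueError("value vector does not match the grid size")
    nx, ny, nz = grid.npoints
    # x-fastest flat order -> (z, y, x) array -> transpose to (x, y, z)
    arr = values.reshape(nz, ny, nx).transpose(2, 1, 0)
    d = grid.spacing
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {grid.origin[0]:.6f} {grid.origin[1]:.6f} {grid.origin[2]:.6f}\n")
        fh.write(f"delta {d:.6f} 0 0\ndelta 0 {d:.6f} 0\ndelta 0 0 {d:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {values.size} data follows\n"
        )
        flat = arr.ravel()
        for start in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[start : start + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "field" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')
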