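"""Molecule, activity and energy-table I/O for field-based 3D-QSAR.

Molecules enter the pipeline pre-aligned in a common Cartesian frame with
partial charges already assigned (or computable); this module reads them from
SDF (V2000) or MOL2, attaches per-atom field parameters (van der Waals radius,
steric weight, hydrophobicity, H-bond donor/acceptor flags) from frozen
element/atom-type tables, and parses the CSV activity and energy-component
tables consumed downstream.

Coordinates are Å throughout, charges in elementary-charge units, energies in
kcal/mol.  No re-alignment, protonation or conformer generation is performed:
a shared alignment frame is a caller contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("fieldqsar")


class FormatError(ValueError):
    """Raised when an input file cannot be parsed as the named format."""


class ParameterizationError(KeyError):
    """Raised when an element is missing from the active parameter tables."""


# ---------------------------------------------------------------------------
# Frozen per-element parameter tables
# ---------------------------------------------------------------------------
# van der Waals radii (Å): Bondi, J. Phys. Chem. 68 (1964) 441.
BONDI_VDW_RADII: Mapping[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}

# Lennard-Jones well depths (kcal/mol): GAFF/parm94-style atomic defaults.
LJ_WELL_DEPTHS: Mapping[str, float] = {
    "H": 0.0157, "C": 0.0860, "N": 0.1700, "O": 0.2100, "F": 0.0610,
    "P": 0.2000, "S": 0.2500, "Cl": 0.2650, "Br": 0.3200, "I": 0.4000,
}

# Atom-typed hydrophobicity increments (dimensionless, Ghose/Crippen-flavoured
# coarse graining): apolar carbons and their hydrogens positive, polar and
# charged heavy atoms negative, halogens mildly positive.
HYDROPHOBICITY: Mapping[str, float] = {
    "C": 0.50, "H": 0.10, "H_polar": -0.20, "N": -0.50, "O": -0.50,
    "F": 0.30, "Cl": 0.40, "Br": 0.40, "I": 0.40, "S": 0.20, "P": -0.20,
}

PARAM_SETS = ("bondi",)  # single frozen set; name kept for provenance


@dataclass(frozen=True)
class Atom:
    """One atom of an aligned molecule with its field parameters.

    ``steric_weight`` (Å³ scale, = r_vdW³) and ``hydrophobicity`` are the
    per-atom weights of the Gaussian similarity fields; ``vdw_radius`` and
    ``well_depth`` parameterize the Lennard-Jones probe interaction.
    """

    element: str
    position: tuple[float, float, float]
    partial_charge: float
    vdw_radius: float = 0.0
    well_depth: float = 0.0
    steric_weight: float = 0.0
    hydrophobicity: float = 0.0
    is_donor: bool = False
    is_acceptor: bool = False


@dataclass
class AlignedMolecule:
    """A pre-aligned 3D structure with partial charges and optional activity.

    ``bonds`` holds 0-based atom index pairs; adjacency is needed only for
    donor/acceptor typing and polar-hydrogen detection.
    """

    id: str
    atoms: list[Atom]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    pic50: float | None = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"molecule {self.id!r} has no atoms")
        coords = self.coords
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"molecule {self.id!r} has non-finite coordinates")
        if not all(np.isfinite(a.partial_charge) for a in self.atoms):
            raise ValueError(f"molecule {self.id!r} has non-finite charges")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    def neighbor_elements(self, i: int) -> list[str]:
        out = []
        for a, b in self.bonds:
            if a == i:
                out.append(self.atoms[b].element)
            elif b == i:
                out.append(self.atoms[a].element)
        return out


@dataclass
class ActivityTable:
    """Compound id → pIC50 mapping (−log10 molar IC50)."""

    ids: list[str]
    pic50: np.ndarray

    def __post_init__(self) -> None:
        self.pic50 = np.asarray(self.pic50, dtype=float)
        if len(self.ids) != len(self.pic50):
            raise ValueError("ids and pIC50 lengths differ")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate compound ids in activity table")
        if not np.all(np.isfinite(self.pic50)):
            raise ValueError("non-finite pIC50 values")

    def lookup(self, cid: str) -> float:
        return float(self.pic50[self.ids.index(cid)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"compound_id": self.ids, "pic50": self.pic50})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ActivityTable":
        return cls(list(df.iloc[:, 0].astype(str)), df.iloc[:, 1].to_numpy(float))


# Recognized energy-table columns (case-insensitive header match).
_ENERGY_COLUMNS = {
    "dg_exp": "dg_exp",
    "dg_mmpbsa": "dg_mmpbsa",
    "dg_mm_pbgbsa": "dg_mmpbsa",
    "fmax": "fmax",
    "fmax_pn": "fmax",
    "dg_lie": "dg_lie",
    "dg_fep": "dg_fep",
}
_ID_COLUMNS = {"complex_id", "complex", "id", "compound_id"}


@dataclass
class EnergyTable:
    """Per-complex experimental and computed binding-energy terms.

    Standard columns (kcal/mol except ``fmax`` in pN): ``dg_exp``,
    ``dg_mmpbsa``, ``fmax``, ``dg_lie``, ``dg_fep``.  Any further numeric
    columns (e.g. MM-PB/GBSA components E_vdW, E_ELE, E_GB, E_SA, TΔS or
    bound/unbound LIE terms) ride along in ``frame`` and are addressable by
    name.  Missing cells are NaN and mean "absent", never zero.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if "complex_id" not in self.frame.columns:
            raise ValueError("energy table needs a complex_id column")
        ids = self.frame["complex_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate complex id {dup!r} in energy table")
        num = self.frame.drop(columns=["complex_id"])
        arr = num.to_numpy(dtype=float)
        if np.any(np.isinf(arr)):
            raise ValueError("infinite value in energy table")

    @property
    def ids(self) -> list[str]:
        return list(self.frame["complex_id"])

    def __len__(self) -> int:
        return len(self.frame)

    def column(self, name: str) -> pd.Series:
        if name not in self.frame.columns:
            avail = [c for c in self.frame.columns if c != "complex_id"]
            raise KeyError(f"unknown column {name!r}; available: {avail}")
        return self.frame.set_index("complex_id")[name]


# ---------------------------------------------------------------------------
# Atom parameter assignment
# ---------------------------------------------------------------------------

def assign_atom_params(mol: AlignedMolecule, param_set: str = "bondi") -> AlignedMolecule:
    """Attach vdW radii, LJ well depths, CoMSIA weights and donor/acceptor
    flags to every atom, from the frozen element tables.

    Idempotent: parameters depend only on element and bonded neighbours.
    Rules: steric weight = r_vdW³; hydrogens on N/O are donors (and take the
    polar-hydrogen hydrophobicity); N and O bearing a lone pair are acceptors
    (N with four bonds is not); carbons and their hydrogens are hydrophobic.
    """
    if param_set not in PARAM_SETS:
        raise ValueError(f"unknown parameter set {param_set!r}; available: {PARAM_SETS}")
    unknown = sorted({a.element for a in mol.atoms} - set(BONDI_VDW_RADII))
    if unknown:
        raise ParameterizationError(
            f"element(s) {unknown} not in parameter set {param_set!r}"
        )
    degree = {i: len(mol.neighbor_elements(i)) for i in range(len(mol.atoms))}
    new_atoms: list[Atom] = []
    for i, a in enumerate(mol.atoms):
        el = a.element
        r = BONDI_VDW_RADII[el]
        eps = LJ_WELL_DEPTHS[el]
        neigh = mol.neighbor_elements(i)
        polar_h = el == "H" and any(n in ("N", "O", "S") for n in neigh)
        if el == "H":
            hyd = HYDROPHOBICITY["H_polar"] if polar_h else HYDROPHOBICITY["H"]
        else:
            hyd = HYDROPHOBICITY[el]
        donor = polar_h
        acceptor = el == "O" or (el == "N" and degree[i] < 4)
        new_atoms.append(
            replace(
                a,
                vdw_radius=r,
                well_depth=eps,
                steric_weight=r ** 3,
                hydrophobicity=hyd,
                is_donor=donor,
                is_acceptor=acceptor,
            )
        )
    return AlignedMolecule(mol.id, new_atoms, list(mol.bonds), mol.pic50)


# ---------------------------------------------------------------------------
# SDF reading/writing (RDKit-backed)
# ---------------------------------------------------------------------------

_CHARGE_PROP = "PartialCharge"


def _mol_from_rdkit(rdmol, idx: int) -> AlignedMolecule:
    from rdkit import Chem

    name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
    mid = name.strip() or f"mol{idx}"
    conf = rdmol.GetConformer()
    coords = conf.GetPositions()
    if (not conf.Is3D()) and np.allclose(coords[:, 2], 0.0, atol=1e-6):
        raise FormatError(f"record {mid!r}: 2D coordinates (flat, flagged 2D)")
    if all(a.HasProp(_CHARGE_PROP) for a in rdmol.GetAtoms()):
        charges = [a.GetDoubleProp(_CHARGE_PROP) for a in rdmol.GetAtoms()]
    else:
        charges = _gasteiger_charges(rdmol, mid)
    atoms = [
        Atom(
            element=a.GetSymbol(),
            position=tuple(coords[a.GetIdx()]),
            partial_charge=float(charges[a.GetIdx()]),
        )
        for a in rdmol.GetAtoms()
    ]
    bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in rdmol.GetBonds()]
    return AlignedMolecule(mid, atoms, bonds)


def _gasteiger_charges(rdmol, mid: str) -> list[float]:
    # Documented fallback charge model when the file carries none: Gasteiger
    # (PEOE) charges as implemented in RDKit, on the sanitized molecule.
    from rdkit import Chem
    from rdkit.Chem import AllChem

    m = Chem.Mol(rdmol)
    try:
        Chem.SanitizeMol(m)
        AllChem.ComputeGasteigerCharges(m)
        charges = [a.GetDoubleProp("_GasteigerCharge") for a in m.GetAtoms()]
    except Exception as exc:  # pragma: no cover - depends on rdkit internals
        raise FormatError(
            f"record {mid!r}: no per-atom charges in file and Gasteiger "
            f"assignment failed ({exc})"
        ) from exc
    if not all(np.isfinite(c) for c in charges):
        raise FormatError(f"record {mid!r}: Gasteiger charges non-finite")
    return charges


def _read_sdf(path: Path) -> list[AlignedMolecule]:
    from rdkit import Chem

    suppl = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    try:
        suppl.SetProcessPropertyLists(True)
    except AttributeError:  # older rdkit: property lists applied by default
        pass
    mols: list[AlignedMolecule] = []
    for idx, rdmol in enumerate(suppl):
        if rdmol is None:
            raise FormatError(f"{path}: SDF record {idx} failed to parse")
        if rdmol.GetNumConformers() == 0:
            raise FormatError(f"{path}: SDF record {idx} has no coordinates")
        mols.append(_mol_from_rdkit(rdmol, idx))
    if not mols:
        raise FormatError(f"{path}: no SDF records found")
    return mols


def write_sdf(mols: Sequence[AlignedMolecule], path: str | Path) -> None:
    """Write molecules to V2000 SDF with per-atom charges as an
    ``atom.dprop.PartialCharge`` property list (round-trips through
    :func:`read_molecules`)."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    writer = Chem.SDWriter(str(path))
    writer.SetForceV3000(False)
    for mol in mols:
        rw = Chem.RWMol()
        for a in mol.atoms:
            ra = Chem.Atom(a.element)
            ra.SetNoImplicit(True)
            rw.AddAtom(ra)
        for i, j in mol.bonds:
            rw.AddBond(int(i), int(j), Chem.BondType.SINGLE)
        m = rw.GetMol()
        conf = Chem.Conformer(len(mol.atoms))
        for i, a in enumerate(mol.atoms):
            conf.SetAtomPosition(i, Point3D(*a.position))
        conf.Set3D(True)
        m.AddConformer(conf)
        for i, a in enumerate(mol.atoms):
            m.GetAtomWithIdx(i).SetDoubleProp(_CHARGE_PROP, a.partial_charge)
        Chem.CreateAtomDoublePropertyList(m, _CHARGE_PROP)
        m.SetProp("_Name", mol.id)
        writer.write(m)
    writer.close()


# ---------------------------------------------------------------------------
# MOL2 reading
# ---------------------------------------------------------------------------
# A dedicated line-oriented reader: MOL2 carries the per-atom charges in
# column 9 of @<TRIPOS>ATOM, which general-purpose readers drop or retype,
# and parse errors must name the offending line.

def _read_mol2(path: Path) -> list[AlignedMolecule]:
    text = Path(path).read_text()
    lines = text.splitlines()
    mols: list[AlignedMolecule] = []
    i = 0
    n = len(lines)
    while i < n:
        if lines[i].strip() != "@<TRIPOS>MOLECULE":
            i += 1
            continue
        name = lines[i + 1].strip() or f"mol{len(mols)}"
        i += 2
        atoms: list[Atom] = []
        bonds: list[tuple[int, int]] = []
        section = None
        while i < n and not (section and lines[i].strip() == "@<TRIPOS>MOLECULE"):
            line = lines[i].strip()
            if line.startswith("@<TRIPOS>"):
                if line == "@<TRIPOS>MOLECULE":
                    break
                section = line[len("@<TRIPOS>"):]
                i += 1
                continue
            if section == "ATOM" and line:
                parts = line.split()
                if len(parts) < 6:
                    raise FormatError(
                        f"{path}: malformed @<TRIPOS>ATOM record at line {i + 1}: {line!r}"
                    )
                try:
                    x, y, z = (float(parts[2]), float(parts[3]), float(parts[4]))
                    charge = float(parts[8]) if len(parts) > 8 else 0.0
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: malformed @<TRIPOS>ATOM record at line {i + 1}: {line!r}"
                    ) from exc
                element = parts[5].split(".")[0].capitalize()
                atoms.append(Atom(element=element, position=(x, y, z), partial_charge=charge))
            elif section == "BOND" and line:
                parts = line.split()
                if len(parts) < 3:
                    raise FormatError(
                        f"{path}: malformed @<TRIPOS>BOND record at line {i + 1}: {line!r}"
                    )
                try:
                    bonds.append((int(parts[1]) - 1, int(parts[2]) - 1))
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: malformed @<TRIPOS>BOND record at line {i + 1}: {line!r}"
                    ) from exc
            i += 1
        if not atoms:
            raise FormatError(f"{path}: molecule {name!r} has no @<TRIPOS>ATOM block")
        mols.append(AlignedMolecule(name, atoms, bonds))
    if not mols:
        raise FormatError(f"{path}: no @<TRIPOS>MOLECULE records found")
    return mols


def read_molecules(
    path: str | Path,
    fmt: str | None = None,
    param_set: str = "bondi",
) -> list[AlignedMolecule]:
    """Read pre-aligned molecules from SDF or MOL2 and assign field parameters.

    Charges come from the file when present (SDF ``atom.dprop.PartialCharge``
    property lists; MOL2 charge column), otherwise from Gasteiger assignment.
    ``fmt`` defaults to the file suffix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "sdf":
        mols = _read_sdf(path)
    elif fmt == "mol2":
        mols = _read_mol2(path)
    else:
        raise FormatError(f"unsupported molecule format {fmt!r} (expected sdf or mol2)")
    return [assign_atom_params(m, param_set) for m in mols]


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def read_activities(path: str | Path) -> ActivityTable:
    """Read a (compound id, pIC50) CSV with a header row."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: activity CSV needs id and pIC50 columns")
    return ActivityTable.from_frame(df)


def read_energy_table(path: str | Path) -> EnergyTable:
    """Read a per-complex energy CSV (Table-1-style layout).

    Recognized headers map to the standard columns; unknown numeric columns
    are preserved as extra terms.  Missing cells stay missing (NaN).
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if df.empty and df.shape[1] == 0:
        raise ValueError(f"{path}: empty file, header required")
    rename: dict[str, str] = {}
    id_col = None
    for col in df.columns:
        key = col.strip().lower().replace("-", "_").replace(" ", "_")
        if key in _ID_COLUMNS and id_col is None:
            id_col = col
            rename[col] = "complex_id"
        elif key in _ENERGY_COLUMNS:
            rename[col] = _ENERGY_COLUMNS[key]
        else:
            rename[col] = col.strip()
    if id_col is None:
        # first column is the id by convention
        id_col = df.columns[0]
        rename[id_col] = "complex_id"
    df = df.rename(columns=rename)
    for col in df.columns:
        if col == "complex_id":
            df[col] = df[col].astype(str)
            continue
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r}, data row {row}"
            )
        df[col] = parsed
    return EnergyTable(df)


def write_predictions(
    path: str | Path,
    ids: Iterable[str],
    observed: Iterable[float],
    predicted: Iterable[float],
    leverage: Iterable[float] | None = None,
    in_domain: Iterable[bool] | None = None,
) -> pd.DataFrame:
    """Write the standard predictions CSV (id, observed, predicted, leverage,
    in_domain) and return it as a DataFrame."""
    df = pd.DataFrame({"compound_id": list(ids)})
    df["observed"] = list(observed)
    df["predicted"] = list(predicted)
    if leverage is not None:
        df["leverage"] = list(leverage)
    if in_domain is not None:
        df["in_domain"] = list(in_domain)
    df.to_csv(path, index=False)
    return df
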