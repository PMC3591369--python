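"""Structure model, PDB input, van der Waals radii, and solvent accessibility.

The package works on a lightweight in-memory model (``Atom`` / ``Residue`` /
``Structure``) built from PDB-format text.  Only heavy atoms are retained:
hydrogens never participate in any distance, surface, or volume computation.
Solvent-accessible surface areas are computed by Shrake–Rupley sphere-point
sampling with a 1.4 Å probe, which for a single isolated sphere converges to
the analytic area ``4*pi*(r + probe)**2``.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Radii and residue vocabularies
# ---------------------------------------------------------------------------

#: Default van der Waals radii (Å) by element symbol.
DEFAULT_VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}
DEFAULT_RADIUS = 1.70

WATER_CODES = frozenset({"HOH", "DOD", "WAT", "H2O"})

#: HET codes excluded from ligand extraction in addition to the
#: monoatomic-group rule (which already catches isolated ions).
DEFAULT_ION_CODES = frozenset(
    {"NA", "CL", "K", "MG", "CA", "ZN", "MN", "FE", "CU", "CO", "NI", "CD",
     "HG", "BR", "IOD", "F", "LI", "CS", "RB", "SR", "BA", "AU", "PT"}
)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class ResidueID(NamedTuple):
    """Unique residue key: chain, residue number, insertion code ('' if none)."""

    chain_id: str
    seq_number: int
    icode: str = ""

    def __str__(self) -> str:  # e.g. "A:42" or "A:42A"
        return f"{self.chain_id}:{self.seq_number}{self.icode}"


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coord: np.ndarray
    radius: float
    is_heavy: bool = True
    sasa: float = 0.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.is_heavy and self.radius <= 0:
            raise ValueError(f"heavy atom {self.name} must have positive radius")


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    icode: str
    aa_type: str  # three-letter (or HET) code
    atoms: list[Atom] = field(default_factory=list)
    sasa: float = 0.0
    is_surface: bool = False

    @property
    def rid(self) -> ResidueID:
        return ResidueID(self.chain_id, self.seq_number, self.icode)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.aa_type, "X")

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    def get_atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Optional[Atom]:
        return self.get_atom("CA")


@dataclass
class LigandInstance:
    het_code: str
    chain_id: str
    atoms: list[Atom]
    seq_number: int = 0
    icode: str = ""

    @property
    def lid(self) -> str:
        return f"{self.het_code}_{self.chain_id}{self.seq_number}{self.icode}"

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)


@dataclass
class Structure:
    id: str
    chains: dict[str, list[Residue]]
    ligands: list[LigandInstance] = field(default_factory=list)

    def get_chain(self, chain_id: str) -> list[Residue]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise KeyError(
                f"chain {chain_id!r} not present in structure {self.id!r} "
                f"(has {sorted(self.chains)})"
            ) from None

    def residues(self, chain_ids: Optional[Iterable[str]] = None) -> Iterator[Residue]:
        for cid in (chain_ids if chain_ids is not None else self.chains):
            yield from self.get_chain(cid)

    def residue(self, rid: ResidueID) -> Residue:
        for res in self.get_chain(rid.chain_id):
            if res.seq_number == rid.seq_number and res.icode == rid.icode:
                return res
        raise KeyError(f"residue {rid} not found in structure {self.id!r}")

    def sequence(self, chain_id: str) -> str:
        return "".join(r.one_letter for r in self.get_chain(chain_id))

    def chain_atoms(self, chain_ids: Optional[Iterable[str]] = None) -> list[Atom]:
        return [a for r in self.residues(chain_ids) for a in r.atoms]


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------

def _radius_for(element: str, radii: Mapping[str, float]) -> float:
    return radii.get(element.upper(), DEFAULT_RADIUS)


def load_structure(
    pdb_text: str,
    chain_filter: Optional[set[str]] = None,
    structure_id: str = "struct",
    radii: Mapping[str, float] = DEFAULT_VDW_RADII,
    excluded_het_codes: frozenset[str] = DEFAULT_ION_CODES,
) -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Only the first model is read.  Hydrogens are dropped; alternate
    locations are resolved to the highest-occupancy conformer (tie broken
    by file order).  HETATM groups other than water become ligand
    candidates, subject to the ion exclusion rules of
    :func:`extract_ligands`.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    # strict parsers silently drop records with malformed names; pre-scan so
    # a broken coordinate line is reported with its line number
    for lineno, line in enumerate(pdb_text.splitlines(), 1):
        if line[:4] == "ATOM" or line[:6] == "HETATM":
            try:
                rec = line[:6].strip()
                assert rec in ("ATOM", "HETATM")
                float(line[30:38]), float(line[38:46]), float(line[46:54])
            except (AssertionError, ValueError, IndexError):
                raise ValueError(
                    f"unparseable PDB record at line {lineno}: {line[:30]!r}"
                ) from None

    parser = PDBParser(PERMISSIVE=0, QUIET=False)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            bio_struct = parser.get_structure(structure_id, io.StringIO(pdb_text))
    except Exception as exc:  # Bio.PDB reports the offending line in its message
        raise ValueError(f"unparseable PDB record: {exc}") from exc

    try:
        model = next(iter(bio_struct))
    except StopIteration:
        raise ValueError("no parseable ATOM/HETATM records in PDB input") from None
    chains: dict[str, list[Residue]] = {}
    het_groups: list[LigandInstance] = []

    for bio_chain in model:
        cid = bio_chain.id
        if chain_filter is not None and cid not in chain_filter:
            continue
        for bio_res in bio_chain:
            hetflag, seqnum, icode = bio_res.id
            icode = icode.strip()
            atoms: list[Atom] = []
            for bio_atom in bio_res:
                if bio_atom.is_disordered():
                    # highest occupancy; Bio.PDB pre-selects it
                    bio_atom = bio_atom.disordered_get()
                element = (bio_atom.element or "").upper()
                if element in ("H", "D"):
                    continue
                atoms.append(
                    Atom(
                        serial=bio_atom.serial_number,
                        name=bio_atom.get_name(),
                        element=element,
                        coord=np.asarray(bio_atom.coord, dtype=float),
                        radius=_radius_for(element, radii),
                    )
                )
            if not atoms:
                continue
            resname = bio_res.get_resname().strip()
            if hetflag == " ":
                chains.setdefault(cid, []).append(
                    Residue(cid, seqnum, icode, resname, atoms)
                )
            elif hetflag == "W" or resname in WATER_CODES:
                continue
            else:
                het_groups.append(
                    LigandInstance(resname, cid, atoms, seqnum, icode)
                )

    if chain_filter is not None:
        missing = set(chain_filter) - set(chains)
        # a chain consisting only of HETATMs satisfies the filter for ligands
        het_chains = {g.chain_id for g in het_groups}
        missing -= het_chains
        if missing:
            raise ValueError(
                f"requested chain(s) {sorted(missing)} not found in PDB input "
                f"(found {sorted(set(chains) | het_chains)})"
            )
    if not chains and not het_groups:
        raise ValueError("no chains parsed from PDB input")

    struct = Structure(structure_id, chains)
    struct.ligands = _filter_ligands(het_groups, excluded_het_codes)
    return struct


def _filter_ligands(
    groups: Sequence[LigandInstance], excluded: frozenset[str]
) -> list[LigandInstance]:
    kept = []
    for g in groups:
        if g.het_code in WATER_CODES or g.het_code in excluded:
            continue
        if len(g.atoms) < 2:  # monoatomic group = ion-like
            continue
        kept.append(g)
    return kept


def extract_ligands(
    structure: Structure,
    excluded_het_codes: frozenset[str] = DEFAULT_ION_CODES,
) -> list[LigandInstance]:
    """Return HET groups that are neither waters, ions, nor monoatomic.

    Idempotent and order-independent: the result depends only on the set of
    HET groups present.
    """
    return _filter_ligands(structure.ligands, excluded_het_codes)


_PDB_ATOM_FMT = (
    "{rec:<6}{serial:>5} {name:<4}{altloc:1}{resname:<3} {chain:1}"
    "{resnum:>4}{icode:1}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{b:>6.2f}"
    "          {element:>2}"
)


def _format_atom_name(name: str, element: str) -> str:
    # PDB columns 13-16: element right-justified in 13-14 for 1-letter elements
    if len(element) == 1 and len(name) < 4:
        return f" {name:<3}"
    return f"{name:<4}"


def to_pdb_text(structure: Structure) -> str:
    """Serialise a :class:`Structure` back to PDB-format text."""
    lines = []
    serial = 0
    for cid in structure.chains:
        for res in structure.get_chain(cid):
            for atom in res.atoms:
                serial += 1
                lines.append(
                    _PDB_ATOM_FMT.format(
                        rec="ATOM", serial=serial,
                        name=_format_atom_name(atom.name, atom.element),
                        altloc=" ", resname=res.aa_type[:3], chain=cid,
                        resnum=res.seq_number, icode=res.icode or " ",
                        x=atom.coord[0], y=atom.coord[1], z=atom.coord[2],
                        occ=1.0, b=0.0, element=atom.element,
                    )
                )
        lines.append(f"TER   {serial + 1:>5}")
    for lig in structure.ligands:
        for atom in lig.atoms:
            serial += 1
            lines.append(
                _PDB_ATOM_FMT.format(
                    rec="HETATM", serial=serial,
                    name=_format_atom_name(atom.name, atom.element),
                    altloc=" ", resname=lig.het_code[:3], chain=lig.chain_id,
                    resnum=lig.seq_number or 1, icode=lig.icode or " ",
                    x=atom.coord[0], y=atom.coord[1], z=atom.coord[2],
                    occ=1.0, b=0.0, element=atom.element,
                )
            )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake-Rupley sphere sampling)
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (golden-section spiral)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def sasa_of_atoms(
    atoms: Sequence[Atom],
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²) of an atom set.

    Each atom's accessible sphere of radius ``r_i + probe`` is sampled with
    ``n_points`` quasi-uniform points; a point is accessible when it lies
    outside every other atom's accessible sphere.
    """
    if not atoms:
        return np.zeros(0)
    coords = np.array([a.coord for a in atoms], dtype=float)
    radii = np.array([a.radius for a in atoms], dtype=float) + probe_radius
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    areas = np.empty(len(atoms))
    for i in range(len(atoms)):
        pts = coords[i] + radii[i] * unit
        nbrs = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r)
                if j != i]
        accessible = np.ones(n_points, dtype=bool)
        if nbrs:
            d2 = ((pts[:, None, :] - coords[nbrs][None, :, :]) ** 2).sum(axis=2)
            accessible = ~(d2 < (radii[nbrs] ** 2)[None, :]).any(axis=1)
        areas[i] = accessible.mean() * 4.0 * np.pi * radii[i] ** 2
    return areas


def compute_sasa(
    structure: Structure,
    probe_radius: float = 1.4,
    n_points: int = 960,
    chain_ids: Optional[Iterable[str]] = None,
    include_ligands: bool = False,
) -> dict[ResidueID, float]:
    """Compute per-residue SASA over the selected chains (the "context").

    Occlusion is computed among all heavy atoms of the selected chains (plus
    ligand atoms if ``include_ligands``).  Atom- and residue-level values are
    stored on the model (``atom.sasa``, ``residue.sasa``); the per-residue
    map is returned.  Calling with a single chain gives the isolated-chain
    SASA used for the surface-residue definition.
    """
    chain_ids = list(chain_ids) if chain_ids is not None else list(structure.chains)
    residues = [r for r in structure.residues(chain_ids)]
    for r in residues:
        if not r.atoms:
            raise ValueError(f"residue {r.rid} has no heavy atoms")
    atoms: list[Atom] = [a for r in residues for a in r.atoms]
    owner = [r for r in residues for _ in r.atoms]
    if include_ligands:
        atoms = atoms + [a for lig in structure.ligands for a in lig.atoms]
        owner = owner + [None] * (len(atoms) - len(owner))
    areas = sasa_of_atoms(atoms, probe_radius, n_points)
    for a, area in zip(atoms, areas):
        a.sasa = float(area)
    result: dict[ResidueID, float] = {}
    for r in residues:
        r.sasa = float(sum(a.sasa for a in r.atoms))
        result[r.rid] = r.sasa
    return result


def surface_residues(
    structure: Structure,
    chain_id: str,
    rel_sasa_threshold: float = 0.05,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> set[ResidueID]:
    """Residues of an isolated chain with relative SASA ≥ threshold.

    The denominator is the residue's fully exposed SASA, computed by the
    same engine from the residue's own atoms in isolation, so the rule is
    self-consistent for arbitrary residue compositions.  Flags
    ``residue.is_surface`` as a side effect.
    """
    compute_sasa(structure, probe_radius, n_points, chain_ids=[chain_id])
    out: set[ResidueID] = set()
    for res in structure.get_chain(chain_id):
        ref = sasa_of_atoms(res.atoms, probe_radius, n_points).sum()
        rel = res.sasa / ref if ref > 0 else 0.0
        res.is_surface = rel >= rel_sasa_threshold
        if res.is_surface:
            out.add(res.rid)
    return out


def sasa_table(structure: Structure, chain_id: str) -> pd.DataFrame:
    """Per-residue SASA export (requires prior compute_sasa / surface calls)."""
    rows = []
    for res in structure.get_chain(chain_id):
        ref = sasa_of_atoms(res.atoms).sum()
        rows.append(
            dict(chain=res.chain_id, resnum=res.seq_number, icode=res.icode,
                 aa=res.aa_type, sasa=res.sasa,
                 rel_sasa=res.sasa / ref if ref > 0 else 0.0,
                 is_surface=res.is_surface)
        )
    return pd.DataFrame(rows)
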