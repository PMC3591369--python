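"""Per-residue interface features for the overlap/non-overlap classifier.

Five feature families are computed for each interface residue of the
reference protein, all on the protein–protein complex structure:

* **protrusion index (cx)** — for each heavy atom, the ratio of empty to
  atom-occupied volume within a 10 Å sphere (V_empty / V_atoms); 0 means
  fully buried, large values mean solvent-exposed.  The residue value is
  the mean over its atoms.  Volumes are estimated on a uniform grid
  (0.5 Å spacing by default) and the occupied volume is the *union* of the
  neighbourhood atoms' spheres, so overlapping atoms are not double
  counted.  The atom's own sphere counts toward V_atoms.
* **contact density** — intra-chain heavy-atom contacts within 5 Å of the
  residue's solvent-accessible atoms, divided by the residue's total heavy
  atom count.
* **relative surface fraction** — residue SASA in the complex divided by a
  fully exposed reference area (tripeptide-style; see
  :func:`surface_fraction`), clipped to [0, 1].
* **evolutionary conservation** — ingested from a Consurf-style grades
  file or plain TSV; normalised scores, negative = conserved.
* **hot-spot status** — a knowledge-based surrogate flag (strong burial in
  the complex plus dense packing), overridable by a user label file.

The 13-dimensional classifier input combines the central residue's surface
fraction and contact density, the protrusion and conservation of the five
nearest surface residues (the residue itself first), and the hot-spot
frequency in its size-8 surface patch.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .interface import InterfaceAnnotation
from .patches import DegeneratePatchError, build_patch
from .structure import Residue, ResidueID, Structure, sasa_of_atoms

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "surfaceFraction", "density",
    "protru1", "protru2", "protru3", "protru4", "protru5",
    "cons1", "cons2", "cons3", "cons4", "cons5",
    "hsfPatch8",
]

#: Total accessible surface (Å²) of residue X in an extended Ala-X-Ala
#: tripeptide (Hubbard & Thornton reference values, as shipped with Naccess).
TRIPEPTIDE_TOTAL_ASA = {
    "ALA": 107.95, "ARG": 238.76, "ASN": 143.94, "ASP": 140.39,
    "CYS": 134.28, "GLN": 178.50, "GLU": 172.25, "GLY": 80.10,
    "HIS": 182.88, "ILE": 175.12, "LEU": 178.63, "LYS": 200.81,
    "MET": 194.15, "PHE": 199.48, "PRO": 136.13, "SER": 116.50,
    "THR": 139.27, "TRP": 249.36, "TYR": 212.76, "VAL": 151.44,
}


# ---------------------------------------------------------------------------
# Protrusion index
# ---------------------------------------------------------------------------

@dataclass
class ProtrusionResult:
    atom_values: dict[tuple[ResidueID, str], float]
    residue_values: dict[ResidueID, float]


def protrusion(
    structure: Structure,
    sphere_radius: float = 10.0,
    grid_spacing: float = 0.5,
    chain_ids: Optional[Sequence[str]] = None,
) -> ProtrusionResult:
    """Protrusion index cx = V_empty / V_atoms for every heavy atom.

    A uniform grid covers the structure's bounding box inflated by the
    sphere radius; each grid cell carries an occupancy fraction in [0, 1]:
    1 well inside an atom sphere, 0 well outside, and a first-order
    partial-cell estimate ``0.5 + (r - d)/h`` across the surface (cell
    size ``h``), maximised over atoms so overlapping spheres are counted
    once (union volume).  For atom i, V_atoms is the occupied volume
    within ``sphere_radius`` and V_empty the remaining sphere volume, both
    measured on the same grid.  Halving ``grid_spacing`` roughly quarters
    the residual error against closed-form volumes.
    """
    chain_ids = list(chain_ids) if chain_ids is not None else list(structure.chains)
    residues = [r for r in structure.residues(chain_ids)]
    for r in residues:
        if not r.atoms:
            raise ValueError(f"residue {r.rid} has no heavy atoms")
    atoms = [(r.rid, a) for r in residues for a in r.atoms]
    coords = np.array([a.coord for _, a in atoms])
    radii = np.array([a.radius for _, a in atoms])

    lo = coords.min(axis=0) - sphere_radius - radii.max()
    hi = coords.max(axis=0) + sphere_radius + radii.max()
    axes = [np.arange(lo[d], hi[d] + grid_spacing, grid_spacing) for d in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    grid_tree = cKDTree(grid)

    h = grid_spacing
    occupancy = np.zeros(len(grid))
    for r in np.unique(radii):
        sel = coords[radii == r]
        idx_lists = grid_tree.query_ball_point(sel, r + h)
        for c, idx in zip(sel, idx_lists):
            idx = np.asarray(idx, dtype=int)
            if idx.size == 0:
                continue
            d = np.linalg.norm(grid[idx] - c, axis=1)
            frac = np.clip(0.5 + (r - d) / h, 0.0, 1.0)
            np.maximum.at(occupancy, idx, frac)

    atom_values: dict[tuple[ResidueID, str], float] = {}
    for (rid, a), c in zip(atoms, coords):
        ball = np.asarray(grid_tree.query_ball_point(c, sphere_radius), dtype=int)
        v_occ = float(occupancy[ball].sum())
        v_empty = len(ball) - v_occ
        # v_occ > 0 always: the atom's own sphere covers grid cells
        atom_values[(rid, a.name)] = v_empty / v_occ if v_occ else float("inf")

    residue_values = {
        r.rid: float(np.mean([atom_values[(r.rid, a.name)] for a in r.atoms]))
        for r in residues
    }
    return ProtrusionResult(atom_values, residue_values)


# ---------------------------------------------------------------------------
# Contact density
# ---------------------------------------------------------------------------

def contact_density(
    structure: Structure,
    chain_id: str,
    residue_id: ResidueID,
    contact_cutoff: float = 5.0,
) -> float:
    """Intra-chain contact density of a residue.

    Sum over the residue's *solvent-accessible* heavy atoms (atom SASA > 0,
    from the most recent SASA computation) of the number of heavy atoms of
    other residues of the same chain within ``contact_cutoff``, divided by
    the residue's total heavy-atom count.
    """
    chain = structure.get_chain(chain_id)
    res = next((r for r in chain if r.rid == residue_id), None)
    if res is None:
        raise ValueError(f"residue {residue_id} not in chain {chain_id}")
    other_coords = np.array(
        [a.coord for r in chain if r.rid != residue_id for a in r.atoms]
    )
    n_contacts = 0
    if other_coords.size:
        tree = cKDTree(other_coords)
        for atom in res.atoms:
            if atom.sasa > 0:
                n_contacts += len(tree.query_ball_point(atom.coord, contact_cutoff))
    return n_contacts / len(res.atoms)


# ---------------------------------------------------------------------------
# Relative surface fraction
# ---------------------------------------------------------------------------

def surface_fraction(
    structure: Structure,
    chain_id: str,
    residue_id: ResidueID,
    reference_mode: str = "context",
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> float:
    """Residue SASA in the complex over its fully exposed reference area.

    ``reference_mode='context'`` (default) computes the reference with the
    same SASA engine from the residue plus its two sequence neighbours —
    the tripeptide-style normalisation, applicable to arbitrary residue
    compositions.  ``reference_mode='table'`` uses the Hubbard–Thornton
    Ala-X-Ala totals and raises for residue types outside the 20 standard
    amino acids.  Requires a prior complex-context SASA computation; the
    result is clipped to [0, 1].
    """
    chain = structure.get_chain(chain_id)
    idx = next((i for i, r in enumerate(chain) if r.rid == residue_id), None)
    if idx is None:
        raise ValueError(f"residue {residue_id} not in chain {chain_id}")
    res = chain[idx]
    if reference_mode == "table":
        try:
            ref = TRIPEPTIDE_TOTAL_ASA[res.aa_type]
        except KeyError:
            raise ValueError(
                f"unknown amino-acid type {res.aa_type!r} for residue "
                f"{residue_id}; no tripeptide reference area"
            ) from None
    elif reference_mode == "context":
        context_atoms = list(res.atoms)
        for j in (idx - 1, idx + 1):
            if 0 <= j < len(chain):
                context_atoms += chain[j].atoms
        areas = sasa_of_atoms(context_atoms, probe_radius, n_points)
        ref = float(areas[: len(res.atoms)].sum())
    else:
        raise ValueError(f"unknown reference_mode {reference_mode!r}")
    if ref <= 0:
        raise ValueError(f"non-positive reference area for residue {residue_id}")
    return float(np.clip(res.sasa / ref, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Conservation ingestion
# ---------------------------------------------------------------------------

@dataclass
class ConservationTable:
    scores: dict[ResidueID, float]


_GRADES_3LATOM = re.compile(r"^([A-Z]{3})(-?\d+)([A-Za-z]?):(\S+)$")


def load_conservation(text: str, dialect: str = "tsv") -> ConservationTable:
    """Parse per-residue conservation scores.

    ``dialect='tsv'``: tab-separated with header ``chain resnum icode score``
    (``icode`` column optional).  ``dialect='consurf_grades'``: the
    Consurf-DB grade-file layout — header junk is skipped and residues are
    read from the 3LATOM column (e.g. ``MET1:A``), the score from the
    SCORE column.
    """
    scores: dict[ResidueID, float] = {}
    if dialect == "tsv":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines:
            raise ValueError("empty conservation file")
        header = [h.strip().lower() for h in lines[0].split("\t")]
        if "score" in header:
            cols = {name: i for i, name in enumerate(header)}
            body = lines[1:]
        else:  # headerless: chain, resnum[, icode], score
            ncol = len(lines[0].split("\t"))
            cols = ({"chain": 0, "resnum": 1, "score": 2} if ncol == 3
                    else {"chain": 0, "resnum": 1, "icode": 2, "score": 3})
            body = lines
        for ln in body:
            f = ln.split("\t")
            icode = f[cols["icode"]].strip() if "icode" in cols and cols["icode"] < len(f) else ""
            rid = ResidueID(f[cols["chain"]].strip(), int(f[cols["resnum"]]), icode)
            scores[rid] = float(f[cols["score"]])
    elif dialect == "consurf_grades":
        for ln in text.splitlines():
            fields = ln.split()
            if len(fields) < 4 or not fields[0].lstrip("-").isdigit():
                continue
            m = _GRADES_3LATOM.match(fields[2])
            if not m:
                continue  # unmodelled position ('-') or malformed token
            _aa, resnum, icode, chain = m.groups()
            try:
                score = float(fields[3])
            except ValueError:
                continue
            scores[ResidueID(chain, int(resnum), icode)] = score
    else:
        raise ValueError(f"unknown conservation dialect {dialect!r}")
    if not scores:
        raise ValueError("no conservation scores parsed")
    return ConservationTable(scores)


def match_conservation(
    table: ConservationTable,
    structure: Structure,
    chain_id: str,
    max_unmatched_frac: float = 0.20,
) -> dict[ResidueID, Optional[float]]:
    """Map scores onto a chain's residues, honouring insertion codes.

    Residues without a score map to ``None`` (later imputed as 0, the
    normalised mean) with a warning; more than ``max_unmatched_frac`` of
    the chain unmatched is treated as a numbering mismatch and raises.
    """
    chain = structure.get_chain(chain_id)
    out: dict[ResidueID, Optional[float]] = {}
    unmatched = []
    for res in chain:
        if res.rid in table.scores:
            out[res.rid] = table.scores[res.rid]
        else:
            out[res.rid] = None
            unmatched.append(res.rid)
    frac = len(unmatched) / len(chain) if chain else 1.0
    if frac > max_unmatched_frac:
        raise ValueError(
            f"{len(unmatched)}/{len(chain)} residues of chain {chain_id} have "
            f"no conservation score ({frac:.0%} > {max_unmatched_frac:.0%}): "
            "residue numbering mismatch?"
        )
    if unmatched:
        logger.warning(
            "%d residue(s) without conservation score (imputed 0): %s",
            len(unmatched), unmatched[:5],
        )
    return out


# ---------------------------------------------------------------------------
# Hot-spot surrogate
# ---------------------------------------------------------------------------

@dataclass
class HotspotLabeling:
    labels: dict[ResidueID, bool]
    source: str  # 'predicted' or 'user-supplied'


def predict_hotspots(
    structure: Structure,
    chain_id: str,
    candidate_residues: set[ResidueID],
    complex_fractions: Mapping[ResidueID, float],
    densities: Mapping[ResidueID, float],
    max_complex_fraction: float = 0.20,
    density_threshold: Optional[float] = None,
    user_labels: Optional[Mapping[ResidueID, bool]] = None,
) -> HotspotLabeling:
    """Knowledge-based hot-spot surrogate.

    A residue is flagged when (a) its relative surface fraction in the
    complex is ≤ ``max_complex_fraction`` (occlusion from solvent) and
    (b) its contact density is at least ``density_threshold`` (dense local
    packing; default: median + 0.5×IQR of the candidate densities).  A
    user-supplied label map overrides the rule entirely.
    """
    if user_labels is not None:
        return HotspotLabeling(
            {rid: bool(user_labels.get(rid, False)) for rid in candidate_residues},
            source="user-supplied",
        )
    vals = np.array([densities[rid] for rid in sorted(candidate_residues)])
    if density_threshold is None:
        q1, med, q3 = np.percentile(vals, [25, 50, 75]) if vals.size else (0, 0, 0)
        density_threshold = med + 0.5 * (q3 - q1)
    labels = {
        rid: (complex_fractions[rid] <= max_complex_fraction
              and densities[rid] >= density_threshold)
        for rid in candidate_residues
    }
    return HotspotLabeling(labels, source="predicted")


def load_hotspot_labels(text: str) -> dict[ResidueID, bool]:
    """TSV (chain, resnum, icode, label) with label in {0,1,true,false}."""
    out: dict[ResidueID, bool] = {}
    for ln in text.splitlines():
        if not ln.strip() or ln.lower().startswith("chain"):
            continue
        ch, num, icode, lab = (ln.split("\t") + [""])[:4]
        out[ResidueID(ch, int(num), icode)] = lab.strip().lower() in ("1", "true", "yes")
    return out


# ---------------------------------------------------------------------------
# Feature-vector assembly
# ---------------------------------------------------------------------------

def build_feature_vectors(
    structure: Structure,
    chain_id: str,
    interface: InterfaceAnnotation,
    surface_set: set[ResidueID],
    conservation: Optional[Mapping[ResidueID, Optional[float]]],
    hotspots: HotspotLabeling,
    protrusion_values: Mapping[ResidueID, float],
    densities: Mapping[ResidueID, float],
    fractions: Mapping[ResidueID, float],
    patch_n: int = 8,
) -> pd.DataFrame:
    """Assemble the 13 classifier features for every interface residue.

    Neighbour features (protru2..5, cons2..5) come from the four nearest
    surface residues by Cα distance (ties broken by residue id); index 1 is
    the central residue itself.  ``hsfPatch8`` is the hot-spot frequency in
    the residue's size-``patch_n`` surface patch; patch members without a
    hot-spot label count as non-hot-spots.  Missing conservation scores are
    imputed as 0.  Output rows are indexed by residue id in sorted order,
    so the table is independent of input residue ordering.
    """
    surf_sorted = sorted(surface_set)
    ca = {}
    for rid in surf_sorted:
        atom = structure.residue(rid).ca
        if atom is None:
            raise ValueError(f"surface residue {rid} lacks a CA atom")
        ca[rid] = atom.coord

    def cons_of(rid: ResidueID) -> float:
        if conservation is None:
            return 0.0
        v = conservation.get(rid)
        return 0.0 if v is None else float(v)

    rows = []
    index = []
    for rid in sorted(interface.residues):
        dists = sorted(
            ((float(np.linalg.norm(ca[o] - ca[rid])), o) for o in surf_sorted if o != rid),
        )
        nearest = [rid] + [o for _, o in dists[:4]]
        while len(nearest) < 5:  # tiny surfaces: pad with the central residue
            nearest.append(rid)
        try:
            patch = build_patch(structure, rid, surface_set, n=patch_n)
            hsf = float(np.mean([
                1.0 if hotspots.labels.get(m, False) else 0.0
                for m in patch.members
            ]))
        except DegeneratePatchError:
            logger.warning("degenerate patch at %s; hsfPatch%d set to 0", rid, patch_n)
            hsf = 0.0
        row = {
            "surfaceFraction": float(fractions[rid]),
            "density": float(densities[rid]),
            **{f"protru{i+1}": float(protrusion_values[nearest[i]]) for i in range(5)},
            **{f"cons{i+1}": cons_of(nearest[i]) for i in range(5)},
            "hsfPatch8": hsf,
        }
        rows.append(row)
        index.append(rid)
    df = pd.DataFrame(
        rows, index=pd.Index(index, name="residue", tupleize_cols=False)
    )
    return df[FEATURE_COLUMNS]


def feature_table_tsv(
    df: pd.DataFrame, structure: Structure, labels: Optional[Mapping[ResidueID, str]] = None
) -> str:
    """Serialise a feature table in the classifier's TSV contract."""
    out = df.copy()
    rids = list(out.index)
    meta = pd.DataFrame(
        {
            "chain": [r.chain_id for r in rids],
            "resnum": [r.seq_number for r in rids],
            "icode": [r.icode for r in rids],
            "aa": [structure.residue(r).aa_type for r in rids],
        },
        index=out.index,
    )
    if labels is not None:
        meta["label"] = [labels.get(r, "") for r in rids]
    return pd.concat([meta, out], axis=1).to_csv(sep="\t", index=False)
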