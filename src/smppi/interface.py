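"""Interface detection, overlap labelling, superposition and clustering.

A residue of the query chain belongs to a binding interface when at least
one of its heavy atoms lies within a distance cutoff (default 5 Å) of a
heavy atom of the binding partner — another protein chain or a small-
molecule ligand — and the residue is a surface residue of the query chain.

Overlap labelling maps the protein–ligand interface of a homologous
reference protein onto the protein–protein interface via a global sequence
alignment: interface residues contacted (through the alignment) by both the
partner protein and the ligand are "overlap" (O), the rest of the
protein–protein interface is "non-overlap" (N).  Competitive binding is
established by superposing the ligand-bound reference onto the
protein-bound one (Kabsch fit on aligned Cα atoms) and testing the mapped
ligand for steric collision with the partner protein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .structure import Atom, LigandInstance, Residue, ResidueID, Structure

logger = logging.getLogger(__name__)

__all__ = [
    "InterfaceAnnotation", "AlignmentMap", "OverlapLabeling", "RigidTransform",
    "InsufficientOverlapError", "detect_interface", "align_sequences",
    "label_overlap", "superpose", "apply_transform", "detect_collision",
    "cluster_overlap_region",
]


class InsufficientOverlapError(ValueError):
    """Raised when a PP:PL pair shares fewer overlap residues than required."""


@dataclass
class InterfaceAnnotation:
    query_chain: str
    partner: str  # chain id or ligand id
    residues: set[ResidueID]
    cutoff: float

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class AlignmentMap:
    """Aligned (non-gap) column pairs between two sequences, 0-based."""

    pairs: list[tuple[int, int]]
    identity: float
    a_to_b: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        pa = [p[0] for p in self.pairs]
        pb = [p[1] for p in self.pairs]
        if any(x >= y for x, y in zip(pa, pa[1:])) or any(
            x >= y for x, y in zip(pb, pb[1:])
        ):
            raise ValueError("alignment positions must be strictly increasing")
        self.a_to_b = dict(self.pairs)


@dataclass
class OverlapLabeling:
    reference: str  # structure id + chain
    labels: dict[ResidueID, str]  # 'O' or 'N', covers the PP interface

    @property
    def n_overlap(self) -> int:
        return sum(1 for v in self.labels.values() if v == "O")

    @property
    def n_nonoverlap(self) -> int:
        return sum(1 for v in self.labels.values() if v == "N")

    @property
    def overlap_residues(self) -> set[ResidueID]:
        return {k for k, v in self.labels.items() if v == "O"}


@dataclass
class RigidTransform:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # 3-vector
    rmsd: float


# ---------------------------------------------------------------------------
# Interface detection
# ---------------------------------------------------------------------------

def _partner_coords(
    structure: Structure, partner: Union[str, LigandInstance]
) -> np.ndarray:
    if isinstance(partner, LigandInstance):
        return partner.coords()
    atoms = structure.chain_atoms([partner])
    return np.array([a.coord for a in atoms], dtype=float)


def detect_interface(
    structure: Structure,
    query_chain: str,
    partner: Union[str, LigandInstance],
    cutoff: float = 5.0,
    surface: Optional[set[ResidueID]] = None,
) -> InterfaceAnnotation:
    """Surface residues of ``query_chain`` within ``cutoff`` of the partner.

    ``surface`` restricts candidates to a pre-computed surface-residue set;
    if omitted, all residues of the query chain are candidates (useful for
    purely geometric tests).  Distances are minimum heavy-atom distances.
    """
    pcoords = _partner_coords(structure, partner)
    if pcoords.size == 0:
        raise ValueError("binding partner has no heavy atoms")
    tree = cKDTree(pcoords)
    hits: set[ResidueID] = set()
    for res in structure.get_chain(query_chain):
        if surface is not None and res.rid not in surface:
            continue
        d, _ = tree.query(res.coords(), k=1)
        if np.min(d) <= cutoff:
            hits.add(res.rid)
    pid = partner.lid if isinstance(partner, LigandInstance) else partner
    return InterfaceAnnotation(query_chain, pid, hits, cutoff)


# ---------------------------------------------------------------------------
# Sequence alignment
# ---------------------------------------------------------------------------

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def align_sequences(seq_a: str, seq_b: str) -> AlignmentMap:
    """Global Needleman–Wunsch alignment (BLOSUM62, gap open 10 / extend 0.5).

    Identity is the fraction of identical residues over aligned (non-gap)
    columns.  Non-standard letters are mapped to ``X`` with a warning.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")

    def sanitise(seq: str, name: str) -> str:
        bad = set(seq.upper()) - _STANDARD_AA - {"X"}
        if bad:
            logger.warning(
                "sequence %s: non-standard residue codes %s mapped to X",
                name, sorted(bad),
            )
        return "".join(c if c in _STANDARD_AA else "X" for c in seq.upper())

    sa, sb = sanitise(seq_a, "A"), sanitise(seq_b, "B")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(sa, sb)[0]
    pairs: list[tuple[int, int]] = []
    matches = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            pairs.append((i, j))
            if sa[i] == sb[j]:
                matches += 1
    identity = matches / len(pairs) if pairs else 0.0
    return AlignmentMap(pairs, identity)


# ---------------------------------------------------------------------------
# Overlap labelling
# ---------------------------------------------------------------------------

def label_overlap(
    pp_iface: InterfaceAnnotation,
    pl_iface: InterfaceAnnotation,
    amap: AlignmentMap,
    pp_residues: Sequence[Residue],
    pl_residues: Sequence[Residue],
    min_overlap: int = 2,
    reference: str = "",
) -> OverlapLabeling:
    """Label PP-interface residues O (aligned onto a PL-interface position)
    or N (all remaining PP-interface residues).

    ``pp_residues`` / ``pl_residues`` are the ordered residue lists of the
    two reference chains, defining sequence positions for ``amap``.  PL
    interface positions that are unaligned (gapped) in the PP chain are
    ignored.  Raises :class:`InsufficientOverlapError` when fewer than
    ``min_overlap`` overlap residues result.
    """
    pos_of_pp = {r.rid: i for i, r in enumerate(pp_residues)}
    pl_iface_pos = {
        i for i, r in enumerate(pl_residues) if r.rid in pl_iface.residues
    }
    labels: dict[ResidueID, str] = {}
    for rid in pp_iface.residues:
        pos = pos_of_pp.get(rid)
        mapped = amap.a_to_b.get(pos) if pos is not None else None
        labels[rid] = "O" if mapped is not None and mapped in pl_iface_pos else "N"
    lab = OverlapLabeling(reference, labels)
    if lab.n_overlap < min_overlap:
        raise InsufficientOverlapError(
            f"only {lab.n_overlap} overlap residue(s); at least "
            f"{min_overlap} required"
        )
    return lab


def labeling_to_tsv(labeling: OverlapLabeling) -> str:
    lines = ["pdb_id\tchain\tresnum\ticode\tlabel"]
    sid, _, chain = labeling.reference.partition(":")
    for rid in sorted(labeling.labels):
        lines.append(
            f"{sid}\t{rid.chain_id}\t{rid.seq_number}\t{rid.icode}\t"
            f"{labeling.labels[rid]}"
        )
    return "\n".join(lines) + "\n"


def labeling_from_tsv(text: str) -> OverlapLabeling:
    labels: dict[ResidueID, str] = {}
    sid = ""
    chain = ""
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        sid, ch, num, icode, lab = (line.split("\t") + [""])[:5]
        chain = ch
        labels[ResidueID(ch, int(num), icode)] = lab
    return OverlapLabeling(f"{sid}:{chain}", labels)


# ---------------------------------------------------------------------------
# Rigid superposition (Kabsch) and collision detection
# ---------------------------------------------------------------------------

def superpose(mobile: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid fit of ``mobile`` onto ``target`` (Kabsch).

    Returns the proper rotation (det +1) and translation minimising the
    RMSD of ``R @ mobile + t`` against ``target``.  Requires at least three
    non-collinear point pairs.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError(f"superposition needs >= 3 point pairs, got {n}")
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    m0, t0 = mobile - mc, target - tc
    if np.linalg.matrix_rank(m0, tol=1e-8) < 2 or np.linalg.matrix_rank(t0, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set; rotation ill-defined")
    h = m0.T @ t0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = tc - rot @ mc
    fitted = (rot @ mobile.T).T + trans
    rmsd = float(np.sqrt(((fitted - target) ** 2).sum(axis=1).mean()))
    return RigidTransform(rot, trans, rmsd)


def apply_transform(t: RigidTransform, coords: np.ndarray) -> np.ndarray:
    return (t.rotation @ np.asarray(coords, dtype=float).T).T + t.translation


def transform_atoms(t: RigidTransform, atoms: Sequence[Atom]) -> list[Atom]:
    """Copies of ``atoms`` with coordinates mapped through the transform."""
    out = []
    for a in atoms:
        out.append(
            Atom(a.serial, a.name, a.element,
                 apply_transform(t, a.coord[None, :])[0], a.radius)
        )
    return out


def detect_collision(
    ligand_atoms: Sequence[Atom],
    partner_atoms: Sequence[Atom],
) -> bool:
    """True iff some ligand/partner heavy-atom pair is closer than the sum
    of the two van der Waals radii (strict inequality)."""
    if not ligand_atoms or not partner_atoms:
        return False
    lc = np.array([a.coord for a in ligand_atoms])
    lr = np.array([a.radius for a in ligand_atoms])
    pc = np.array([a.coord for a in partner_atoms])
    pr = np.array([a.radius for a in partner_atoms])
    d = np.sqrt(((lc[:, None, :] - pc[None, :, :]) ** 2).sum(axis=2))
    return bool((d < lr[:, None] + pr[None, :]).any())


# ---------------------------------------------------------------------------
# Overlap-region clustering
# ---------------------------------------------------------------------------

def cluster_overlap_region(
    structure: Structure,
    residue_ids: set[ResidueID],
    linkage_cutoff: float = 5.0,
) -> list[set[ResidueID]]:
    """Single-linkage connected components of a residue set.

    Two residues are linked when their minimum heavy-atom distance is
    ≤ ``linkage_cutoff``; components partition the input.  Returned in
    order of each component's smallest residue id.
    """
    rids = sorted(residue_ids)
    if not rids:
        return []
    residues = [structure.residue(rid) for rid in rids]
    coords = [r.coords() for r in residues]
    rows, cols = [], []
    for i in range(len(rids)):
        ti = cKDTree(coords[i])
        for j in range(i + 1, len(rids)):
            if ti.query(coords[j], k=1)[0].min() <= linkage_cutoff:
                rows += [i, j]
                cols += [j, i]
    adj = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(rids), len(rids))
    )
    n_comp, lab = connected_components(adj, directed=False)
    clusters: list[set[ResidueID]] = [set() for _ in range(n_comp)]
    for rid, c in zip(rids, lab):
        clusters[c].add(rid)
    clusters.sort(key=lambda s: min(s))
    return clusters
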