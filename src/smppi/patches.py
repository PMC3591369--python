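"""Surface-patch construction around a central residue.

A patch of size *n* (5–8) describes the local micro-environment of a
central surface residue.  Construction proceeds in three steps:

1. *pre-patch*: the central residue plus its n−1 nearest surface residues
   by Cα distance;
2. the centre of mass (COM) of the pre-patch Cα coordinates defines, for
   every surface residue, a *solvent vector* pointing from the COM to the
   residue's Cα;
3. the final patch keeps the central residue plus the up-to-n−1 closest
   surface residues whose solvent vector makes an angle within [0°, 110°]
   (closed interval) with the central residue's solvent vector.

The angle filter removes residues lying on the far side of the protein
body that are close in space but face away from the central residue.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .structure import ResidueID, Structure

logger = logging.getLogger(__name__)

__all__ = ["SurfacePatch", "DegeneratePatchError", "build_patch",
           "patch_label_ratio", "patches_to_tsv"]

ANGLE_MAX_DEG = 110.0


class DegeneratePatchError(ValueError):
    """Central residue's Cα coincides with the pre-patch centre of mass."""


@dataclass
class SurfacePatch:
    central: ResidueID
    members: list[ResidueID]  # central first, then by Cα distance
    n_requested: int
    solvent_vectors: dict[ResidueID, np.ndarray]
    complete: bool
    pre_patch: list[ResidueID] = None  # central + n-1 nearest (COM support)

    def __len__(self) -> int:
        return len(self.members)


def _ca_coord(structure: Structure, rid: ResidueID) -> np.ndarray:
    ca = structure.residue(rid).ca
    if ca is None:
        raise ValueError(f"residue {rid} lacks a CA atom")
    return ca.coord


def build_patch(
    structure: Structure,
    central: ResidueID,
    surface_set: set[ResidueID],
    n: int = 7,
    angle_max_deg: float = ANGLE_MAX_DEG,
) -> SurfacePatch:
    """Build the size-``n`` surface patch centred on ``central``.

    ``surface_set`` must contain ``central``; distances use Cα atoms, ties
    broken by (chain, resnum, icode) ordering.  If fewer than ``n``
    residues qualify the patch is returned with ``complete=False``.
    """
    if central not in surface_set:
        raise ValueError(f"central residue {central} not in surface set")
    if not 5 <= n <= 8:
        raise ValueError(f"patch size must be in [5, 8], got {n}")

    others = sorted(surface_set - {central})
    c_ca = _ca_coord(structure, central)
    coords = {rid: _ca_coord(structure, rid) for rid in others}
    # pre-patch: central + n-1 nearest by Cα distance (tie -> id order)
    ranked = sorted(others, key=lambda r: (np.linalg.norm(coords[r] - c_ca), r))
    pre = [central] + ranked[: n - 1]
    com = np.mean([c_ca] + [coords[r] for r in pre[1:]], axis=0)

    sv: dict[ResidueID, np.ndarray] = {}
    for rid in [central] + others:
        v = (c_ca if rid == central else coords[rid]) - com
        norm = np.linalg.norm(v)
        if norm < 1e-9:
            if rid == central:
                raise DegeneratePatchError(
                    f"central residue {central}: Cα coincides with pre-patch COM"
                )
            logger.warning("residue %s has zero solvent vector; excluded", rid)
            continue
        sv[rid] = v / norm

    cos_min = math.cos(math.radians(angle_max_deg))
    qualifying = [
        rid for rid in others
        if rid in sv and float(sv[rid] @ sv[central]) >= cos_min - 1e-12
    ]
    qualifying.sort(key=lambda r: (np.linalg.norm(coords[r] - c_ca), r))
    members = [central] + qualifying[: n - 1]
    vectors = {rid: sv[rid] for rid in members}
    return SurfacePatch(central, members, n, vectors,
                        complete=len(members) == n, pre_patch=pre)


def patch_label_ratio(patch: SurfacePatch, labels: dict[ResidueID, str]) -> float:
    """Fraction of patch members labelled (or predicted) 'O'."""
    missing = [rid for rid in patch.members if rid not in labels]
    if missing:
        raise ValueError(f"unlabeled patch member(s): {missing}")
    n_o = sum(1 for rid in patch.members if labels[rid] == "O")
    return n_o / len(patch.members)


def patches_to_tsv(patches: list[SurfacePatch]) -> str:
    lines = ["central\tmembers\tcomplete"]
    for p in patches:
        members = ",".join(str(m) for m in p.members)
        lines.append(f"{p.central}\t{members}\t{int(p.complete)}")
    return "\n".join(lines) + "\n"
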