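"""Assembly of labelled PP:PL training pairs and redundancy reduction.

A candidate pair couples a protein–protein complex (reference chain P1
bound to partner chain P2) with a protein–ligand complex (reference chain
P3 bound to small molecule L).  The pair is valid when

1. P1 and P3 share at least 40% sequence identity (global alignment),
2. the aligned PP and PL interfaces share at least two residues
   (the overlap), and
3. the ligand, mapped into the PP frame by superposing P3 onto P1,
   sterically collides with P2 (competitive binding).

Invalid pairs carry exactly one rejection reason: ``low_identity``,
``insufficient_overlap`` or ``collision_free``.  Redundancy among accepted
pairs is removed by greedy sequence clustering of the reference proteins
at the same 40% cutoff, dropping clusters whose partners are all short
peptides (< 5 residues), and keeping per cluster the pair with the highest
interface-residue identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import pandas as pd

from . import interface as iface
from .features import (
    build_feature_vectors,
    contact_density,
    match_conservation,
    predict_hotspots,
    protrusion,
    surface_fraction,
)
from .structure import (
    LigandInstance,
    ResidueID,
    Structure,
    compute_sasa,
    surface_residues,
)

logger = logging.getLogger(__name__)

__all__ = ["PPPLPair", "PairRejection", "make_pair", "reduce_redundancy"]

REJECTION_REASONS = ("low_identity", "insufficient_overlap", "collision_free")


@dataclass
class PPPLPair:
    pair_id: str
    p1_sequence: str
    p2_length: int
    identity: float
    interface_identity: float
    labeling: iface.OverlapLabeling
    competitive: bool = True
    # structure context (optional; redundancy reduction works without it)
    pp_structure: Optional[Structure] = None
    pp_chains: Optional[tuple[str, str]] = None
    pl_structure: Optional[Structure] = None
    pl_chain: Optional[str] = None
    ligand: Optional[LigandInstance] = None
    pp_interface: Optional[iface.InterfaceAnnotation] = None
    pp_surface: Optional[set[ResidueID]] = None


@dataclass
class PairRejection:
    pair_id: str
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in REJECTION_REASONS:
            raise ValueError(f"unknown rejection reason {self.reason!r}")


def _interface_identity(
    amap: iface.AlignmentMap,
    pp_residues,
    pl_residues,
    pp_iface: iface.InterfaceAnnotation,
    pl_iface: iface.InterfaceAnnotation,
) -> float:
    """Identity over the union of aligned PP- and PL-interface positions."""
    pp_pos = {i for i, r in enumerate(pp_residues) if r.rid in pp_iface.residues}
    pl_pos = {j for j, r in enumerate(pl_residues) if r.rid in pl_iface.residues}
    cols = [
        (i, j) for i, j in amap.pairs if i in pp_pos or j in pl_pos
    ]
    if not cols:
        return 0.0
    matches = sum(
        1 for i, j in cols
        if pp_residues[i].one_letter == pl_residues[j].one_letter
    )
    return matches / len(cols)


def make_pair(
    pp_structure: Structure,
    pp_chains: tuple[str, str],
    pl_structure: Structure,
    pl_chain: str,
    ligand: Union[LigandInstance, str],
    min_identity: float = 0.40,
    min_overlap: int = 2,
    interface_cutoff: float = 5.0,
    pair_id: Optional[str] = None,
    surface_threshold: float = 0.05,
) -> Union[PPPLPair, PairRejection]:
    """Run the full validity pipeline on one candidate PP:PL pair.

    ``ligand`` may be a :class:`LigandInstance` or a HET code looked up in
    the PL structure (first matching copy).  Returns an accepted
    :class:`PPPLPair` carrying the overlap labelling, or a
    :class:`PairRejection` naming the single decisive reason.
    """
    p1, p2 = pp_chains
    if isinstance(ligand, str):
        matches = [g for g in pl_structure.ligands if g.het_code == ligand]
        if not matches:
            raise ValueError(
                f"ligand {ligand!r} not found in structure {pl_structure.id!r}"
            )
        ligand = matches[0]
    pid = pair_id or f"{pp_structure.id}:{p1}-{p2}|{pl_structure.id}:{pl_chain}-{ligand.het_code}"

    seq_pp = pp_structure.sequence(p1)
    seq_pl = pl_structure.sequence(pl_chain)
    amap = iface.align_sequences(seq_pp, seq_pl)
    if amap.identity < min_identity:
        return PairRejection(pid, "low_identity")

    pp_surf = surface_residues(pp_structure, p1, surface_threshold)
    pl_surf = surface_residues(pl_structure, pl_chain, surface_threshold)
    pp_if = iface.detect_interface(pp_structure, p1, p2, interface_cutoff, pp_surf)
    pl_if = iface.detect_interface(
        pl_structure, pl_chain, ligand, interface_cutoff, pl_surf
    )
    pp_res = pp_structure.get_chain(p1)
    pl_res = pl_structure.get_chain(pl_chain)
    try:
        labeling = iface.label_overlap(
            pp_if, pl_if, _flip(amap), pp_res, pl_res, min_overlap,
            reference=f"{pp_structure.id}:{p1}",
        )
    except iface.InsufficientOverlapError:
        return PairRejection(pid, "insufficient_overlap")

    # superpose P3 onto P1 on aligned Cα pairs, map the ligand, test collision
    ca_pairs = [
        (pl_res[j].ca, pp_res[i].ca)
        for i, j in amap.pairs
        if pp_res[i].ca is not None and pl_res[j].ca is not None
    ]
    mobile = [a.coord for a, _ in ca_pairs]
    target = [b.coord for _, b in ca_pairs]
    transform = iface.superpose(mobile, target)
    mapped_ligand = iface.transform_atoms(transform, ligand.atoms)
    partner_atoms = pp_structure.chain_atoms([p2])
    if not iface.detect_collision(mapped_ligand, partner_atoms):
        return PairRejection(pid, "collision_free")

    return PPPLPair(
        pair_id=pid,
        p1_sequence=seq_pp,
        p2_length=len(pp_structure.get_chain(p2)),
        identity=amap.identity,
        interface_identity=_interface_identity(amap, pp_res, pl_res, pp_if, pl_if),
        labeling=labeling,
        competitive=True,
        pp_structure=pp_structure,
        pp_chains=(p1, p2),
        pl_structure=pl_structure,
        pl_chain=pl_chain,
        ligand=ligand,
        pp_interface=pp_if,
        pp_surface=pp_surf,
    )


def _flip(amap: iface.AlignmentMap) -> iface.AlignmentMap:
    # label_overlap maps PP positions -> PL positions; align_sequences(seq_pp,
    # seq_pl) already orients A=PP, B=PL, so no flip is needed — kept as an
    # explicit identity for readability at the call site.
    return amap


def reduce_redundancy(
    pairs: Sequence[PPPLPair],
    identity_cutoff: float = 0.40,
    min_peptide_length: int = 5,
) -> list[PPPLPair]:
    """Greedy sequence clustering of reference proteins + representative pick.

    Pairs are clustered on their P1 sequences: the longest unassigned
    sequence seeds a cluster and collects every pair whose P1 aligns to it
    with at least ``identity_cutoff`` identity.  Clusters in which every
    partner protein is a peptide shorter than ``min_peptide_length``
    residues are dropped entirely.  Each surviving cluster contributes the
    pair with the highest interface-residue identity (ties broken by pair
    id).  Idempotent: re-running on the output returns it unchanged.
    """
    if not pairs:
        return []
    order = sorted(
        range(len(pairs)),
        key=lambda k: (-len(pairs[k].p1_sequence), pairs[k].pair_id),
    )
    assigned = [False] * len(pairs)
    clusters: list[list[int]] = []
    for k in order:
        if assigned[k]:
            continue
        seed = pairs[k]
        cluster = [k]
        assigned[k] = True
        for m in order:
            if assigned[m]:
                continue
            ident = (
                1.0 if pairs[m].p1_sequence == seed.p1_sequence
                else iface.align_sequences(seed.p1_sequence, pairs[m].p1_sequence).identity
            )
            if ident >= identity_cutoff:
                cluster.append(m)
                assigned[m] = True
        clusters.append(cluster)

    kept: list[PPPLPair] = []
    for cluster in clusters:
        members = [pairs[k] for k in cluster]
        if all(p.p2_length < min_peptide_length for p in members):
            logger.info(
                "dropping cluster %s: only peptide partners (< %d residues)",
                [p.pair_id for p in members], min_peptide_length,
            )
            continue
        members.sort(key=lambda p: (-p.interface_identity, p.pair_id))
        kept.append(members[0])
    kept.sort(key=lambda p: p.pair_id)
    return kept


# ---------------------------------------------------------------------------
# Feature-table orchestration
# ---------------------------------------------------------------------------

def compute_interface_features(
    structure: Structure,
    query_chain: str,
    partner: Union[str, LigandInstance],
    conservation_table=None,
    hotspot_labels=None,
    interface_cutoff: float = 5.0,
    contact_cutoff: float = 5.0,
    sphere_radius: float = 10.0,
    surface_threshold: float = 0.05,
    reference_mode: str = "context",
    surface: Optional[set[ResidueID]] = None,
    pp_interface: Optional[iface.InterfaceAnnotation] = None,
):
    """Compute the 13-feature table for the interface of ``query_chain``.

    Runs the whole feature pipeline on the complex: surface definition on
    the isolated chain, complex-context SASA, protrusion, contact density,
    surface fraction, conservation matching (scores imputed 0 when no
    table is given) and the hot-spot surrogate.  Returns
    ``(features, interface, surface_set)``.
    """
    if surface is None:
        surface = surface_residues(structure, query_chain, surface_threshold)
    if pp_interface is None:
        pp_interface = iface.detect_interface(
            structure, query_chain, partner, interface_cutoff, surface
        )
    # complex-context SASA: atom.sasa now reflects the bound state
    chain_ids = list(structure.chains)
    compute_sasa(structure, chain_ids=chain_ids)
    prot = protrusion(structure, sphere_radius, chain_ids=chain_ids)
    densities = {
        rid: contact_density(structure, query_chain, rid, contact_cutoff)
        for rid in pp_interface.residues
    }
    fractions = {
        rid: surface_fraction(structure, query_chain, rid, reference_mode)
        for rid in pp_interface.residues
    }
    conservation = (
        match_conservation(conservation_table, structure, query_chain)
        if conservation_table is not None
        else None
    )
    hotspots = predict_hotspots(
        structure, query_chain, pp_interface.residues, fractions, densities,
        user_labels=hotspot_labels,
    )
    features = build_feature_vectors(
        structure, query_chain, pp_interface, surface, conservation,
        hotspots, prot.residue_values, densities, fractions,
    )
    return features, pp_interface, surface


def pair_feature_table(
    pair: PPPLPair, conservation_table=None, **kwargs
) -> pd.DataFrame:
    """Labelled feature table (13 features + ``label``) for an accepted pair."""
    if pair.pp_structure is None or pair.pp_chains is None:
        raise ValueError(f"pair {pair.pair_id} carries no structure context")
    p1, p2 = pair.pp_chains
    features, _, _ = compute_interface_features(
        pair.pp_structure, p1, p2,
        conservation_table=conservation_table,
        surface=pair.pp_surface,
        pp_interface=pair.pp_interface,
        **kwargs,
    )
    features = features.copy()
    features["label"] = [pair.labeling.labels[rid] for rid in features.index]
    features["pair_id"] = pair.pair_id
    return features
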