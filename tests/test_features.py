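"""Protrusion, contact density, surface fraction, conservation ingestion,
hot-spot surrogate, and feature-vector assembly."""

import numpy as np
import pytest

from smppi.features import (
    FEATURE_COLUMNS,
    build_feature_vectors,
    contact_density,
    HotspotLabeling,
    load_conservation,
    match_conservation,
    predict_hotspots,
    protrusion,
    surface_fraction,
)
from smppi.fixtures import make_sphere_cloud
from smppi.interface import InterfaceAnnotation
from smppi.structure import (
    Atom,
    Residue,
    ResidueID,
    Structure,
    compute_sasa,
)

V_BALL = 4.0 / 3.0 * np.pi * 10.0**3


def _one_atom(radius=1.70):
    res = Residue("A", 1, "", "ALA", [Atom(1, "CA", "C", [0, 0, 0], radius)])
    return Structure("one", {"A": [res]}), res


class TestProtrusion:
    def test_isolated_carbon_matches_closed_form(self):
        s, res = _one_atom(1.70)
        v_atom = 4.0 / 3.0 * np.pi * 1.70**3
        expected = (V_BALL - v_atom) / v_atom  # ≈ 202.5
        got = protrusion(s).residue_values[res.rid]
        assert got == pytest.approx(expected, rel=0.02)

    def test_two_sphere_union_inclusion_exclusion(self):
        d, r1, r2 = 2.0, 1.70, 1.70
        res1 = Residue("A", 1, "", "ALA", [Atom(1, "CA", "C", [0, 0, 0], r1)])
        res2 = Residue("A", 2, "", "ALA", [Atom(2, "CA", "C", [d, 0, 0], r2)])
        s = Structure("two", {"A": [res1, res2]})
        v_sphere = 4.0 / 3.0 * np.pi * r1**3
        v_lens = (
            np.pi * (r1 + r2 - d) ** 2
            * (d**2 + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2)
            / (12 * d)
        )
        v_union = 2 * v_sphere - v_lens
        expected = (V_BALL - v_union) / v_union
        got = protrusion(s).atom_values[(res1.rid, "CA")]
        assert got == pytest.approx(expected, rel=0.02)

    def test_fully_buried_atom_near_zero(self):
        # solid lattice of overlapping spheres filling the 10 Å ball
        a = 1.8
        n = int(np.ceil(11.0 / a))
        coords = [
            np.array([i, j, k], dtype=float) * a
            for i in range(-n, n + 1)
            for j in range(-n, n + 1)
            for k in range(-n, n + 1)
            if np.linalg.norm([i, j, k]) * a <= 11.0
        ]
        atoms = [Atom(i + 1, f"C{i}", "C", p, 1.70) for i, p in enumerate(coords)]
        res = Residue("A", 1, "", "ALA", atoms)
        s = Structure("block", {"A": [res]})
        centre_name = atoms[
            next(i for i, p in enumerate(coords) if np.linalg.norm(p) < 0.1)
        ].name
        cx = protrusion(s).atom_values[(res.rid, centre_name)]
        assert cx < 0.05

    def test_grid_refinement_reduces_error(self):
        s, res = _one_atom(1.70)
        v_atom = 4.0 / 3.0 * np.pi * 1.70**3
        expected = (V_BALL - v_atom) / v_atom
        err = {
            h: abs(protrusion(s, grid_spacing=h).residue_values[res.rid] - expected)
            for h in (0.5, 0.25)
        }
        assert err[0.25] <= err[0.5] / 2

    def test_zero_atom_residue_raises(self):
        s, _ = _one_atom()
        s.chains["A"].append(Residue("A", 2, "", "GLY", []))
        with pytest.raises(ValueError, match="no heavy atoms"):
            protrusion(s)

    def test_residue_value_is_mean_of_atoms(self):
        s = make_sphere_cloud(2, n_residues=6)
        result = protrusion(s)
        for res in s.get_chain("A"):
            vals = [result.atom_values[(res.rid, a.name)] for a in res.atoms]
            assert result.residue_values[res.rid] == pytest.approx(np.mean(vals))


def brute_force_density(structure, chain_id, rid, cutoff=5.0):
    chain = structure.get_chain(chain_id)
    res = next(r for r in chain if r.rid == rid)
    n = 0
    for atom in res.atoms:
        if atom.sasa <= 0:
            continue
        for other in chain:
            if other.rid == rid:
                continue
            for oa in other.atoms:
                if np.linalg.norm(atom.coord - oa.coord) <= cutoff:
                    n += 1
    return n / len(res.atoms)


class TestContactDensity:
    def test_isolated_residue_zero(self):
        s, res = _one_atom()
        compute_sasa(s)
        assert contact_density(s, "A", res.rid) == 0.0

    def test_one_atom_residue_with_three_neighbours(self):
        res = Residue("A", 1, "", "ALA", [Atom(1, "CA", "C", [0, 0, 0], 1.7)])
        other = Residue(
            "A", 2, "", "GLY",
            [Atom(2, "C1", "C", [4.0, 0, 0], 1.7),
             Atom(3, "C2", "C", [0, 4.0, 0], 1.7),
             Atom(4, "C3", "C", [0, 0, 4.0], 1.7)],
        )
        s = Structure("t", {"A": [res, other]})
        compute_sasa(s)
        assert contact_density(s, "A", res.rid) == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_brute_force_enumeration(self, seed):
        s = make_sphere_cloud(seed, n_residues=12, radius=7.0)
        compute_sasa(s)
        for res in s.get_chain("A"):
            assert contact_density(s, "A", res.rid) == pytest.approx(
                brute_force_density(s, "A", res.rid)
            )

    def test_missing_residue_raises(self):
        s, _ = _one_atom()
        with pytest.raises(ValueError, match="not in chain"):
            contact_density(s, "A", ResidueID("A", 99, ""))


def _extended_chain(n=3, spacing=3.8):
    residues = [
        Residue("A", i + 1, "", "ALA",
                [Atom(2 * i + 1, "CA", "C", [i * spacing, 0, 0], 1.7),
                 Atom(2 * i + 2, "CB", "C", [i * spacing, 1.5, 0.8], 1.7)])
        for i in range(n)
    ]
    return Structure("ext", {"A": residues})


class TestSurfaceFraction:
    def test_free_tripeptide_centre_fraction_is_one(self):
        s = _extended_chain(3)
        compute_sasa(s)
        f = surface_fraction(s, "A", ResidueID("A", 2, ""), "context")
        assert f == pytest.approx(1.0, abs=1e-9)

    def test_buried_residue_fraction_near_zero(self):
        s = _extended_chain(3)
        # enclose the centre residue in a cage of foreign atoms
        cage = []
        k = 0
        centre = np.array([3.8, 0.7, 0.4])
        for dx in (-2.4, 0.0, 2.4):
            for dy in (-2.4, 0.0, 2.4):
                for dz in (-2.4, 0.0, 2.4):
                    if (dx, dy, dz) == (0.0, 0.0, 0.0):
                        continue
                    k += 1
                    cage.append(Atom(100 + k, f"C{k}", "C",
                                     centre + [dx, dy, dz], 2.2))
        s.chains["B"] = [Residue("B", 1, "", "GLY", cage)]
        compute_sasa(s)
        f = surface_fraction(s, "A", ResidueID("A", 2, ""), "context")
        assert f < 0.05

    def test_adding_occluders_never_increases_fraction(self):
        s = _extended_chain(3)
        compute_sasa(s)
        rid = ResidueID("A", 2, "")
        prev = surface_fraction(s, "A", rid, "context")
        occluders = []
        for i, pos in enumerate([[3.8, 4.5, 0.0], [3.8, -3.5, 0.0],
                                 [3.8, 0.5, 3.5]]):
            occluders.append(Atom(200 + i, f"C{i}", "C", pos, 1.9))
            s.chains["B"] = [Residue("B", 1, "", "GLY", list(occluders))]
            compute_sasa(s)
            f = surface_fraction(s, "A", rid, "context")
            assert f <= prev + 1e-9
            assert 0.0 <= f <= 1.0
            prev = f

    def test_table_mode_unknown_residue_raises(self):
        s = _extended_chain(3)
        s.chains["A"][1].aa_type = "XYZ"
        compute_sasa(s)
        with pytest.raises(ValueError, match="XYZ"):
            surface_fraction(s, "A", ResidueID("A", 2, ""), "table")

    def test_table_mode_uses_reference_area(self):
        s = _extended_chain(3)
        compute_sasa(s)
        f = surface_fraction(s, "A", ResidueID("A", 2, ""), "table")
        assert 0.0 <= f <= 1.0


class TestConservation:
    TSV = "chain\tresnum\ticode\tscore\nA\t1\t\t-1.2\nA\t2\t\t0.3\nA\t3\t\t0.8\n"
    GRADES = (
        "\t Amino Acid Conservation Scores\n"
        "\t===============================\n"
        "- POS\t SEQ\t 3LATOM\tSCORE\tCOLOR\n"
        "   1\t  A\t ALA1:A\t-1.200\t  9\n"
        "   2\t  G\t GLY2:A\t 0.300\t  4\n"
        "   3\t  S\t SER3:A\t 0.800\t  2\n"
    )

    def test_three_line_tsv(self):
        table = load_conservation(self.TSV, "tsv")
        assert len(table.scores) == 3
        assert table.scores[ResidueID("A", 1, "")] == pytest.approx(-1.2)

    def test_grades_dialect_skips_header_junk(self):
        table = load_conservation(self.GRADES, "consurf_grades")
        assert len(table.scores) == 3
        assert table.scores[ResidueID("A", 3, "")] == pytest.approx(0.8)

    def test_dialects_agree(self):
        a = load_conservation(self.TSV, "tsv").scores
        b = load_conservation(self.GRADES, "consurf_grades").scores
        assert set(a) == set(b)
        for rid in a:
            assert a[rid] == pytest.approx(b[rid])

    def test_wrong_chain_hard_error(self):
        s = _extended_chain(3)
        wrong = self.TSV.replace("A\t", "B\t")
        table = load_conservation(wrong, "tsv")
        with pytest.raises(ValueError, match="numbering mismatch"):
            match_conservation(table, s, "A")

    def test_partial_match_reports_none(self):
        s = _extended_chain(5)
        table = load_conservation(
            "chain\tresnum\ticode\tscore\n"
            "A\t1\t\t-1.0\nA\t2\t\t0.0\nA\t3\t\t0.5\nA\t4\t\t0.1\n",
            "tsv",
        )
        matched = match_conservation(table, s, "A")
        assert matched[ResidueID("A", 5, "")] is None
        assert matched[ResidueID("A", 1, "")] == pytest.approx(-1.0)

    def test_unknown_dialect_raises(self):
        with pytest.raises(ValueError, match="dialect"):
            load_conservation(self.TSV, "csv")


class TestHotspots:
    def _maps(self):
        rids = [ResidueID("A", i, "") for i in range(1, 7)]
        fractions = dict(zip(rids, [0.05, 0.10, 0.30, 0.15, 0.60, 0.02]))
        densities = dict(zip(rids, [9.9, 8.0, 9.5, 8.5, 9.6, 8.2]))
        return set(rids), fractions, densities

    def test_buried_dense_residue_is_hotspot(self):
        rids, fr, dn = self._maps()
        lab = predict_hotspots(None, "A", rids, fr, dn)
        assert lab.labels[ResidueID("A", 1, "")]  # buried + dense
        assert lab.source == "predicted"

    def test_exposed_residue_not_hotspot(self):
        rids, fr, dn = self._maps()
        lab = predict_hotspots(None, "A", rids, fr, dn)
        assert not lab.labels[ResidueID("A", 5, "")]  # dense but exposed

    def test_sparse_residue_not_hotspot(self):
        rids, fr, dn = self._maps()
        lab = predict_hotspots(None, "A", rids, fr, dn)
        assert not lab.labels[ResidueID("A", 6, "")]  # buried but sparse

    def test_explicit_density_threshold(self):
        rids, fr, dn = self._maps()
        lab = predict_hotspots(None, "A", rids, fr, dn, density_threshold=100.0)
        assert not any(lab.labels.values())

    def test_user_labels_override_exactly(self):
        rids, fr, dn = self._maps()
        user = {rid: (rid.seq_number % 2 == 0) for rid in rids}
        lab = predict_hotspots(None, "A", rids, fr, dn, user_labels=user)
        assert lab.labels == user
        assert lab.source == "user-supplied"


class TestBuildFeatureVectors:
    def _setup(self):
        s = _extended_chain(8)
        rids = [r.rid for r in s.get_chain("A")]
        surface = set(rids)
        interface = InterfaceAnnotation("A", "B", set(rids[2:6]), 5.0)
        prot = {rid: float(i) for i, rid in enumerate(rids)}
        dens = {rid: 2.0 + i for i, rid in enumerate(rids)}
        frac = {rid: 0.1 * (i + 1) for i, rid in enumerate(rids)}
        cons = {rid: -0.5 + 0.1 * i for i, rid in enumerate(rids)}
        hs = HotspotLabeling({rid: i % 4 == 0 for i, rid in enumerate(rids)},
                             "predicted")
        return s, interface, surface, cons, hs, prot, dens, frac

    def test_thirteen_columns_and_central_values(self):
        s, iface, surf, cons, hs, prot, dens, frac = self._setup()
        df = build_feature_vectors(s, "A", iface, surf, cons, hs, prot, dens, frac)
        assert list(df.columns) == FEATURE_COLUMNS
        assert len(df) == 4
        for rid in df.index:
            assert df.loc[rid, "protru1"] == prot[rid]  # central is index 1
            assert df.loc[rid, "cons1"] == pytest.approx(cons[rid])
            assert df.loc[rid, "density"] == dens[rid]
            assert df.loc[rid, "surfaceFraction"] == frac[rid]

    def test_neighbours_are_nearest_by_ca_distance(self):
        s, iface, surf, cons, hs, prot, dens, frac = self._setup()
        df = build_feature_vectors(s, "A", iface, surf, cons, hs, prot, dens, frac)
        rid = ResidueID("A", 4, "")
        # linear chain: nearest four surface residues of 4 are 3, 5, 2, 6
        expected = [prot[rid]] + [prot[ResidueID("A", k, "")] for k in (3, 5, 2, 6)]
        assert [df.loc[rid, f"protru{i+1}"] for i in range(5)] == expected

    def test_hsf_patch_arithmetic(self):
        s, iface, surf, cons, hs, prot, dens, frac = self._setup()
        df = build_feature_vectors(s, "A", iface, surf, cons, hs, prot, dens, frac)
        for rid in df.index:
            from smppi.patches import build_patch

            patch = build_patch(s, rid, surf, n=8)
            expected = np.mean([hs.labels.get(m, False) for m in patch.members])
            assert df.loc[rid, "hsfPatch8"] == pytest.approx(expected)

    def test_missing_conservation_imputed_zero(self):
        s, iface, surf, cons, hs, prot, dens, frac = self._setup()
        cons = {rid: (None if rid.seq_number == 4 else v)
                for rid, v in cons.items()}
        df = build_feature_vectors(s, "A", iface, surf, cons, hs, prot, dens, frac)
        assert df.loc[ResidueID("A", 4, ""), "cons1"] == 0.0

    def test_deterministic_and_input_order_independent(self):
        s, iface, surf, cons, hs, prot, dens, frac = self._setup()
        df1 = build_feature_vectors(s, "A", iface, surf, cons, hs, prot, dens, frac)
        # rebuild every mapping with reversed insertion order
        rev = lambda d: dict(reversed(list(d.items())))
        iface2 = InterfaceAnnotation("A", "B", set(sorted(iface.residues,
                                                          reverse=True)), 5.0)
        df2 = build_feature_vectors(
            s, "A", iface2, set(sorted(surf, reverse=True)), rev(cons),
            HotspotLabeling(rev(hs.labels), hs.source), rev(prot), rev(dens),
            rev(frac),
        )
        assert df1.equals(df2)
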