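import numpy as np
import pytest

from smppi.structure import Atom, Residue, Structure


def _pdb_line(rec, serial, name, resname, chain, resnum, x, y, z,
              element, occ=1.0, altloc=" ", icode=" "):
    pname = f" {name:<3}" if len(element) == 1 and len(name) < 4 else f"{name:<4}"
    return (
        f"{rec:<6}{serial:>5} {pname}{altloc}{resname:<3} {chain}"
        f"{resnum:>4}{icode}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}  0.00"
        f"          {element:>2}"
    )


@pytest.fixture(scope="session")
def mini_pdb_text():
    """Hand-written 3-residue chain plus HOH, a sodium ion and a 9-atom
    benzamidine-like HET group."""
    lines = [
        _pdb_line("ATOM", 1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, "N"),
        _pdb_line("ATOM", 2, "CA", "ALA", "A", 1, 1.5, 0.0, 0.0, "C"),
        _pdb_line("ATOM", 3, "C", "ALA", "A", 1, 2.2, 1.3, 0.0, "C"),
        _pdb_line("ATOM", 4, "O", "ALA", "A", 1, 1.6, 2.4, 0.0, "O"),
        _pdb_line("ATOM", 5, "N", "GLY", "A", 2, 3.5, 1.2, 0.0, "N"),
        _pdb_line("ATOM", 6, "CA", "GLY", "A", 2, 4.4, 2.4, 0.0, "C"),
        _pdb_line("ATOM", 7, "C", "GLY", "A", 2, 5.8, 2.0, 0.3, "C"),
        _pdb_line("ATOM", 8, "N", "SER", "A", 3, 6.8, 2.9, 0.2, "N"),
        _pdb_line("ATOM", 9, "CA", "SER", "A", 3, 8.2, 2.6, 0.5, "C"),
        _pdb_line("ATOM", 10, "OG", "SER", "A", 3, 9.0, 3.8, 0.4, "O"),
        _pdb_line("HETATM", 11, "O", "HOH", "A", 101, 12.0, 0.0, 0.0, "O"),
        _pdb_line("HETATM", 12, "NA", "NA", "A", 102, 14.0, 0.0, 0.0, "NA"),
    ]
    # benzamidine-like group: 6-ring + C + 2 N
    ring = [(20.0, 0.0), (21.4, 0.0), (22.1, 1.2), (21.4, 2.4), (20.0, 2.4),
            (19.3, 1.2)]
    for i, (x, y) in enumerate(ring):
        lines.append(
            _pdb_line("HETATM", 13 + i, f"C{i+1}", "BEN", "A", 103, x, y, 0.0, "C")
        )
    lines += [
        _pdb_line("HETATM", 19, "C7", "BEN", "A", 103, 22.1, 3.6, 0.0, "C"),
        _pdb_line("HETATM", 20, "N1", "BEN", "A", 103, 21.4, 4.8, 0.0, "N"),
        _pdb_line("HETATM", 21, "N2", "BEN", "A", 103, 23.5, 3.6, 0.0, "N"),
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def altloc_pdb_text():
    lines = [
        _pdb_line("ATOM", 1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C",
                  occ=0.4, altloc="A"),
        _pdb_line("ATOM", 2, "CA", "ALA", "A", 1, 5.0, 0.0, 0.0, "C",
                  occ=0.6, altloc="B"),
        _pdb_line("ATOM", 3, "CA", "GLY", "A", 2, 3.8, 0.0, 0.0, "C"),
        "END",
    ]
    return "\n".join(lines) + "\n"


def make_single_atom_structure(radius=1.70, element="C"):
    res = Residue("A", 1, "", "ALA", [Atom(1, "CA", element, [0, 0, 0], radius)])
    return Structure("one", {"A": [res]})


@pytest.fixture(scope="session")
def pocket_pair_trio():
    """One competitive pair, one remote-ligand pair, one flat non-competitive
    pair, with ground truth for the first."""
    from smppi.fixtures import make_pocket_complex

    good = make_pocket_complex(1)
    remote = make_pocket_complex(2, ligand_placement="remote")
    flat = make_pocket_complex(3, pocket_depth=0.0)
    return good, remote, flat
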