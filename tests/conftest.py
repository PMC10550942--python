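"""Shared helpers: synthetic polar sites and tiny text fixtures."""

import numpy as np
import pytest

from aquabridge.chemistry import GeometryParams, PolarSite
from aquabridge.structure import AtomRecord


def unit(v):
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


def make_site(position, role="acceptor", element="O", orbital=None,
              hydrogen_toward=None, res_id=None, chain="A"):
    """A bare synthetic polar site with explicit orbital geometry."""
    params = GeometryParams()
    position = np.asarray(position, float)
    if res_id is None:
        make_site._counter += 1
        res_id = make_site._counter
    atom = AtomRecord(element=element, name=element, res_name="UNK",
                      chain=chain, res_id=res_id, position=position)
    site = PolarSite(atom=atom, role=role, hybridization="sp3",
                     rule="synthetic",
                     ideal_water_distance=params.ideal_distance(element))
    if hydrogen_toward is not None:
        h = position + 1.01 * unit(np.asarray(hydrogen_toward) - position)
        site.attached_hydrogens = [h]
    if orbital is not None:
        site.orbital_vectors = [unit(orbital)]
    elif hydrogen_toward is not None:
        site.orbital_vectors = list(site.donor_vectors)
    return site

make_site._counter = 0


def random_eligible_pair(rng, roles=("acceptor", "acceptor")):
    """Random constructible site pair with random orbital directions."""
    params = GeometryParams()
    elements = [rng.choice(["O", "N"]) for _ in range(2)]
    d = [params.ideal_distance(e) for e in elements]
    lo, hi = params.pair_window
    sep = rng.uniform(lo + 0.01, min(hi, d[0] + d[1]) - 0.01)
    Xi = rng.uniform(-10, 10, size=3)
    u = unit(rng.normal(size=3))
    Xj = Xi + sep * u
    sites = []
    for pos, role, el in zip((Xi, Xj), roles, elements):
        if role == "acceptor":
            sites.append(make_site(pos, role=role, element=el,
                                   orbital=rng.normal(size=3)))
        else:
            target = pos + 2.0 * unit(rng.normal(size=3))
            sites.append(make_site(pos, role=role, element=el,
                                   hydrogen_toward=target))
    return sites[0], sites[1]


MINI_PDB = """\
CRYST1   20.000   20.000   20.000  90.00  90.00  90.00 P 1           1
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.200   2.700   3.100  1.00  0.00           C
ATOM      3  C   ALA A   1       3.400   1.800   3.400  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  SER A   1       1.400   0.000   0.000  1.00  0.00           C
ATOM      3  OG ASER A   1       2.000   1.000   0.000  0.60  0.00           O
ATOM      4  OG BSER A   1       2.000  -1.000   0.000  0.40  0.00           O
HETATM    5  O   HOH A   2       5.000   5.000   5.000  1.00  0.00           O
END
"""


@pytest.fixture
def mini_pdb(tmp_path):
    p = tmp_path / "mini.pdb"
    p.write_text(MINI_PDB)
    return p


@pytest.fixture
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p
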