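"""Polar-site classification, hydrogen building and orbital vectors.

A *polar site* is a donor/acceptor-capable heavy atom (O or N) together
with its rebuilt polar hydrogens and the unit "orbital vectors" along
which it ideally donates (X-H axis) or accepts (sp2/sp3 lone-pair axis)
a hydrogen bond.  Sulphur is never emitted: protein-bound waters contact
it too rarely for reliable geometry statistics.

Ideal water-oxygen contact distances are element based: 2.73 A to oxygen
(and the general default), 2.87 A to nitrogen.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import AtomRecord, Structure, STANDARD_AA

__all__ = [
    "GeometryParams",
    "PolarSite",
    "classify_polar_sites",
    "build_polar_hydrogens",
    "orbital_vectors",
    "prepare_sites",
    "water_site",
]

OH_BOND = 0.96     # A, hydroxyl and water O-H
NH_BOND = 1.01     # A, amide/amine N-H
TETRAHEDRAL = 109.47122   # degrees
SP3_HALF = TETRAHEDRAL / 2.0


@dataclass
class GeometryParams:
    """Geometric thresholds of the water-building algorithm.

    Defaults follow the crystallographic survey this package models:
    ideal water contact distances of 2.73 A (O and general polar atoms)
    and 2.87 A (N); a pair window of mu +/- 2 sigma = 3.65-5.57 A on the
    bridged-atom distance (strict mode: +/- 1 sigma = 4.13-5.09 A); a
    2.99 A coordination cut-off; water internal geometry O-H = 0.96 A,
    H-O-H = 104.45 deg.
    """

    d_H2O_X: float = 2.73
    d_H2O_N: float = 2.87
    pair_window: tuple[float, float] = (3.65, 5.57)
    strict_window: tuple[float, float] = (4.13, 5.09)
    coordination_cutoff: float = 2.99
    OH_length: float = 0.96
    HOH_angle: float = 104.45
    clash_distance: float = 2.4
    merge_radius: float = 1.0
    hbond_search: float = 3.5

    def window(self, strict: bool = False) -> tuple[float, float]:
        return self.strict_window if strict else self.pair_window

    def ideal_distance(self, element: str) -> float:
        return self.d_H2O_N if element.upper() == "N" else self.d_H2O_X


@dataclass
class PolarSite:
    """A donor/acceptor-capable heavy atom with hydrogens and orbitals."""

    atom: AtomRecord
    role: str                 # donor | acceptor | both
    hybridization: str        # sp2 | sp3
    attached_hydrogens: list = field(default_factory=list)
    orbital_vectors: list = field(default_factory=list)
    ideal_water_distance: float = 2.73
    # geometry context used by the hydrogen/orbital builders
    rule: str = ""
    parent: np.ndarray | None = None
    aux: list = field(default_factory=list)

    @property
    def position(self) -> np.ndarray:
        return self.atom.position

    @property
    def can_donate(self) -> bool:
        return self.role in ("donor", "both") and \
            len(self.attached_hydrogens) > 0

    @property
    def can_accept(self) -> bool:
        return self.role in ("acceptor", "both")

    @property
    def donor_vectors(self) -> list:
        p = self.position
        return [_unit(h - p) for h in self.attached_hydrogens]

    @property
    def acceptor_vectors(self) -> list:
        n_don = len(self.attached_hydrogens)
        return self.orbital_vectors[n_don:] if self.can_donate \
            else self.orbital_vectors


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("degenerate (zero) direction vector")
    return v / n


def _rotate(v, axis, angle_deg):
    return Rotation.from_rotvec(
        np.radians(angle_deg) * _unit(np.asarray(axis, float))).apply(v)


# ---------------------------------------------------------------------------
# chemotype table

def _load_chemotypes() -> dict:
    table = {}
    text = resources.files("aquabridge.data").joinpath(
        "chemotypes.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        res, atom, role, hyb, rule, parent, aux = line.split("\t")
        table[(res, atom)] = dict(role=role, hybridization=hyb, rule=rule,
                                  parent=parent, aux=aux.split("|"))
    return table

_CHEMOTYPES = _load_chemotypes()


def _find(atoms: list[AtomRecord], name: str) -> AtomRecord | None:
    for a in atoms:
        if a.name == name:
            return a
    return None


# ---------------------------------------------------------------------------
# classification

def classify_polar_sites(s: Structure,
                         params: GeometryParams | None = None,
                         include_waters: bool = False) -> list[PolarSite]:
    """Emit every polar site of a structure (no hydrogens built yet).

    Covers side-chain O/N per the chemotype table, backbone carbonyl O
    (acceptor, sp2) and amide N (donor, sp2; proline skipped), OXT, and
    ligand polar atoms via element-based fallbacks.  Unknown chemotypes
    are skipped with a warning.
    """
    params = params or GeometryParams()
    residues = s.residues()
    res_list = list(residues.items())
    sites: list[PolarSite] = []

    for idx, (key, atoms) in enumerate(res_list):
        res_name = key[2]
        if atoms[0].is_water:
            if include_waters:
                for a in atoms:
                    if a.element == "O":
                        sites.append(PolarSite(
                            atom=a, role="both", hybridization="sp3",
                            rule="water",
                            ideal_water_distance=params.d_H2O_X))
            continue
        if atoms[0].is_ligand:
            sites.extend(_ligand_sites(atoms, params))
            continue
        if res_name not in STANDARD_AA:
            warnings.warn(f"unknown residue chemotype {res_name}; skipped")
            continue
        # backbone
        n = _find(atoms, "N")
        ca = _find(atoms, "CA")
        c = _find(atoms, "C")
        o = _find(atoms, "O")
        if n is not None and ca is not None and res_name != "PRO":
            prev_c = _previous_carbonyl(res_list, idx, n)
            sites.append(PolarSite(
                atom=n, role="donor", hybridization="sp2",
                rule="backbone_n", parent=ca.position.copy(),
                aux=[prev_c] if prev_c is not None else [],
                ideal_water_distance=params.d_H2O_N))
        if o is not None and c is not None and ca is not None:
            sites.append(PolarSite(
                atom=o, role="acceptor", hybridization="sp2",
                rule="carbonyl", parent=c.position.copy(),
                aux=[ca.position.copy()],
                ideal_water_distance=params.d_H2O_X))
        oxt = _find(atoms, "OXT")
        if oxt is not None and c is not None and ca is not None:
            sites.append(PolarSite(
                atom=oxt, role="acceptor", hybridization="sp2",
                rule="carbonyl", parent=c.position.copy(),
                aux=[ca.position.copy()],
                ideal_water_distance=params.d_H2O_X))
        # side chain
        for a in atoms:
            spec = _CHEMOTYPES.get((res_name, a.name))
            if spec is None:
                continue
            parent = _find(atoms, spec["parent"])
            aux = [_find(atoms, nm) for nm in spec["aux"]]
            if parent is None or any(x is None for x in aux):
                warnings.warn(
                    f"missing parent atoms for {res_name} {a.name}; "
                    "site demoted to acceptor-only")
                sites.append(PolarSite(
                    atom=a, role="acceptor",
                    hybridization=spec["hybridization"], rule="bare",
                    ideal_water_distance=params.ideal_distance(a.element)))
                continue
            sites.append(PolarSite(
                atom=a, role=spec["role"],
                hybridization=spec["hybridization"], rule=spec["rule"],
                parent=parent.position.copy(),
                aux=[x.position.copy() for x in aux],
                ideal_water_distance=params.ideal_distance(a.element)))
    return sites


def _previous_carbonyl(res_list, idx, n_atom) -> np.ndarray | None:
    """Position of the preceding residue's carbonyl C, if peptide-bonded."""
    for j in (idx - 1, idx + 1):
        if 0 <= j < len(res_list):
            c = _find(res_list[j][1], "C")
            if c is not None and \
                    np.linalg.norm(c.position - n_atom.position) < 1.6:
                return c.position.copy()
    return None


def _ligand_sites(atoms, params) -> list[PolarSite]:
    """Element-based fallback chemotypes for ligand polar atoms."""
    sites = []
    for a in atoms:
        if a.element not in ("O", "N"):
            continue
        # nearest bonded heavy atom as geometric parent
        others = [(np.linalg.norm(b.position - a.position), b)
                  for b in atoms if b is not a and b.element != "H"]
        others.sort(key=lambda t: t[0])
        parent = others[0][1].position.copy() \
            if others and others[0][0] < 1.8 else None
        if parent is None:
            warnings.warn(f"isolated ligand atom {a.name}; skipped")
            continue
        if a.element == "O":
            warnings.warn(
                f"ligand atom {a.res_name} {a.name}: element fallback "
                "O -> both/sp3")
            sites.append(PolarSite(
                atom=a, role="both", hybridization="sp3",
                rule="ligand_o", parent=parent,
                ideal_water_distance=params.d_H2O_X))
        else:
            warnings.warn(
                f"ligand atom {a.res_name} {a.name}: element fallback "
                "N -> donor/sp2")
            sites.append(PolarSite(
                atom=a, role="donor", hybridization="sp2",
                rule="ligand_n", parent=parent, aux=[],
                ideal_water_distance=params.d_H2O_N))
    return sites


# ---------------------------------------------------------------------------
# hydrogen building

def build_polar_hydrogens(site: PolarSite,
                          neighbours: list[PolarSite] | None = None
                          ) -> PolarSite:
    """Place polar hydrogens on a site at ideal geometry.

    Amide, guanidinium, imidazole and ring N-H hydrogens are placed at
    ideal planar geometry; NH3+ hydrogens staggered; rotatable hydroxyls
    are sampled at 60 deg torsion steps and fixed to the orientation with
    the best summed H-bond score to *neighbours* (first staggered position
    when isolated -- deterministic tie-break).
    """
    neighbours = neighbours or []
    x = site.position
    rule = site.rule
    hs: list[np.ndarray] = []

    if rule == "backbone_n":
        if not site.aux:
            # chain terminus: no peptide plane to place the H in
            site.role = "acceptor"
            site.rule = "bare"
            warnings.warn("backbone N without preceding carbonyl; demoted")
            return site
        prev_c = site.aux[0]
        # H along the external bisector of the two N bonds, in-plane
        d = -(_unit(site.parent - x) + _unit(prev_c - x))
        hs.append(x + NH_BOND * _unit(d))
    elif rule == "amide2":
        b = _unit(site.parent - x)             # N -> C bond
        normal = _unit(np.cross(site.aux[0] - site.parent,
                                x - site.parent))
        hs.append(x + NH_BOND * _rotate(b, normal, 120.0))
        hs.append(x + NH_BOND * _rotate(b, normal, -120.0))
    elif rule == "ring_n_h":
        d = -(_unit(site.parent - x) + _unit(site.aux[0] - x))
        hs.append(x + NH_BOND * _unit(d))
    elif rule == "nh3":
        axis = _unit(x - site.parent)
        ref = _unit(site.aux[0] - site.parent)
        perp = _unit(ref - np.dot(ref, axis) * axis)
        for torsion in (60.0, 180.0, 300.0):
            d = _rotate(
                math.cos(math.radians(180 - TETRAHEDRAL)) * axis
                + math.sin(math.radians(180 - TETRAHEDRAL)) * perp,
                axis, torsion)
            hs.append(x + NH_BOND * _unit(d))
    elif rule == "hydroxyl":
        hs.append(_best_hydroxyl_h(site, neighbours))
    # carbonyl, ring_n, water, bare, ligand_o: no hydrogens

    site.attached_hydrogens = hs
    return site


def _hydroxyl_candidates(site: PolarSite) -> list[np.ndarray]:
    x = site.position
    axis = _unit(x - site.parent)
    ref = _unit(site.aux[0] - site.parent)
    perp = _unit(ref - np.dot(ref, axis) * axis)
    out = []
    # C-O-H angle ~ tetrahedral; six staggered/eclipsed torsions
    tilt = 180.0 - TETRAHEDRAL
    base = math.cos(math.radians(tilt)) * axis \
        + math.sin(math.radians(tilt)) * perp
    for torsion in (60.0, 120.0, 180.0, 240.0, 300.0, 360.0):
        out.append(x + OH_BOND * _unit(_rotate(base, axis, torsion)))
    return out


def _best_hydroxyl_h(site: PolarSite, neighbours: list[PolarSite]
                     ) -> np.ndarray:
    """Hydroxyl torsion with the best summed H-bond score (12-10 radial
    times squared-cosine directional weight); first candidate on ties."""
    candidates = _hydroxyl_candidates(site)
    if not neighbours:
        return candidates[0]
    x = site.position
    best, best_score = candidates[0], -np.inf
    for h in candidates:
        oh = _unit(h - x)
        score = 0.0
        for nb in neighbours:
            if nb.atom is site.atom:
                continue
            d = np.linalg.norm(nb.position - x)
            if not 2.0 < d < 3.5 or not nb.can_accept:
                continue
            q = site.ideal_water_distance / d
            radial = -(5 * q ** 12 - 6 * q ** 10)
            cosang = max(float(np.dot(oh, _unit(nb.position - x))), 0.0)
            score += max(radial, 0.0) * cosang ** 2
        if score > best_score + 1e-12:
            best, best_score = h, score
    return best


# ---------------------------------------------------------------------------
# orbital vectors

def orbital_vectors(site: PolarSite) -> list[np.ndarray]:
    """Unit direction vectors for ideal H-bond formation.

    Donors contribute one vector per attached hydrogen (heavy atom -> H);
    sp2 acceptors two in-plane lone pairs at 120 deg from the parent
    bond; sp3 acceptors tetrahedral lone pairs completing the valence
    around the existing bonds and hydrogens.
    """
    x = site.position
    vectors: list[np.ndarray] = []
    if site.can_donate:
        vectors.extend(site.donor_vectors)
    if site.can_accept:
        vectors.extend(_acceptor_lone_pairs(site))
    site.orbital_vectors = vectors
    return vectors


def _acceptor_lone_pairs(site: PolarSite) -> list[np.ndarray]:
    x = site.position
    rule = site.rule
    if rule == "carbonyl":
        b = _unit(site.parent - x)
        normal = _unit(np.cross(site.aux[0] - site.parent,
                                x - site.parent))
        return [_rotate(b, normal, 120.0), _rotate(b, normal, -120.0)]
    if rule in ("ring_n", "ring_n_h") and not site.attached_hydrogens:
        d = -(_unit(site.parent - x) + _unit(site.aux[0] - x))
        return [_unit(d)]
    if rule in ("ring_n_h",):
        # protonated ring N: donor only
        return []
    # sp3: complete the tetrahedron around the known bonds
    known = []
    if site.parent is not None:
        known.append(_unit(site.parent - x))
    known.extend(site.donor_vectors)
    if len(known) >= 2:
        u1, u2 = known[0], known[1]
        cross = np.cross(u1, u2)
        if np.linalg.norm(cross) < 1e-8:
            raise ValueError("collinear parent geometry at sp3 acceptor")
        nrm = _unit(cross)
        bis = -_unit(u1 + u2)
        half = math.radians(SP3_HALF)
        return [_unit(math.cos(half) * bis + math.sin(half) * nrm),
                _unit(math.cos(half) * bis - math.sin(half) * nrm)]
    if len(known) == 1:
        # bare sp3 acceptor (e.g. ether-like ligand O): three staggered
        # lone pairs around the single bond
        u = known[0]
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, u)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        perp = _unit(ref - np.dot(ref, u) * u)
        tilt = 180.0 - TETRAHEDRAL
        base = _unit(math.cos(math.radians(tilt)) * (-u)
                     + math.sin(math.radians(tilt)) * perp)
        return [_unit(_rotate(base, -u, t)) for t in (0.0, 120.0, 240.0)]
    return []


# ---------------------------------------------------------------------------
# convenience

def prepare_sites(s: Structure, params: GeometryParams | None = None,
                  include_waters: bool = False) -> list[PolarSite]:
    """Classify sites, build hydrogens (two passes so that rotatable
    hydroxyls see their neighbours' fixed hydrogens), compute orbitals."""
    sites = classify_polar_sites(s, params, include_waters=include_waters)
    fixed = [st for st in sites if st.rule != "hydroxyl"]
    for st in fixed:
        build_polar_hydrogens(st, [])
    for st in sites:
        if st.rule == "hydroxyl":
            build_polar_hydrogens(st, sites)
    for st in sites:
        orbital_vectors(st)
    return sites


def water_site(oxygen, hydrogens, params: GeometryParams | None = None
               ) -> PolarSite:
    """A water molecule as a polar site: two O-H donor vectors plus two
    tetrahedral lone pairs."""
    params = params or GeometryParams()
    oxygen = np.asarray(oxygen, float)
    atom = AtomRecord(element="O", name="O", res_name="HOH", chain="W",
                      res_id=0, position=oxygen, is_water=True)
    site = PolarSite(atom=atom, role="both", hybridization="sp3",
                     rule="water",
                     attached_hydrogens=[np.asarray(h, float)
                                         for h in hydrogens],
                     ideal_water_distance=params.d_H2O_X)
    u1, u2 = site.donor_vectors
    nrm = _unit(np.cross(u1, u2))
    bis = -_unit(u1 + u2)
    half = math.radians(SP3_HALF)
    site.orbital_vectors = (
        site.donor_vectors
        + [_unit(math.cos(half) * bis + math.sin(half) * nrm),
           _unit(math.cos(half) * bis - math.sin(half) * nrm)])
    return site
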