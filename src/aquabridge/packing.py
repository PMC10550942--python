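"""Simplified side-chain packing with solvated rotamer pairs.

Rotamers are built from idealised residue templates (biotite's chemical
component dictionary) superimposed onto the fixed backbone, with chi
angles set from a small bundled backbone-independent library.  Bridging
waters constructed between cross-position rotamer pairs are duplicated
onto both rotamers, creating solvated copies that compete with their
unsolvated originals through Goldstein dead-end elimination and a
Monte-Carlo simulated-annealing search for the GMEC.

The energy model is a deliberately simple stand-in (soft Lennard-Jones
sterics plus the package's directional H-bond term); no parity with any
published force field is claimed, and packing quality is validated
against exhaustive enumeration on small problems, not against absolute
recovery rates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
from scipy.spatial.transform import Rotation

from .chemistry import GeometryParams, PolarSite, prepare_sites, _unit
from .energy import HBondModel
from .structure import AtomRecord, Structure
from .waterbuild import WaterPlacement, merge_waters, solvate_pair

__all__ = [
    "Rotamer",
    "PackingProblem",
    "enumerate_rotamers",
    "build_solvated_rotamers",
    "pairwise_energy",
    "dee_goldstein",
    "mc_simulated_annealing",
    "emit_model",
    "load_rotamer_library",
]

# chi dihedral atom quadruples, in order chi1..chi4
CHI_DEFS = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "ALA": [], "GLY": [], "PRO": [],
}

# side-chain bond tree (atom -> parent), used to find the atoms that
# rotate with each chi
SIDECHAIN_PARENTS = {
    "ALA": {"CB": "CA"},
    "ARG": {"CB": "CA", "CG": "CB", "CD": "CG", "NE": "CD", "CZ": "NE",
            "NH1": "CZ", "NH2": "CZ"},
    "ASN": {"CB": "CA", "CG": "CB", "OD1": "CG", "ND2": "CG"},
    "ASP": {"CB": "CA", "CG": "CB", "OD1": "CG", "OD2": "CG"},
    "CYS": {"CB": "CA", "SG": "CB"},
    "GLN": {"CB": "CA", "CG": "CB", "CD": "CG", "OE1": "CD", "NE2": "CD"},
    "GLU": {"CB": "CA", "CG": "CB", "CD": "CG", "OE1": "CD", "OE2": "CD"},
    "GLY": {},
    "HIS": {"CB": "CA", "CG": "CB", "ND1": "CG", "CD2": "CG",
            "CE1": "ND1", "NE2": "CD2"},
    "ILE": {"CB": "CA", "CG1": "CB", "CG2": "CB", "CD1": "CG1"},
    "LEU": {"CB": "CA", "CG": "CB", "CD1": "CG", "CD2": "CG"},
    "LYS": {"CB": "CA", "CG": "CB", "CD": "CG", "CE": "CD", "NZ": "CE"},
    "MET": {"CB": "CA", "CG": "CB", "SD": "CG", "CE": "SD"},
    "PHE": {"CB": "CA", "CG": "CB", "CD1": "CG", "CD2": "CG",
            "CE1": "CD1", "CE2": "CD2", "CZ": "CE1"},
    "PRO": {"CB": "CA", "CG": "CB", "CD": "CG"},
    "SER": {"CB": "CA", "OG": "CB"},
    "THR": {"CB": "CA", "OG1": "CB", "CG2": "CB"},
    "TRP": {"CB": "CA", "CG": "CB", "CD1": "CG", "CD2": "CG",
            "NE1": "CD1", "CE2": "CD2", "CE3": "CD2", "CZ2": "CE2",
            "CZ3": "CE3", "CH2": "CZ2"},
    "TYR": {"CB": "CA", "CG": "CB", "CD1": "CG", "CD2": "CG",
            "CE1": "CD1", "CE2": "CD2", "CZ": "CE1", "OH": "CZ"},
    "VAL": {"CB": "CA", "CG1": "CB", "CG2": "CB"},
}


@dataclass
class Rotamer:
    position: tuple            # (chain, res_id)
    res_type: str
    chi: tuple                 # degrees
    atoms: list                # AtomRecord, full heavy-atom residue
    attached_waters: list = field(default_factory=list)
    self_energy: float = 0.0
    sites: list = field(default_factory=list)   # PolarSite, lazily built
    bridge_ids: frozenset = frozenset()

    @property
    def is_solvated(self) -> bool:
        return bool(self.attached_waters)

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def solvated_copy(self, water: WaterPlacement,
                      bridge_id: int) -> "Rotamer":
        return Rotamer(
            position=self.position, res_type=self.res_type, chi=self.chi,
            atoms=self.atoms,
            attached_waters=self.attached_waters + [water],
            self_energy=self.self_energy, sites=self.sites,
            bridge_ids=self.bridge_ids | {bridge_id})


@dataclass
class PackingProblem:
    context: Structure                      # fixed atoms (backbone etc.)
    positions: list = field(default_factory=list)
    rotamer_sets: dict = field(default_factory=dict)
    params: GeometryParams = field(default_factory=GeometryParams)
    energy_model: HBondModel = field(default_factory=HBondModel)
    pair_energies: dict = field(default_factory=dict)   # cache

    def n_assignments(self) -> int:
        n = 1
        for p in self.positions:
            n *= len(self.rotamer_sets[p])
        return n


# ---------------------------------------------------------------------------
# rotamer building

def load_rotamer_library() -> dict:
    lib: dict[str, list] = {}
    text = resources.files("aquabridge.data").joinpath(
        "rotamers.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        res, chis, freq = line.split("\t")
        angles = () if chis == "-" else tuple(
            float(x) for x in chis.split(","))
        lib.setdefault(res, []).append((angles, float(freq)))
    return lib

_LIBRARY = load_rotamer_library()


def _kabsch(P: np.ndarray, Q: np.ndarray):
    """Rigid transform (R, t) minimising |R P + t - Q|."""
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, cq - R @ cp


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    return math.degrees(math.atan2(
        float(np.dot(np.cross(b1, v), w)), float(np.dot(v, w))))


def _descendants(res_type: str, root: str) -> set:
    parents = SIDECHAIN_PARENTS[res_type]
    out = set()
    frontier = [root]
    while frontier:
        node = frontier.pop()
        for child, parent in parents.items():
            if parent == node and child not in out:
                out.add(child)
                frontier.append(child)
    return out


def _set_chi(coords: dict, res_type: str, chi_index: int,
             target: float) -> None:
    a, b, c, d = CHI_DEFS[res_type][chi_index]
    current = _dihedral(coords[a], coords[b], coords[c], coords[d])
    axis = _unit(coords[c] - coords[b])
    rot = Rotation.from_rotvec(
        math.radians(target - current) * axis)
    pivot = coords[c]
    moving = _descendants(res_type, c)
    for name in moving:
        if name in coords:
            coords[name] = pivot + rot.apply(coords[name] - pivot)


def _template_coords(res_type: str) -> dict:
    import biotite.structure.info as info

    arr = info.residue(res_type)
    return {str(arr.atom_name[i]): arr.coord[i].astype(float)
            for i in range(arr.array_length())
            if str(arr.element[i]) != "H" and str(arr.atom_name[i]) != "OXT"}


def enumerate_rotamers(backbone: Structure, position: tuple,
                       res_type: str, expand_chi1: bool = False
                       ) -> list[Rotamer]:
    """Build library conformers onto the backbone frame of *position*.

    With ``expand_chi1`` each conformer is emitted in three copies
    (chi1, chi1 +/- 10 deg) for finer sampling near ligands.
    """
    if res_type not in CHI_DEFS:
        raise ValueError(f"unknown residue type {res_type!r}")
    res_atoms = {a.name: a for a in backbone.atoms
                 if (a.chain, a.res_id) == tuple(position)
                 and not a.is_water}
    for needed in ("N", "CA", "C"):
        if needed not in res_atoms:
            raise ValueError(
                f"position {position} lacks backbone atom {needed}")
    template = _template_coords(res_type)
    P = np.array([template[n] for n in ("N", "CA", "C")])
    Q = np.array([res_atoms[n].position for n in ("N", "CA", "C")])
    R, t = _kabsch(P, Q)
    placed = {n: R @ xyz + t for n, xyz in template.items()}
    # keep the crystal backbone (incl. O) fixed; template supplies the rest
    for n in ("N", "CA", "C", "O"):
        if n in res_atoms:
            placed[n] = res_atoms[n].position.copy()

    chi_defs = CHI_DEFS[res_type]
    rotamers = []
    for angles, freq in _LIBRARY[res_type]:
        chi_sets = [angles]
        if expand_chi1 and angles:
            chi_sets = [(angles[0] + d,) + tuple(angles[1:])
                        for d in (0.0, 10.0, -10.0)]
        for chis in chi_sets:
            coords = {n: xyz.copy() for n, xyz in placed.items()}
            for k, chi in enumerate(chis):
                if k < len(chi_defs):
                    _set_chi(coords, res_type, k, chi)
            atoms = []
            chain, res_id = position
            for name, xyz in coords.items():
                element = name[0] if name[0] in ("N", "C", "O", "S") else "C"
                atoms.append(AtomRecord(
                    element=element, name=name, res_name=res_type,
                    chain=chain, res_id=res_id, position=xyz))
            rotamers.append(Rotamer(position=tuple(position),
                                    res_type=res_type, chi=tuple(chis),
                                    atoms=atoms))
    return rotamers


# ---------------------------------------------------------------------------
# energies

STERIC_SIGMA = 3.2      # A, generic heavy-atom contact distance
STERIC_EPS = 0.05       # kcal/mol, shallow generic well
STERIC_CAP = 50.0       # kcal/mol, soft clash cap
INTERACTION_CUTOFF = 10.0


def _steric(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    if coords_a.size == 0 or coords_b.size == 0:
        return 0.0
    d = np.linalg.norm(
        coords_a[:, None, :] - coords_b[None, :, :], axis=2)
    d = d[d < 6.0]
    if d.size == 0:
        return 0.0
    d = np.clip(d, 0.5, None)
    q6 = (STERIC_SIGMA / d) ** 6
    e = STERIC_EPS * (q6 * q6 - 2.0 * q6)
    return float(np.clip(e, -STERIC_EPS, STERIC_CAP).sum())


def _rotamer_sites(rot: Rotamer, params: GeometryParams) -> list[PolarSite]:
    if not rot.sites:
        rot.sites = prepare_sites(Structure(atoms=rot.atoms), params)
    return rot.sites


def _min_sep(rot_a: Rotamer, rot_b: Rotamer) -> float:
    ca = rot_a.heavy_coords()
    cb = rot_b.heavy_coords()
    return float(np.linalg.norm(
        ca[:, None, :] - cb[None, :, :], axis=2).min())


def pairwise_energy(rot_a: Rotamer, rot_b: Rotamer,
                    params: GeometryParams | None = None,
                    energy_model: HBondModel | None = None) -> float:
    """Interaction energy of two rotamers at distinct positions.

    Soft Lennard-Jones sterics over cross heavy atoms plus H-bond terms
    of each rotamer's attached waters against the partner's polar sites.
    When both rotamers carry copies of the same bridge, the shared-water
    terms are half-weighted on each copy so the physical water counts
    once.
    """
    params = params or GeometryParams()
    energy_model = energy_model or HBondModel()
    if _min_sep(rot_a, rot_b) > INTERACTION_CUTOFF:
        return 0.0
    e = _steric(rot_a.heavy_coords(), rot_b.heavy_coords())
    shared = rot_a.bridge_ids & rot_b.bridge_ids
    for rot, other in ((rot_a, rot_b), (rot_b, rot_a)):
        other_sites = _rotamer_sites(other, params)
        other_coords = other.heavy_coords()
        for w in rot.attached_waters:
            dup = w.bridge_id in shared
            weight = 0.5 if dup else 1.0
            # steric of the water oxygen against the partner atoms
            d = np.linalg.norm(other_coords - w.oxygen, axis=1)
            partner_mask = d > 1e-6
            close = d[partner_mask & (d < 2.4)]
            e += weight * STERIC_CAP * len(close) / 10.0
            for site in other_sites:
                if np.linalg.norm(site.position - w.oxygen) \
                        < energy_model.params.cutoff_distance:
                    e += weight * energy_model.hbond_energy(w, site)
    # a shared bridge's intrinsic (site_i + site_j) energy, once
    for bid in shared:
        for w in rot_a.attached_waters:
            if w.bridge_id == bid:
                e += w.energy
                break
    return e


def compute_self_energies(problem: PackingProblem) -> None:
    ctx = np.array([a.position for a in problem.context.atoms
                    if not a.is_water]) \
        if problem.context.atoms else np.zeros((0, 3))
    for pos in problem.positions:
        for rot in problem.rotamer_sets[pos]:
            own = {(a.chain, a.res_id) for a in rot.atoms}
            if ctx.size:
                mask = np.array(
                    [(a.chain, a.res_id) not in own
                     for a in problem.context.atoms if not a.is_water])
                env = ctx[mask]
            else:
                env = ctx
            e = _steric(rot.heavy_coords(), env)
            # half of each attached bridge's energy; the other half comes
            # in through the partner copy (or is an accepted approximation
            # when the partner ends up unsolvated)
            for w in rot.attached_waters:
                e += 0.5 * w.energy
                if env.size:
                    d = np.linalg.norm(env - w.oxygen, axis=1)
                    e += STERIC_CAP * int((d < 2.4).sum()) / 10.0
            rot.self_energy = e


# ---------------------------------------------------------------------------
# solvation of rotamer pairs

def build_solvated_rotamers(problem: PackingProblem) -> PackingProblem:
    """Solvate every cross-position rotamer pair (and rotamer-context
    pairs) and add solvated copies alongside the unsolvated originals.

    Waters bridging to fixed context atoms (the ligand rule generalised:
    the partner cannot carry state) are attached to the rotamer only.
    """
    params, model = problem.params, problem.energy_model
    ctx_struct = problem.context
    ctx_sites = prepare_sites(ctx_struct, params)
    ctx_coords = np.array([a.position for a in ctx_struct.atoms
                           if not a.is_water]) \
        if ctx_struct.atoms else np.zeros((0, 3))
    design_keys = {tuple(p) for p in problem.positions}
    ctx_sites = [s for s in ctx_sites
                 if (s.atom.chain, s.atom.res_id) not in design_keys]

    bridge_counter = itertools.count()
    additions: dict[tuple, list[Rotamer]] = {p: [] for p in problem.positions}

    pos = problem.positions
    for ia in range(len(pos)):
        for ib in range(ia + 1, len(pos)):
            for ra in problem.rotamer_sets[pos[ia]]:
                for rb in problem.rotamer_sets[pos[ib]]:
                    env = np.vstack([c for c in (
                        ctx_coords, ra.heavy_coords(), rb.heavy_coords())
                        if c.size]) if ctx_coords.size else np.vstack(
                        [ra.heavy_coords(), rb.heavy_coords()])
                    waters = solvate_pair(
                        _rotamer_sites(ra, params),
                        _rotamer_sites(rb, params),
                        params, model, environment=env)
                    for w in waters:
                        bid = next(bridge_counter)
                        w.bridge_id = bid
                        additions[pos[ia]].append(ra.solvated_copy(w, bid))
                        additions[pos[ib]].append(rb.solvated_copy(w, bid))
        # rotamer vs fixed context (backbone outside the design shell,
        # ligand pose): water goes to the rotamer exclusively
        for ra in problem.rotamer_sets[pos[ia]]:
            env = np.vstack([ctx_coords, ra.heavy_coords()]) \
                if ctx_coords.size else ra.heavy_coords()
            waters = solvate_pair(_rotamer_sites(ra, params), ctx_sites,
                                  params, model, environment=env)
            for w in waters:
                bid = next(bridge_counter)
                w.bridge_id = bid
                additions[pos[ia]].append(ra.solvated_copy(w, bid))

    for p in problem.positions:
        problem.rotamer_sets[p] = problem.rotamer_sets[p] + additions[p]
    return problem


# ---------------------------------------------------------------------------
# combinatorial search

def _energy_tables(problem: PackingProblem):
    compute_self_energies(problem)
    pos = problem.positions
    selfE = {p: np.array([r.self_energy
                          for r in problem.rotamer_sets[p]])
             for p in pos}
    pairE = {}
    for i in range(len(pos)):
        for j in range(i + 1, len(pos)):
            A, B = problem.rotamer_sets[pos[i]], problem.rotamer_sets[pos[j]]
            table = np.zeros((len(A), len(B)))
            for a, ra in enumerate(A):
                for b, rb in enumerate(B):
                    table[a, b] = pairwise_energy(
                        ra, rb, problem.params, problem.energy_model)
            pairE[(pos[i], pos[j])] = table
    return selfE, pairE


def _pair_table(pairE, p, q):
    if (p, q) in pairE:
        return pairE[(p, q)]
    return pairE[(q, p)].T


def total_energy(problem: PackingProblem, assignment: dict,
                 selfE=None, pairE=None) -> float:
    if selfE is None or pairE is None:
        selfE, pairE = _energy_tables(problem)
    pos = problem.positions
    e = sum(selfE[p][assignment[p]] for p in pos)
    for i in range(len(pos)):
        for j in range(i + 1, len(pos)):
            e += _pair_table(pairE, pos[i], pos[j])[
                assignment[pos[i]], assignment[pos[j]]]
    return float(e)


def dee_goldstein(problem: PackingProblem, tables=None
                  ) -> tuple[PackingProblem, dict]:
    """Goldstein dead-end elimination to a fixed point.

    Rotamer r at position i is eliminated if some competitor r' always
    interacts at least as favourably:
    E(r) - E(r') + sum_j min_s [E(r,s) - E(r',s)] > 0.
    Returns the pruned problem and the surviving index map.
    """
    selfE, pairE = tables if tables is not None else _energy_tables(problem)
    pos = problem.positions
    alive = {p: list(range(len(problem.rotamer_sets[p]))) for p in pos}
    changed = True
    while changed:
        changed = False
        for p in pos:
            if len(alive[p]) <= 1:
                continue
            dead = set()
            for r in alive[p]:
                for rp in alive[p]:
                    if rp == r or rp in dead:
                        continue
                    gap = selfE[p][r] - selfE[p][rp]
                    for q in pos:
                        if q == p:
                            continue
                        tab = _pair_table(pairE, p, q)
                        diffs = [tab[r, s] - tab[rp, s]
                                 for s in alive[q]]
                        gap += min(diffs)
                    if gap > 1e-12:
                        dead.add(r)
                        break
            if dead:
                alive[p] = [r for r in alive[p] if r not in dead]
                if not alive[p]:
                    raise RuntimeError(
                        f"DEE emptied position {p}")  # must not happen
                changed = True
    pruned = PackingProblem(
        context=problem.context, positions=list(pos),
        rotamer_sets={p: [problem.rotamer_sets[p][r] for r in alive[p]]
                      for p in pos},
        params=problem.params, energy_model=problem.energy_model)
    return pruned, alive


def mc_simulated_annealing(problem: PackingProblem, seed: int = 0,
                           n_steps: int | None = None,
                           t_start: float = 15.0, t_end: float = 0.05
                           ) -> tuple[dict, float]:
    """Metropolis single-flip chain over a geometric cooling schedule.

    Returns the best-seen assignment (position -> rotamer index) and its
    energy; reproducible for a given seed.
    """
    selfE, pairE = _energy_tables(problem)
    rng = np.random.default_rng(seed)
    pos = problem.positions
    sizes = {p: len(problem.rotamer_sets[p]) for p in pos}
    assignment = {p: int(rng.integers(sizes[p])) for p in pos}

    def delta(p, new):
        old = assignment[p]
        d = selfE[p][new] - selfE[p][old]
        for q in pos:
            if q == p:
                continue
            tab = _pair_table(pairE, p, q)
            d += tab[new, assignment[q]] - tab[old, assignment[q]]
        return float(d)

    energy = total_energy(problem, assignment, selfE, pairE)
    best, best_e = dict(assignment), energy
    if n_steps is None:
        n_steps = 400 * max(len(pos), 1) * max(
            max(sizes.values(), default=1), 1)
        n_steps = min(n_steps, 60000)
    cool = (t_end / t_start) ** (1.0 / max(n_steps - 1, 1))
    T = t_start
    flippable = [p for p in pos if sizes[p] > 1]
    if not flippable:
        return assignment, energy
    for _ in range(n_steps):
        p = flippable[int(rng.integers(len(flippable)))]
        new = int(rng.integers(sizes[p]))
        if new == assignment[p]:
            continue
        d = delta(p, new)
        if d <= 0 or rng.random() < math.exp(-d / T):
            assignment[p] = new
            energy += d
            if energy < best_e - 1e-12:
                best, best_e = dict(assignment), energy
        T *= cool
    return best, best_e


def exhaustive_gmec(problem: PackingProblem) -> tuple[dict, float]:
    """Brute-force oracle over all assignments (small problems only)."""
    selfE, pairE = _energy_tables(problem)
    pos = problem.positions
    best, best_e = None, np.inf
    for combo in itertools.product(
            *[range(len(problem.rotamer_sets[p])) for p in pos]):
        assignment = dict(zip(pos, combo))
        e = total_energy(problem, assignment, selfE, pairE)
        if e < best_e:
            best, best_e = assignment, e
    return best, float(best_e)


def emit_model(problem: PackingProblem, assignment: dict) -> Structure:
    """Fixed context + chosen rotamers + de-duplicated bridge waters."""
    out = problem.context.copy()
    design_keys = {tuple(p) for p in problem.positions}
    out.atoms = [a for a in out.atoms
                 if (a.chain, a.res_id) not in design_keys]
    waters: list[WaterPlacement] = []
    seen_bridges = set()
    for p in problem.positions:
        rot = problem.rotamer_sets[p][assignment[p]]
        out.atoms.extend(replace(a, position=a.position.copy())
                         for a in rot.atoms)
        for w in rot.attached_waters:
            bid = w.bridge_id
            if bid is not None and bid in seen_bridges:
                continue  # the duplicated copy is the same physical water
            if bid is not None:
                seen_bridges.add(bid)
            waters.append(w)
    waters = merge_waters(waters, problem.params.merge_radius)
    res_id = max((a.res_id for a in out.atoms), default=0) + 1
    for w in waters:
        out.atoms.extend(w.as_atoms(res_id))
        res_id += 1
    return out
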