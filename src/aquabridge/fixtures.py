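"""Deterministic synthetic structures with analytically known bridging waters.

The generator emulates the statistical world of the crystallographic
survey this package is built on: water-contact legs drawn from
Normal(2.73, 0.09) A for oxygen partners and Normal(2.87, 0.11) A for
nitrogen partners, bridging angles from Normal(111, 16.7) deg, with
nitrogen sites making up ~16% of contacts (10,000 of 61,000 observed).
Angles are redrawn until the implied polar-atom separation lies strictly
inside the eligibility window -- the generator plants bridging
geometries the algorithm is defined over, not a tuned subset.

Each polar site is realised as a minimal real fragment: a carbonyl
(CA-C=O, sp2 acceptor) or an imidazole-like ring nitrogen (CG-ND1-CE1,
sp2 acceptor) oriented so that one lone pair points exactly at the
analytic water position.  Optional Gaussian jitter displaces each
planted constellation rigidly (one isotropic draw per bridge or
coordination cluster; decoys move individually): coordinate
uncertainty in crystal structures moves covalently bonded groups
together -- independent per-atom noise of this size would imply
chemically impossible bond-length distortions -- and under this model
the deviation between the predicted and the analytic water position is
exactly the 3-D |N(0, sd)| displacement of the constellation.  The
returned ground-truth waters always keep their analytic (pre-jitter)
positions, mimicking prediction from perturbed coordinates against
fixed crystallographic truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .chemistry import GeometryParams, prepare_sites, _unit
from .structure import AtomRecord, Structure, ReferenceSphere
from .waterbuild import WaterPlacement, orient_hydrogens

__all__ = ["FixtureSpec", "make_bridge_fixture", "make_sphere_fixture"]

LEG_O = (2.73, 0.09)
LEG_N = (2.87, 0.11)
ANGLE = (111.0, 16.7)
FRACTION_N = 0.16
BRIDGE_SPACING = 12.0   # A between planted bridges: keeps them independent


@dataclass
class FixtureSpec:
    seed: int = 0
    n_bridges: int = 3
    leg_distances: tuple[float, float] | None = None  # None: draw from survey
    bridge_angle: float | None = None                 # None: draw from survey
    jitter_sd: float = 0.0
    decoy_atoms: int = 10
    coordination: int = 2        # central-water coordination (sphere fixture)
    n_neighbours: int = 2        # planted waters beyond the 6 A eval border

    def __post_init__(self):
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.bridge_angle is not None \
                and not 0.0 < self.bridge_angle < 180.0:
            raise ValueError("bridge_angle must lie in (0, 180)")


def _rotate(v, axis, angle_deg):
    return Rotation.from_rotvec(
        math.radians(angle_deg) * _unit(np.asarray(axis, float))).apply(v)


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _perpendicular(u, rng) -> np.ndarray:
    v = _random_unit(rng)
    w = v - np.dot(v, u) * u
    while np.linalg.norm(w) < 1e-6:
        v = _random_unit(rng)
        w = v - np.dot(v, u) * u
    return w / np.linalg.norm(w)


def _carbonyl_fragment(X, W, rng, res_id) -> list[AtomRecord]:
    """CA-C=O fragment whose sp2 lone pair at O points exactly at W."""
    o_vec = _unit(W - X)
    n = _perpendicular(o_vec, rng)          # sp2 plane normal
    bond = _rotate(o_vec, n, 120.0)         # O -> C direction
    c = X + 1.23 * bond
    ca = c + 1.52 * _rotate(-bond, n, 120.0)
    mk = lambda el, nm, pos: AtomRecord(
        element=el, name=nm, res_name="GLY", chain="F", res_id=res_id,
        position=pos)
    return [mk("C", "CA", ca), mk("C", "C", c), mk("O", "O", X)]


def _ring_n_fragment(X, W, rng, res_id) -> list[AtomRecord]:
    """CG-ND1-CE1 imidazole-like fragment; the ring-N lone pair (external
    bisector of the two ring bonds) points exactly at W."""
    o_vec = _unit(W - X)
    n = _perpendicular(o_vec, rng)
    half = 54.0   # half-angle between the two ring bonds and -lone-pair
    d1 = _rotate(-o_vec, n, half)
    d2 = _rotate(-o_vec, n, -half)
    mk = lambda el, nm, pos: AtomRecord(
        element=el, name=nm, res_name="HIS", chain="F", res_id=res_id,
        position=pos)
    return [mk("C", "CG", X + 1.38 * d1), mk("N", "ND1", X),
            mk("C", "CE1", X + 1.32 * d2)]


def _draw_leg(rng, params: GeometryParams,
              fixed: tuple | None) -> tuple[float, bool]:
    """(ideal-contact distance used for construction, is_nitrogen)."""
    if fixed is not None:
        return fixed
    is_n = bool(rng.random() < FRACTION_N)
    return (params.d_H2O_N if is_n else params.d_H2O_X), is_n


def _plant_bridge(center, rng, params: GeometryParams, spec: FixtureSpec,
                  res_id_start: int):
    """One bridge: two site fragments + the analytic water placement."""
    W = np.asarray(center, float)
    leg_i = _draw_leg(rng, params, None) if spec.leg_distances is None \
        else (spec.leg_distances[0], False)
    leg_j = _draw_leg(rng, params, None) if spec.leg_distances is None \
        else (spec.leg_distances[1], False)
    d_i, n_i = leg_i
    d_j, n_j = leg_j
    lo, hi = params.pair_window
    for _ in range(1000):
        theta = spec.bridge_angle if spec.bridge_angle is not None \
            else rng.normal(*ANGLE)
        if not 0.0 < theta < 180.0:
            continue
        sep = math.sqrt(d_i ** 2 + d_j ** 2
                        - 2 * d_i * d_j * math.cos(math.radians(theta)))
        if lo + 1e-9 < sep < hi - 1e-9:
            break
    else:
        raise RuntimeError("could not draw an eligible bridge angle")
    u = _random_unit(rng)
    v = _rotate(u, _perpendicular(u, rng), theta)
    Xi, Xj = W + d_i * u, W + d_j * v
    frag_i = (_ring_n_fragment if n_i else _carbonyl_fragment)(
        Xi, W, rng, res_id_start)
    frag_j = (_ring_n_fragment if n_j else _carbonyl_fragment)(
        Xj, W, rng, res_id_start + 1)
    return frag_i + frag_j, W, (Xi, Xj)


def _planted_placement(W, atoms, params: GeometryParams
                       ) -> WaterPlacement:
    """Ground-truth WaterPlacement (satisfies the water invariants)."""
    sites = prepare_sites(Structure(atoms=list(atoms)), params)
    best = sorted(sites, key=lambda s: np.linalg.norm(s.position - W))[:2]
    return orient_hydrogens(W, best[0], best[1], params)[0]


def _add_decoys(atoms, waters, n, rng, box_lo, box_hi,
                max_radius=None, center=None):
    """Carbon decoys kept >= 3.0 A from every atom and planted water."""
    existing = [a.position for a in atoms] + [w for w in waters]
    count = 0
    attempts = 0
    while count < n and attempts < 200 * max(n, 1):
        attempts += 1
        p = rng.uniform(box_lo, box_hi, size=3)
        if max_radius is not None and \
                np.linalg.norm(p - center) > max_radius:
            continue
        if all(np.linalg.norm(p - q) >= 3.0 for q in existing):
            atoms.append(AtomRecord(
                element="C", name="CA", res_name="GLY", chain="D",
                res_id=9000 + count, position=p))
            existing.append(p)
            count += 1


def make_bridge_fixture(spec: FixtureSpec,
                        params: GeometryParams | None = None
                        ) -> tuple[Structure, list[WaterPlacement]]:
    """Mini pseudo-peptide constellation with planted bridging waters.

    Bridges are laid out on a 12 A grid so that sites of different
    bridges can never form eligible cross-pairs; carbon decoys are added
    away from the planted geometry.  Returns the (optionally jittered)
    structure and the analytic ground-truth placements.
    """
    params = params or GeometryParams()
    rng = np.random.default_rng(spec.seed)
    atoms: list[AtomRecord] = []
    truth: list[WaterPlacement] = []
    side = max(1, int(math.ceil(spec.n_bridges ** (1.0 / 3.0))))
    centers = []
    for b in range(spec.n_bridges):
        i, j, k = b % side, (b // side) % side, b // (side * side)
        centers.append(np.array([i, j, k], float) * BRIDGE_SPACING)
    for b, center in enumerate(centers):
        frag, W, _ = _plant_bridge(center, rng, params, spec, 10 * b + 1)
        truth.append(_planted_placement(W, frag, params))
        atoms.extend(frag)
    if atoms:
        lo = np.min([a.position for a in atoms], axis=0) - 4.0
        hi = np.max([a.position for a in atoms], axis=0) + 4.0
    else:
        lo, hi = np.full(3, -6.0), np.full(3, 6.0)
    _add_decoys(atoms, [t.oxygen for t in truth], spec.decoy_atoms,
                rng, lo, hi)
    _apply_jitter(atoms, spec.jitter_sd, rng)
    return Structure(atoms=atoms), truth


def _apply_jitter(atoms, sd: float, rng) -> None:
    """Rigid per-constellation displacement.

    Bridge fragments share residue ids within one decade (10b+1, 10b+2),
    so ``res_id // 10`` groups the two fragments of a bridge (and the
    central coordination cluster of a sphere fixture) into one rigid
    unit; decoys (chain D) move one by one.
    """
    if sd <= 0:
        return
    shifts: dict = {}
    for a in atoms:
        if a.is_water:
            continue
        key = (a.chain, a.res_id if a.chain == "D" else a.res_id // 10)
        if key not in shifts:
            shifts[key] = rng.normal(scale=sd, size=3)
        a.position = a.position + shifts[key]


def _coordination_directions(k: int, rng) -> list[np.ndarray]:
    """k unit directions with pairwise angles near the observed bridging
    angle (111 deg): planar/tetrahedral templates, randomly rotated."""
    t = math.radians(111.0)
    if k == 2:
        base = [np.array([math.sin(t / 2), 0, math.cos(t / 2)]),
                np.array([-math.sin(t / 2), 0, math.cos(t / 2)])]
    elif k == 3:
        # trigonal-pyramidal: pairwise angles ~111 deg
        tilt = math.radians(68.0)
        base = [np.array([math.sin(tilt) * math.cos(a),
                          math.sin(tilt) * math.sin(a),
                          math.cos(tilt)])
                for a in (0.0, 2 * math.pi / 3, 4 * math.pi / 3)]
    else:
        s = 1.0 / math.sqrt(3.0)
        base = [np.array(v) * s for v in
                [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]][:k]
    R = Rotation.random(random_state=int(rng.integers(2 ** 31)))
    return [R.apply(b) for b in base]


def make_sphere_fixture(spec: FixtureSpec,
                        params: GeometryParams | None = None
                        ) -> tuple[ReferenceSphere, list[WaterPlacement]]:
    """A 20 A reference sphere with a planted central water.

    The central water is coordinated by ``spec.coordination`` acceptor
    fragments at ideal contact distances (all within the 2.99 A
    coordination cut-off); ``spec.n_neighbours`` further bridges are
    planted beyond the 6 A evaluation border to exercise border
    filtering.  The central water atom itself is part of the structure.
    """
    params = params or GeometryParams()
    rng = np.random.default_rng(spec.seed)
    center = np.zeros(3)
    atoms: list[AtomRecord] = []
    truth: list[WaterPlacement] = []

    dirs = _coordination_directions(max(spec.coordination, 2), rng)
    frag_atoms: list[AtomRecord] = []
    for k, u in enumerate(dirs):
        is_n = rng.random() < FRACTION_N
        d0 = params.d_H2O_N if is_n else params.d_H2O_X
        X = center + d0 * u
        frag = (_ring_n_fragment if is_n else _carbonyl_fragment)(
            X, center, rng, 100 + k)
        frag_atoms.extend(frag)
    truth.append(_planted_placement(center, frag_atoms, params))
    atoms.extend(frag_atoms)

    for m in range(spec.n_neighbours):
        u = _random_unit(rng)
        dist = rng.uniform(8.0, 14.0)
        frag, W, _ = _plant_bridge(center + dist * u, rng, params, spec,
                                   200 + 10 * m)
        truth.append(_planted_placement(W, frag, params))
        atoms.extend(frag)

    # the central water is present exactly once, as the sphere demands
    atoms.append(AtomRecord(element="O", name="O", res_name="HOH",
                            chain="W", res_id=1, position=center.copy(),
                            is_water=True))
    lo, hi = np.full(3, -11.0), np.full(3, 11.0)
    _add_decoys(atoms, [t.oxygen for t in truth], spec.decoy_atoms,
                rng, lo, hi, max_radius=19.0, center=center)
    _apply_jitter(atoms, spec.jitter_sd, rng)
    sphere = ReferenceSphere(central_water=center,
                             atoms=Structure(atoms=atoms))
    return sphere, truth
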