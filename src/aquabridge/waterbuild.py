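"""The core algorithm: place bridging waters between polar-site pairs.

For a pair of polar atoms Xi, Xj at an eligible separation, every point
at the ideal H-bond distance from both lies on a circle perpendicular to
the Xi-Xj axis.  Its centre and radius follow from the triangle
(Xi, Xj, water) via Heron's formula.  The water oxygen is the perimeter
point closest to the projection of the midpoint of the shortest segment
between the two sites' orbital vectors -- the position with ideal H-bond
distances and minimal deviation from the ideal orbital directions.
Hydrogens are then attached at 0.96 A / 104.45 deg in one or two
orientation variants depending on the donor/acceptor roles of the pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .chemistry import GeometryParams, PolarSite, _unit
from .structure import AtomRecord, Structure

__all__ = [
    "BridgeCircle",
    "WaterPlacement",
    "GeometryError",
    "pair_eligible",
    "bridge_circle",
    "closest_approach_midpoint",
    "place_water_oxygen",
    "orient_hydrogens",
    "construct_water",
    "solvate_pair",
    "solvate_structure",
]


class GeometryError(ValueError):
    """Geometrically impossible construction (should have been filtered)."""


@dataclass
class BridgeCircle:
    """Circle of points at ideal H-bond distance from both polar atoms."""

    center: np.ndarray
    radius: float
    normal: np.ndarray      # unit vector along Xi -> Xj


@dataclass
class WaterPlacement:
    """A constructed water: O and two H positions plus bookkeeping."""

    oxygen: np.ndarray
    hydrogens: list
    site_i: PolarSite | None = None
    site_j: PolarSite | None = None
    orientation_variant: int = 1
    energy_i: float = 0.0
    energy_j: float = 0.0
    parallel_fallback: bool = False
    bridge_id: int | None = None

    @property
    def energy(self) -> float:
        return self.energy_i + self.energy_j

    def as_atoms(self, res_id: int, chain: str = "W") -> list[AtomRecord]:
        o = AtomRecord(element="O", name="O", res_name="HOH", chain=chain,
                       res_id=res_id, position=self.oxygen.copy(),
                       is_water=True)
        hs = [AtomRecord(element="H", name=f"H{k + 1}", res_name="HOH",
                         chain=chain, res_id=res_id, position=h.copy(),
                         is_water=True)
              for k, h in enumerate(self.hydrogens)]
        return [o] + hs


# ---------------------------------------------------------------------------
# geometric construction

def pair_eligible(site_i: PolarSite, site_j: PolarSite,
                  params: GeometryParams, strict: bool = False) -> bool:
    """True iff the separation lies strictly inside the pair window and
    the sites belong to distinct residues (or molecules)."""
    if site_i.atom.residue_key == site_j.atom.residue_key:
        return False
    lo, hi = params.window(strict)
    d = float(np.linalg.norm(site_i.position - site_j.position))
    return lo < d < hi


def bridge_circle(Xi, Xj, d_i: float, d_j: float) -> BridgeCircle:
    """Centre and radius of the ideal-distance circle (Heron's formula).

    Every point P on the circle satisfies |P-Xi| = d_i and |P-Xj| = d_j.
    """
    Xi = np.asarray(Xi, float)
    Xj = np.asarray(Xj, float)
    d = float(np.linalg.norm(Xj - Xi))
    if d < 1e-9:
        raise GeometryError("coincident polar atoms")
    if d > d_i + d_j + 1e-9 or d < abs(d_i - d_j) - 1e-9:
        raise GeometryError(
            f"triangle inequality violated: |XiXj|={d:.3f}, "
            f"d_i={d_i}, d_j={d_j}")
    normal = (Xj - Xi) / d
    # foot of the altitude from the water vertex onto the Xi-Xj base;
    # r is the altitude, i.e. 2*Heron_area / d
    a_i = (d * d + d_i * d_i - d_j * d_j) / (2.0 * d)
    r_sq = d_i * d_i - a_i * a_i
    radius = math.sqrt(max(r_sq, 0.0))
    return BridgeCircle(center=Xi + a_i * normal, radius=radius,
                        normal=normal)


def closest_approach_midpoint(p_i, o_i, p_j, o_j) -> tuple[np.ndarray, bool]:
    """Midpoint of the shortest segment between two lines.

    Returns ``(point, parallel_flag)``.  For parallel directions the
    documented fallback is the midpoint between each origin's projection
    onto the other line.
    """
    p_i = np.asarray(p_i, float)
    p_j = np.asarray(p_j, float)
    u = _unit(np.asarray(o_i, float))
    v = _unit(np.asarray(o_j, float))
    w0 = p_i - p_j
    b = float(np.dot(u, v))
    denom = 1.0 - b * b
    if denom < 1e-10:
        qi = p_j + np.dot(p_i - p_j, v) * v   # p_i projected onto line j
        qj = p_i + np.dot(p_j - p_i, u) * u   # p_j projected onto line i
        return 0.5 * (qi + qj), True
    d_ = float(np.dot(u, w0))
    e_ = float(np.dot(v, w0))
    t = (b * e_ - d_) / denom
    s = (e_ - b * d_) / denom
    return 0.5 * ((p_i + t * u) + (p_j + s * v)), False


def place_water_oxygen(circle: BridgeCircle, midpoint,
                       tiebreak_dirs=None) -> np.ndarray:
    """Perimeter point nearest the in-plane projection of *midpoint*.

    The midpoint is projected onto the circle plane and shifted to the
    perimeter along the ray from the centre.  If the projection falls on
    the centre itself, the perimeter point with the smallest summed
    angular deviation from *tiebreak_dirs* is chosen by a 1 deg grid scan
    (a fixed in-plane axis when no directions are supplied).
    """
    m = np.asarray(midpoint, float)
    c, n, r = circle.center, circle.normal, circle.radius
    if r <= 0.0:
        return c.copy()
    in_plane = (m - c) - np.dot(m - c, n) * n
    norm = np.linalg.norm(in_plane)
    if norm > 1e-9:
        return c + (r / norm) * in_plane
    # degenerate projection: deterministic 1-degree perimeter scan
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, n)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = _unit(ref - np.dot(ref, n) * n)
    e2 = np.cross(n, e1)
    angles = np.radians(np.arange(0.0, 360.0, 1.0))
    pts = c + r * (np.cos(angles)[:, None] * e1
                   + np.sin(angles)[:, None] * e2)
    if not tiebreak_dirs:
        return pts[0]
    score = np.zeros(len(pts))
    for origin, direction in tiebreak_dirs:
        rel = pts - np.asarray(origin, float)
        rel /= np.linalg.norm(rel, axis=1)[:, None]
        score += np.arccos(np.clip(
            rel @ _unit(np.asarray(direction, float)), -1.0, 1.0))
    return pts[int(np.argmin(score))]


# canonical water frame: O at origin, H bisector along +z, H's in the
# xz-plane, lone pairs in the yz-plane pointing into -z
def _water_frame(params: GeometryParams):
    half_h = math.radians(params.HOH_angle / 2.0)
    half_lp = math.radians(109.47122 / 2.0)
    h1 = np.array([math.sin(half_h), 0.0, math.cos(half_h)])
    h2 = np.array([-math.sin(half_h), 0.0, math.cos(half_h)])
    l1 = np.array([0.0, math.sin(half_lp), -math.cos(half_lp)])
    l2 = np.array([0.0, -math.sin(half_lp), -math.cos(half_lp)])
    return h1, h2, l1, l2


def _aligned_water(oxygen, sources, targets, params, site_i, site_j,
                   variant) -> WaterPlacement:
    rot, _ = Rotation.align_vectors(np.asarray(targets, float),
                                    np.asarray(sources, float))
    h1_0, h2_0, _, _ = _water_frame(params)
    hs = [oxygen + params.OH_length * rot.apply(h1_0),
          oxygen + params.OH_length * rot.apply(h2_0)]
    return WaterPlacement(oxygen=oxygen.copy(), hydrogens=hs,
                          site_i=site_i, site_j=site_j,
                          orientation_variant=variant)


def orient_hydrogens(oxygen, site_i: PolarSite, site_j: PolarSite,
                     params: GeometryParams | None = None
                     ) -> list[WaterPlacement]:
    """Attach water hydrogens in one or two orientation variants.

    Two acceptors: hydrogens point at the acceptors (one variant).  Two
    donors: the lone pairs face the donors, hydrogens away (one variant).
    Any mixed donor/acceptor combination: exactly two variants.
    """
    params = params or GeometryParams()
    oxygen = np.asarray(oxygen, float)
    u_i = _unit(site_i.position - oxygen)
    u_j = _unit(site_j.position - oxygen)
    h1_0, h2_0, l1_0, l2_0 = _water_frame(params)

    acc_i, acc_j = site_i.can_accept, site_j.can_accept
    don_i, don_j = site_i.can_donate, site_j.can_donate

    if acc_i and acc_j and not (don_i or don_j):
        return [_aligned_water(oxygen, [h1_0, h2_0], [u_i, u_j],
                               params, site_i, site_j, 1)]
    if don_i and don_j and not (acc_i or acc_j):
        return [_aligned_water(oxygen, [l1_0, l2_0], [u_i, u_j],
                               params, site_i, site_j, 1)]
    # mixed: each partner is served once as acceptor of a water hydrogen
    # where possible; a pure donor partner instead receives the water
    # lone pair in both (mirror-image) variants
    if acc_i and acc_j:
        variants = [([h1_0, l1_0], [u_j, u_i]),
                    ([h1_0, l1_0], [u_i, u_j])]
    elif acc_j:  # i donates to the water, water donates to j
        variants = [([h1_0, l1_0], [u_j, u_i]),
                    ([h1_0, l2_0], [u_j, u_i])]
    else:        # mirror case: j donates to the water
        variants = [([h1_0, l1_0], [u_i, u_j]),
                    ([h1_0, l2_0], [u_i, u_j])]
    return [_aligned_water(oxygen, src, tgt, params, site_i, site_j, k + 1)
            for k, (src, tgt) in enumerate(variants)]


def construct_water(site_i: PolarSite, site_j: PolarSite,
                    params: GeometryParams | None = None
                    ) -> list[WaterPlacement]:
    """Full geometric construction for one polar-site pair.

    All orbital-vector combinations of the two sites are evaluated at the
    closest-approach step and the combination with the smallest summed
    angular deviation from the constructed oxygen is used.
    """
    params = params or GeometryParams()
    Xi, Xj = site_i.position, site_j.position
    circle = bridge_circle(Xi, Xj, site_i.ideal_water_distance,
                           site_j.ideal_water_distance)
    vecs_i = site_i.orbital_vectors or [_unit(Xj - Xi)]
    vecs_j = site_j.orbital_vectors or [_unit(Xi - Xj)]
    best = None
    for o_i in vecs_i:
        for o_j in vecs_j:
            mid, parallel = closest_approach_midpoint(Xi, o_i, Xj, o_j)
            oxy = place_water_oxygen(
                circle, mid, tiebreak_dirs=[(Xi, o_i), (Xj, o_j)])
            dev = (_angle(oxy - Xi, o_i) + _angle(oxy - Xj, o_j))
            if best is None or dev < best[0] - 1e-12:
                best = (dev, oxy, parallel)
    _, oxygen, parallel = best
    placements = orient_hydrogens(oxygen, site_i, site_j, params)
    for p in placements:
        p.parallel_fallback = parallel
    return placements


def _angle(v, w) -> float:
    return float(np.arccos(np.clip(
        np.dot(_unit(np.asarray(v, float)), _unit(np.asarray(w, float))),
        -1.0, 1.0)))


# ---------------------------------------------------------------------------
# solvation drivers

def _clash_free(oxygen, heavy_coords: np.ndarray, exclude: np.ndarray,
                min_dist: float) -> bool:
    """Water oxygen must stay >= min_dist from every heavy atom other
    than its two partner atoms."""
    if heavy_coords.shape[0] == 0:
        return True
    d = np.linalg.norm(heavy_coords - oxygen, axis=1)
    mask = np.ones(len(d), dtype=bool)
    for pos in exclude:
        mask &= np.linalg.norm(heavy_coords - pos, axis=1) > 1e-6
    return bool(np.all(d[mask] >= min_dist))


def _gate_and_pick(placements, energy_model, heavy_coords, params
                   ) -> WaterPlacement | None:
    """Energy-gate the orientation variants; keep the best accepted."""
    best = None
    for p in placements:
        if not _clash_free(p.oxygen, heavy_coords,
                           [p.site_i.position, p.site_j.position],
                           params.clash_distance):
            continue
        p.energy_i = energy_model.hbond_energy(p, p.site_i)
        p.energy_j = energy_model.hbond_energy(p, p.site_j)
        if not energy_model.accept_water(p):
            continue
        if best is None or p.energy < best.energy:
            best = p
    return best


def solvate_pair(sites_i: list[PolarSite], sites_j: list[PolarSite],
                 params: GeometryParams, energy_model,
                 environment: np.ndarray | None = None,
                 strict: bool = False) -> list[WaterPlacement]:
    """Bridge waters between two site groups (e.g. two rotamers).

    Every eligible cross-group pair is constructed, energy-gated and
    clash-filtered against *environment* heavy-atom coordinates.
    """
    env = environment if environment is not None else np.zeros((0, 3))
    out = []
    for si in sites_i:
        for sj in sites_j:
            if not pair_eligible(si, sj, params, strict=strict):
                continue
            try:
                placements = construct_water(si, sj, params)
            except GeometryError:
                continue
            best = _gate_and_pick(placements, energy_model, env, params)
            if best is not None:
                out.append(best)
    return out


def merge_waters(waters: list[WaterPlacement], merge_radius: float
                 ) -> list[WaterPlacement]:
    """Collapse waters closer than the merge radius to the lowest-energy
    one (deterministic: sorted by energy, then construction order)."""
    order = sorted(range(len(waters)),
                   key=lambda k: (waters[k].energy, k))
    kept: list[WaterPlacement] = []
    for k in order:
        w = waters[k]
        if all(np.linalg.norm(w.oxygen - u.oxygen) >= merge_radius
               for u in kept):
            kept.append(w)
    return kept


def solvate_structure(s: Structure, params: GeometryParams, energy_model,
                      strict: bool = False,
                      sites: list[PolarSite] | None = None
                      ) -> list[WaterPlacement]:
    """Posterior mode: solvate every eligible polar-site pair of a fixed
    structure, then de-duplicate by the merge radius."""
    from .chemistry import prepare_sites

    if sites is None:
        sites = prepare_sites(s, params)
    heavy = np.array([a.position for a in s.atoms
                      if a.element not in ("H", "D") and not a.is_water]) \
        if s.atoms else np.zeros((0, 3))
    accepted: list[WaterPlacement] = []
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            si, sj = sites[i], sites[j]
            if not pair_eligible(si, sj, params, strict=strict):
                continue
            try:
                placements = construct_water(si, sj, params)
            except GeometryError:
                continue
            best = _gate_and_pick(placements, energy_model, heavy, params)
            if best is not None:
                accepted.append(best)
    return merge_waters(accepted, params.merge_radius)
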