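"""Directional hydrogen-bond energy and the water acceptance gate.

The original packing program's force field is unpublished; a standard
12-10 hydrogen-bond potential with cosine angular weights stands in:

    E = well_depth * [5 (d0/d)^12 - 6 (d0/d)^10] * cos^k(t_don) * cos^k(t_acc)

with d the heavy-atom separation, d0 the element-specific ideal contact
distance, t_don the deviation from linearity at the donated hydrogen and
t_acc the deviation of the acceptor's best lone-pair/orbital direction
from the incoming hydrogen.  E is clamped to zero beyond the distance
cut-off, when any angular cosine is non-positive, and in the short-range
repulsive regime (steric rejection is handled by a geometric clash
filter).  Acceptance never depends on the absolute energy scale, only on
geometry and threshold monotonicity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemistry import PolarSite, _unit

__all__ = ["HBondParams", "HBondModel", "hbond_energy", "accept_water"]


@dataclass
class HBondParams:
    well_depth: float = -5.0          # kcal/mol at ideal geometry
    distance_exponents: tuple = (12, 10)
    angular_weight: int = 2           # exponent on the cosine terms
    accept_threshold: float = -2.0    # kcal/mol (presets: -4.0, -5.0)
    cutoff_distance: float = 3.5      # A
    gate: str = "per_leg"             # per_leg | sum

    def __post_init__(self):
        if self.well_depth >= 0:
            raise ValueError("well_depth must be negative")
        if self.accept_threshold > 0:
            raise ValueError("accept_threshold must be <= 0")


class HBondModel:
    """Evaluates water-site H-bond energies and the acceptance gate."""

    def __init__(self, params: HBondParams | None = None):
        self.params = params or HBondParams()

    # -- energy -----------------------------------------------------------
    def hbond_energy(self, w, site: PolarSite) -> float:
        """Best (most negative) H-bond energy between a placed water and
        a polar site, over the geometrically possible polarities."""
        p = self.params
        oxy = np.asarray(w.oxygen, float)
        x = site.position
        d = float(np.linalg.norm(x - oxy))
        if d >= p.cutoff_distance or d < 1e-6:
            return 0.0
        radial = self._radial(d, site.ideal_water_distance)
        if radial >= 0.0:
            return 0.0  # repulsive regime: handled by the clash filter
        k = p.angular_weight
        best = 0.0
        if site.can_accept:
            # water donates: O-H ... X
            acc_vecs = site.acceptor_vectors or []
            for h in w.hydrogens:
                cos_don = float(np.dot(_unit(h - oxy), _unit(x - h)))
                if cos_don <= 0.0:
                    continue
                cos_acc = max((float(np.dot(v, _unit(h - x)))
                               for v in acc_vecs), default=1.0)
                if cos_acc <= 0.0:
                    continue
                best = min(best, abs(p.well_depth) * radial
                           * cos_don ** k * cos_acc ** k)
        if site.can_donate:
            # site donates: X-H ... O(water); the water accepts along its
            # lone pairs (O-H directions excluded)
            lone = self._water_lone_pairs(w)
            for hs in site.attached_hydrogens:
                cos_don = float(np.dot(_unit(hs - x), _unit(oxy - hs)))
                if cos_don <= 0.0:
                    continue
                cos_acc = max((float(np.dot(v, _unit(hs - oxy)))
                               for v in lone), default=1.0)
                if cos_acc <= 0.0:
                    continue
                best = min(best, abs(p.well_depth) * radial
                           * cos_don ** k * cos_acc ** k)
        return best

    def _radial(self, d: float, d0: float) -> float:
        # (n/(m-n)) q^m - (m/(m-n)) q^n: minimum -1 at d = d0;
        # (12, 10) gives the familiar 5 q^12 - 6 q^10
        m, n = self.params.distance_exponents
        q = d0 / d
        return (n / (m - n)) * q ** m - (m / (m - n)) * q ** n

    @staticmethod
    def _water_lone_pairs(w) -> list[np.ndarray]:
        import math
        oxy = np.asarray(w.oxygen, float)
        u1 = _unit(w.hydrogens[0] - oxy)
        u2 = _unit(w.hydrogens[1] - oxy)
        nrm = _unit(np.cross(u1, u2))
        bis = -_unit(u1 + u2)
        half = math.radians(109.47122 / 2.0)
        return [_unit(math.cos(half) * bis + math.sin(half) * nrm),
                _unit(math.cos(half) * bis - math.sin(half) * nrm)]

    # -- gate -------------------------------------------------------------
    def accept_water(self, w) -> bool:
        """True iff the water genuinely bridges under the threshold."""
        e_min = self.params.accept_threshold
        if self.params.gate == "sum":
            return w.energy_i + w.energy_j <= 2 * e_min
        return w.energy_i <= e_min and w.energy_j <= e_min


def hbond_energy(w, site: PolarSite,
                 params: HBondParams | None = None) -> float:
    return HBondModel(params).hbond_energy(w, site)


def accept_water(w, params: HBondParams | None = None) -> bool:
    return HBondModel(params).accept_water(w)
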