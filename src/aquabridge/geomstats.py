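"""Water-geometry statistics: contact distances, bridging geometry, fits.

Reproduces the survey arithmetic the placement algorithm is built on:
normal fits to water-contact and bridged-atom distance distributions,
log-normal fits to prediction-deviation distributions, and the
mu +/- k*sigma eligibility windows derived from them (e.g. the
4.61 +/- 0.48 A bridged-atom fit gives 4.13-5.09 A at 1 sigma and
3.65-5.57 A at 2 sigma).

Fits are maximum likelihood on the raw samples rather than curve fits
to histograms; at the survey's sample sizes (10^4-10^5) the difference
is immaterial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .chemistry import GeometryParams, classify_polar_sites
from .structure import ReferenceSphere

__all__ = [
    "DistributionFit",
    "water_contact_distances",
    "bridging_geometry",
    "fit_normal",
    "fit_lognormal",
    "sigma_window",
    "gaussian_mass",
]


@dataclass
class DistributionFit:
    family: str           # normal | lognormal
    mu: float             # mean (normal) or log-mean (lognormal)
    sigma: float
    n: int
    median: float = math.nan
    mode: float = math.nan


def fit_normal(samples) -> DistributionFit:
    """MLE normal fit; errors on degenerate input (n < 2 or sigma = 0)."""
    x = np.asarray(samples, float)
    if x.size < 2:
        raise ValueError("need at least two samples")
    mu, sigma = float(np.mean(x)), float(np.std(x))
    if sigma <= 0.0:
        raise ValueError("degenerate sample set (sigma = 0)")
    return DistributionFit(family="normal", mu=mu, sigma=sigma,
                           n=int(x.size), median=mu, mode=mu)


def fit_lognormal(samples) -> DistributionFit:
    """MLE log-normal fit with closed-form median exp(mu) and mode
    exp(mu - sigma^2)."""
    x = np.asarray(samples, float)
    if x.size < 2:
        raise ValueError("need at least two samples")
    if np.any(x <= 0.0):
        raise ValueError("log-normal fit requires positive samples")
    logs = np.log(x)
    mu, sigma = float(np.mean(logs)), float(np.std(logs))
    if sigma <= 0.0:
        raise ValueError("degenerate sample set (sigma = 0)")
    return DistributionFit(family="lognormal", mu=mu, sigma=sigma,
                           n=int(x.size), median=math.exp(mu),
                           mode=math.exp(mu - sigma * sigma))


def sigma_window(fit: DistributionFit, k: float) -> tuple[float, float]:
    """(mu - k*sigma, mu + k*sigma) of a normal fit."""
    if fit.family != "normal":
        raise ValueError("sigma windows are defined for normal fits")
    return fit.mu - k * fit.sigma, fit.mu + k * fit.sigma


def gaussian_mass(k: float) -> float:
    """Probability mass of a Gaussian within mu +/- k*sigma."""
    return float(stats.norm.cdf(k) - stats.norm.cdf(-k))


# ---------------------------------------------------------------------------
# sphere-set analyses

def _polar_protein_positions(sphere: ReferenceSphere, element_filter="all"):
    sites = classify_polar_sites(sphere.atoms)
    out = []
    for st in sites:
        if st.atom.is_water or st.atom.is_ligand:
            continue
        if element_filter != "all" and st.atom.element != element_filter:
            continue
        out.append(st.position)
    return np.asarray(out).reshape(-1, 3)


def _nearest_heavy_is_polar(sphere: ReferenceSphere, center, search: float
                            ) -> bool:
    """Is the central water's nearest heavy non-water atom within the
    H-bond search radius a polar protein atom?"""
    best_d, best_atom = np.inf, None
    for a in sphere.atoms.atoms:
        if a.is_water or a.element == "H":
            continue
        d = np.linalg.norm(a.position - center)
        if 1e-6 < d < best_d:
            best_d, best_atom = d, a
    if best_atom is None or best_d > search:
        return False
    return best_atom.element in ("O", "N") and not best_atom.is_ligand


def water_contact_distances(spheres: list[ReferenceSphere],
                            element_filter: str = "all",
                            params: GeometryParams | None = None
                            ) -> list[float]:
    """Central-water contact distances to coordinating polar atoms.

    Only central waters whose nearest H-bonded partner is a polar
    protein atom contribute; the H-bond search radius (3.5 A)
    operationalises "closest H-bonded binding partner".
    """
    params = params or GeometryParams()
    out: list[float] = []
    for sp in spheres:
        c = sp.central_water
        if not _nearest_heavy_is_polar(sp, c, params.hbond_search):
            continue
        polar = _polar_protein_positions(sp, element_filter)
        if polar.size == 0:
            continue
        d = np.linalg.norm(polar - c, axis=1)
        out.extend(float(x) for x in d[d <= params.hbond_search])
    return out


def bridging_geometry(spheres: list[ReferenceSphere],
                      params: GeometryParams | None = None,
                      coordination_cutoff: float | None = None
                      ) -> tuple[list[float], list[float]]:
    """Bridged-atom distances and water-vertex angles.

    For every central water coordinated by >= 2 polar protein atoms,
    each unordered coordinating pair contributes one Xi-Xj distance and
    one Xi-water-Xj angle (so the two sample sets are equally sized).
    """
    params = params or GeometryParams()
    cutoff = coordination_cutoff \
        if coordination_cutoff is not None else params.hbond_search
    distances: list[float] = []
    angles: list[float] = []
    for sp in spheres:
        c = sp.central_water
        polar = _polar_protein_positions(sp, "all")
        if polar.size == 0:
            continue
        d = np.linalg.norm(polar - c, axis=1)
        coord = polar[d <= cutoff]
        for i in range(len(coord)):
            for j in range(i + 1, len(coord)):
                xi, xj = coord[i], coord[j]
                distances.append(float(np.linalg.norm(xi - xj)))
                u = (xi - c) / np.linalg.norm(xi - c)
                v = (xj - c) / np.linalg.norm(xj - c)
                angles.append(float(math.degrees(
                    math.acos(max(-1.0, min(1.0, float(np.dot(u, v))))))))
    return distances, angles
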