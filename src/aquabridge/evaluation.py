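"""Validation metrics: water recovery, mesh matching, chi1 and RMSD.

The mesh protocol mirrors crystallographic practice: predicted and
reference waters inside a 6 A border around the central water are paired
uniquely (no double picking), greedily by ascending distance; TP and FP
percentages are taken over the predicted set, FN over the reference set,
so TP% + FP% = 100 whenever anything was predicted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .chemistry import GeometryParams, classify_polar_sites
from .structure import Structure, ReferenceSphere

__all__ = [
    "MatchResult",
    "coordination_count",
    "central_water_deviation",
    "recovery_rate",
    "match_waters",
    "chi1_recovery",
    "sidechain_rmsd",
    "evaluate_sphere",
]

NO_PREDICTION = None   # sentinel for spheres with an empty prediction

CHI1_ATOMS = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "CYS": "SG", "GLN": "CG",
    "GLU": "CG", "HIS": "CG", "ILE": "CG1", "LEU": "CG", "LYS": "CG",
    "MET": "CG", "PHE": "CG", "PRO": "CG", "SER": "OG", "THR": "OG1",
    "TRP": "CG", "TYR": "CG", "VAL": "CG1",
}

# chemically equivalent atom-name swaps for symmetric side chains
SYMMETRIC_SWAPS = {
    "PHE": [("CD1", "CD2"), ("CE1", "CE2")],
    "TYR": [("CD1", "CD2"), ("CE1", "CE2")],
    "ASP": [("OD1", "OD2")],
    "GLU": [("OE1", "OE2")],
    "ARG": [("NH1", "NH2")],
}

MAIN_CHAIN = {"N", "CA", "C", "O", "CB", "OXT"}


@dataclass
class MatchResult:
    pairs: list = field(default_factory=list)  # (pred idx, ref idx, dev A)
    tp_percent: float = 0.0
    fp_percent: float = 0.0
    fn_percent: float = 0.0
    cutoff: float = 1.4
    mean_deviation: float = math.nan
    n_predicted: int = 0
    n_reference: int = 0


def coordination_count(water, s: Structure, cutoff: float = 2.99,
                       sites=None) -> int:
    """Polar protein atoms within *cutoff* (closed ball) of a water."""
    water = np.asarray(water, float)
    if sites is None:
        sites = classify_polar_sites(s)
    protein = [st for st in sites
               if not st.atom.is_water and not st.atom.is_ligand]
    return sum(np.linalg.norm(st.position - water) <= cutoff
               for st in protein)


def central_water_deviation(predicted, central) -> float | None:
    """Shortest distance from any predicted water to the central water;
    ``None`` when nothing was predicted (counts against recovery but is
    excluded from the deviation distribution)."""
    if len(predicted) == 0:
        return NO_PREDICTION
    central = np.asarray(central, float)
    pts = np.asarray(predicted, float)
    return float(np.linalg.norm(pts - central, axis=1).min())


def recovery_rate(deviations, cutoff: float) -> float:
    """Percentage of spheres whose central water was predicted within
    *cutoff*; entries of ``None`` (no prediction) count as failures."""
    if len(deviations) == 0:
        return math.nan
    hits = sum(1 for d in deviations
               if d is not None and d <= cutoff)
    return 100.0 * hits / len(deviations)


def recovery_curve(deviations, cutoffs) -> list[float]:
    return [recovery_rate(deviations, c) for c in cutoffs]


def _border_filter(points, center, radius):
    points = np.asarray(points, float).reshape(-1, 3)
    if center is None:
        return points
    center = np.asarray(center, float)
    keep = np.linalg.norm(points - center, axis=1) <= radius
    return points[keep]


def match_waters(predicted, reference, cutoff: float = 1.4,
                 border_center=None, border_radius: float = 6.0,
                 method: str = "greedy") -> MatchResult:
    """Unique pairing of predicted vs reference waters.

    Candidate pairs within *cutoff* are matched greedily by ascending
    distance (ties: lower predicted index), each point used at most
    once.  ``method="hungarian"`` instead maximises the number of
    matches via optimal bipartite assignment.
    """
    pred = _border_filter(predicted, border_center, border_radius)
    ref = _border_filter(reference, border_center, border_radius)
    n_p, n_r = len(pred), len(ref)
    pairs = []
    if n_p and n_r:
        dmat = np.linalg.norm(
            pred[:, None, :] - ref[None, :, :], axis=2)
        if method == "hungarian":
            from scipy.optimize import linear_sum_assignment
            # large constant disfavours out-of-cutoff assignments
            cost = np.where(dmat <= cutoff, dmat, 1e6)
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if dmat[i, j] <= cutoff:
                    pairs.append((int(i), int(j), float(dmat[i, j])))
        else:
            cands = [(float(dmat[i, j]), i, j)
                     for i in range(n_p) for j in range(n_r)
                     if dmat[i, j] <= cutoff]
            cands.sort(key=lambda t: (t[0], t[1], t[2]))
            used_p, used_r = set(), set()
            for d, i, j in cands:
                if i in used_p or j in used_r:
                    continue
                used_p.add(i)
                used_r.add(j)
                pairs.append((i, j, d))
    tp = len(pairs)
    res = MatchResult(pairs=pairs, cutoff=cutoff,
                      n_predicted=n_p, n_reference=n_r)
    if n_p:
        res.tp_percent = 100.0 * tp / n_p
        res.fp_percent = 100.0 * (n_p - tp) / n_p
    if n_r:
        res.fn_percent = 100.0 * (n_r - tp) / n_r
    if pairs:
        res.mean_deviation = float(np.mean([p[2] for p in pairs]))
    return res


# ---------------------------------------------------------------------------
# side-chain metrics

def _chi1(res_atoms: dict, res_name: str) -> float | None:
    names = ("N", "CA", "CB", CHI1_ATOMS.get(res_name, ""))
    if not names[3] or any(n not in res_atoms for n in names):
        return None
    a, b, c, d = (res_atoms[n] for n in names)
    return _dihedral(a, b, c, d)


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return math.degrees(math.atan2(y, x))


def _circular_diff(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def _residue_maps(s: Structure) -> dict:
    out = {}
    for key, atoms in s.residues().items():
        if atoms[0].is_water or atoms[0].is_ligand:
            continue
        out[(key[0], key[1])] = (key[2],
                                 {a.name: a.position for a in atoms})
    return out


def chi1_recovery(model: Structure, reference: Structure,
                  tolerance: float = 20.0) -> float:
    """Percentage of chi1-bearing rebuilt residues whose chi1 deviates by
    strictly less than *tolerance* degrees (circular difference).

    Residues left truncated in the model (no atoms past CB) and Ala/Gly
    are excluded from the denominator.
    """
    mod = _residue_maps(model)
    ref = _residue_maps(reference)
    n = hits = 0
    for rk, (res_name, atoms) in mod.items():
        if rk not in ref:
            warnings.warn(f"residue {rk} unpaired; skipped")
            continue
        chi_m = _chi1(atoms, res_name)
        chi_r = _chi1(ref[rk][1], ref[rk][0])
        if chi_m is None or chi_r is None:
            continue
        n += 1
        if _circular_diff(chi_m, chi_r) < tolerance:
            hits += 1
    return 100.0 * hits / n if n else math.nan


def _sidechain_devs(res_name: str, mod_atoms: dict, ref_atoms: dict
                    ) -> list[float]:
    """Per-atom deviations past CB, minimised over symmetric swaps."""
    names = [n for n in mod_atoms
             if n not in MAIN_CHAIN and n in ref_atoms]
    if not names:
        return []
    base = [np.linalg.norm(mod_atoms[n] - ref_atoms[n]) for n in names]
    swaps = SYMMETRIC_SWAPS.get(res_name)
    if not swaps:
        return base
    swapped_ref = dict(ref_atoms)
    for a, b in swaps:
        if a in swapped_ref and b in swapped_ref:
            swapped_ref[a], swapped_ref[b] = swapped_ref[b], swapped_ref[a]
    alt = [np.linalg.norm(mod_atoms[n] - swapped_ref[n]) for n in names]
    if math.sqrt(np.mean(np.square(alt))) < \
            math.sqrt(np.mean(np.square(base))):
        return alt
    return base


def sidechain_rmsd(model: Structure, reference: Structure,
                   mode: str = "overall") -> float:
    """RMSD over side-chain atoms past Cbeta (main chain and CB omitted).

    ``overall`` pools all atomic deviations; symmetric side chains
    (Phe/Tyr rings, Asp/Glu carboxylates, Arg NH) are evaluated under
    both atom-name swaps and the lower RMSD is used per residue.
    """
    mod = _residue_maps(model)
    ref = _residue_maps(reference)
    devs = []
    for rk, (res_name, atoms) in mod.items():
        if rk not in ref:
            continue
        devs.extend(_sidechain_devs(res_name, atoms, ref[rk][1]))
    if not devs:
        return math.nan
    return float(math.sqrt(np.mean(np.square(devs))))


# ---------------------------------------------------------------------------
# per-sphere bundling

@dataclass
class SphereReport:
    central_deviation: float | None
    mesh: MatchResult
    chi1_percent: float
    rmsd: float
    coordination: int


def evaluate_sphere(sp: ReferenceSphere, rebuilt: Structure,
                    predicted_waters=None, cutoff: float = 1.4,
                    params: GeometryParams | None = None) -> SphereReport:
    """Bundle all per-sphere metrics into one record.

    Reference waters are taken from the sphere's structure; predicted
    waters either from *predicted_waters* or from HOH records of the
    rebuilt model.  Mesh matching applies the 6 A border around the
    central water.
    """
    params = params or GeometryParams()
    if predicted_waters is None:
        predicted_waters = [a.position for a in rebuilt.atoms
                            if a.is_water and a.element == "O"]
    predicted_waters = list(predicted_waters)
    reference_waters = [a.position for a in sp.atoms.atoms
                        if a.is_water and a.element == "O"]
    dev = central_water_deviation(predicted_waters, sp.central_water)
    mesh = match_waters(predicted_waters, reference_waters, cutoff=cutoff,
                        border_center=sp.central_water,
                        border_radius=sp.eval_radius)
    chi1 = chi1_recovery(rebuilt, sp.atoms)
    rmsd = sidechain_rmsd(rebuilt, sp.atoms)
    coord = coordination_count(sp.central_water, sp.atoms,
                               params.coordination_cutoff)
    return SphereReport(central_deviation=dev, mesh=mesh,
                        chi1_percent=chi1, rmsd=rmsd, coordination=coord)


def aggregate_reports(reports: list[SphereReport], cutoff: float = 1.4
                      ) -> dict:
    """Table-style aggregate row over a sphere set."""
    devs = [r.central_deviation for r in reports]
    known = [d for d in devs if d is not None]
    tp = [r.mesh.tp_percent for r in reports if r.mesh.n_predicted]
    fn = [r.mesh.fn_percent for r in reports if r.mesh.n_reference]
    pair_devs = [p[2] for r in reports for p in r.mesh.pairs]
    rmsds = [r.rmsd for r in reports if not math.isnan(r.rmsd)]
    chi1s = [r.chi1_percent for r in reports
             if not math.isnan(r.chi1_percent)]
    return {
        "n_spheres": len(reports),
        "recovery_percent": recovery_rate(devs, cutoff),
        "median_deviation": float(np.median(known)) if known else math.nan,
        "median_rmsd": float(np.median(rmsds)) if rmsds else math.nan,
        "chi1_percent": float(np.mean(chi1s)) if chi1s else math.nan,
        "tp_percent": float(np.mean(tp)) if tp else math.nan,
        "fp_percent": float(100 - np.mean(tp)) if tp else math.nan,
        "fn_percent": float(np.mean(fn)) if fn else math.nan,
        "mean_pair_deviation": float(np.mean(pair_devs))
        if pair_devs else math.nan,
        "cutoff": cutoff,
    }
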