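"""End-to-end sphere rebuilding: truncation, packing, water prediction.

Mirrors the validation protocol: strip waters, truncate residues within
the design radius to alanine/glycine, rebuild side chains with the
packing engine (optionally with solvated rotamer pairs or posterior
water building) and score the result against the original sphere.
"""

from __future__ import annotations

import numpy as np

from .config import RunConfig
from .energy import HBondModel
from .evaluation import SphereReport, evaluate_sphere
from .packing import (PackingProblem, build_solvated_rotamers,
                      dee_goldstein, emit_model, enumerate_rotamers,
                      mc_simulated_annealing)
from .structure import ReferenceSphere, Structure, prepare_for_rebuild
from .waterbuild import solvate_structure

__all__ = ["rebuild_sphere", "posterior_waters"]


def posterior_waters(model: Structure, cfg: RunConfig) -> Structure:
    """Append posterior-mode waters to a fixed structure."""
    waters = solvate_structure(model, cfg.geometry, HBondModel(cfg.energy),
                               strict=cfg.strict_window)
    out = model.copy()
    res_id = max((a.res_id for a in out.atoms), default=0) + 1
    for w in waters:
        out.atoms.extend(w.as_atoms(res_id))
        res_id += 1
    return out


def rebuild_sphere(sp: ReferenceSphere, cfg: RunConfig | None = None
                   ) -> tuple[Structure, SphereReport]:
    """Rebuild a truncated sphere and score it against the original.

    Positions without a complete N/CA/C backbone frame (bare fragments)
    are left truncated; they still participate as fixed context.
    """
    cfg = cfg or RunConfig()
    prepared = prepare_for_rebuild(sp)
    model = _pack(prepared, cfg)
    if cfg.build_waters and cfg.posterior:
        model = posterior_waters(model, cfg)
    report = evaluate_sphere(sp, model, params=cfg.geometry)
    return model, report


def _pack(prepared: Structure, cfg: RunConfig) -> Structure:
    sequence = prepared.rebuild_sequence or {}
    energy_model = HBondModel(cfg.energy)
    positions, rotamer_sets = [], {}
    for pos, res_type in sequence.items():
        names = {a.name for a in prepared.atoms
                 if (a.chain, a.res_id) == pos}
        if not {"N", "CA", "C"} <= names:
            continue
        try:
            rots = enumerate_rotamers(prepared, pos, res_type,
                                      expand_chi1=cfg.expand_chi1)
        except ValueError:
            continue
        positions.append(pos)
        rotamer_sets[pos] = rots
    if not positions:
        return prepared.copy()
    problem = PackingProblem(context=prepared, positions=positions,
                             rotamer_sets=rotamer_sets,
                             params=cfg.geometry,
                             energy_model=energy_model)
    if cfg.build_waters and not cfg.posterior:
        build_solvated_rotamers(problem)
    problem, _ = dee_goldstein(problem)
    assignment, _ = mc_simulated_annealing(problem, seed=cfg.seed)
    return emit_model(problem, assignment)
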