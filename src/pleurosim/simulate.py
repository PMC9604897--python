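"""ODE integration of a model under generated rate laws, plus scans.

The state is the vector of species amounts; its dynamics are

    d[X]/dt = sum_r s_rX * v_r(state)

where ``s_rX`` is the net stoichiometry of X in reaction r and ``v_r``
the reaction's assigned rate law.  Constant (boundary) species such as
environmental stimuli are held fixed.  Integration uses a stiff-capable
implicit solver (LSODA) with tight tolerances; amounts are evaluated with
a non-negativity clip inside the right-hand side, so mass-action systems
started from non-negative amounts stay non-negative up to solver noise.

Initial amounts follow the role scheme of the study conditions: genes
0.5, mRNA 1.0, proteins and complexes 2.0, phenotypes 2.5, simple
molecules and receptors 0.5 — overridable per species.

:func:`scan_initial` varies one species' initial amount over a grid and
records a terminal readout, reproducing dose-response behavior such as
"more hydrophobin, more pinheads" or "more Pofst, fewer pinheads".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp

from .core import Model, Species, SpeciesRole, require_valid
from .kinetics import RateLaw

#: default initial amount per species role (arbitrary concentration units)
ROLE_DEFAULTS: dict[SpeciesRole, float] = {
    SpeciesRole.gene: 0.5,
    SpeciesRole.mrna: 1.0,
    SpeciesRole.protein: 2.0,
    SpeciesRole.complex: 2.0,
    SpeciesRole.phenotype: 2.5,
    SpeciesRole.simple_molecule: 0.5,
    SpeciesRole.receptor: 0.5,
}


@dataclass(frozen=True)
class SimulationSettings:
    t_end: float = 10.0
    n_points: int = 200
    rtol: float = 1e-8
    atol: float = 1e-10
    #: with the flag on, values below -10*atol abort with an error and
    #: smaller negative excursions are clamped to zero.
    clamp_negative: bool = True

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass(frozen=True)
class Trajectory:
    time: np.ndarray
    amounts: dict[str, np.ndarray]

    def terminal(self, species: str) -> float:
        return float(self.amounts[species][-1])


@dataclass(frozen=True)
class DoseResponse:
    varied: str
    grid: np.ndarray
    readout: str
    terminal: np.ndarray


class SolverFailure(RuntimeError):
    pass


def default_initial_conditions(model: Model) -> dict[str, float]:
    """Initial amount per species: explicit value if set, else role default."""
    require_valid(model)
    out = {}
    for s in model.species:
        if s.initial_amount is not None:
            out[s.id] = float(s.initial_amount)
        else:
            out[s.id] = ROLE_DEFAULTS[s.role]
    return out


def _compile_rhs(model: Model, laws: Mapping[str, RateLaw]):
    """Lambdify the rate vector and build the stoichiometry matrix."""
    sids = [s.id for s in model.species]
    index = {sid: i for i, sid in enumerate(sids)}
    constant = np.array([s.constant for s in model.species])

    n_r = len(model.reactions)
    stoich = np.zeros((len(sids), n_r))
    exprs = []
    for j, r in enumerate(model.reactions):
        if r.id not in laws:
            raise ValueError(f"reaction {r.id} has no rate law")
        law = laws[r.id]
        expr = law.expression.xreplace(
            {sp.Symbol(k): sp.Float(v) for k, v in law.parameters.items()}
        )
        exprs.append(expr)
        for sid, n in r.reactants:
            stoich[index[sid], j] -= n
        for sid, n in r.products:
            stoich[index[sid], j] += n
    stoich[constant, :] = 0.0  # boundary species are held fixed

    symbols = [sp.Symbol(sid) for sid in sids]
    rate_fn = sp.lambdify(symbols, exprs, modules="numpy")

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        v = np.asarray(rate_fn(*np.maximum(y, 0.0)), dtype=float)
        return stoich @ v

    return sids, rhs


def integrate(
    model: Model,
    laws: Mapping[str, RateLaw],
    ics: Optional[Mapping[str, float]] = None,
    settings: SimulationSettings = SimulationSettings(),
) -> Trajectory:
    """Integrate the model ODE system from 0 to ``t_end``.

    Deterministic for fixed inputs.  Raises :class:`SolverFailure` when
    the solver cannot complete or a negative excursion exceeds tolerance.
    """
    require_valid(model)
    full_ics = default_initial_conditions(model)
    if ics:
        unknown = set(ics) - set(full_ics)
        if unknown:
            raise KeyError(f"unknown species in initial conditions: {sorted(unknown)}")
        full_ics.update({k: float(v) for k, v in ics.items()})
    if any(v < 0 for v in full_ics.values()):
        raise ValueError("initial amounts must be non-negative")

    sids, rhs = _compile_rhs(model, laws)
    y0 = np.array([full_ics[sid] for sid in sids])
    t_eval = np.linspace(0.0, settings.t_end, settings.n_points)

    sol = solve_ivp(
        rhs,
        (0.0, settings.t_end),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=settings.rtol,
        atol=settings.atol,
    )
    if not sol.success:
        raise SolverFailure(f"integration failed at t={sol.t[-1]:.4g}: {sol.message}")

    y = sol.y
    if settings.clamp_negative:
        floor = -10.0 * settings.atol
        worst = y.min()
        if worst < floor:
            i, j = np.unravel_index(np.argmin(y), y.shape)
            raise SolverFailure(
                f"negative excursion {worst:.3g} for {sids[i]} at t={sol.t[j]:.4g}"
            )
        y = np.maximum(y, 0.0)

    return Trajectory(time=sol.t, amounts={sid: y[i] for i, sid in enumerate(sids)})


def scan_initial(
    model: Model,
    laws: Mapping[str, RateLaw],
    varied: str,
    grid: Sequence[float],
    readout: str,
    settings: SimulationSettings = SimulationSettings(),
) -> DoseResponse:
    """Terminal readout amount as a function of one species' initial amount.

    One integration per grid value; everything else sits at its default.
    """
    ids = {s.id for s in model.species}
    for sid in (varied, readout):
        if sid not in ids:
            raise KeyError(f"unknown species {sid!r}")
    grid_arr = np.asarray(list(grid), dtype=float)
    if grid_arr.size == 0:
        raise ValueError("grid must be non-empty")
    if (grid_arr < 0).any():
        raise ValueError("grid values must be non-negative")

    terminal = np.empty_like(grid_arr)
    for i, v in enumerate(grid_arr):
        traj = integrate(model, laws, {varied: float(v)}, settings)
        terminal[i] = traj.terminal(readout)
    return DoseResponse(varied=varied, grid=grid_arr, readout=readout, terminal=terminal)


def trajectory_frame(traj: Trajectory):
    """Tidy DataFrame (time, species, amount) for CSV export."""
    import pandas as pd

    rows = []
    for sid, series in traj.amounts.items():
        rows.append(pd.DataFrame({"time": traj.time, "species": sid, "amount": series}))
    return pd.concat(rows, ignore_index=True)


def dose_response_frame(dr: DoseResponse):
    import pandas as pd

    return pd.DataFrame(
        {
            "varied": dr.varied,
            "initial_amount": dr.grid,
            "readout": dr.readout,
            "terminal_amount": dr.terminal,
        }
    )
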