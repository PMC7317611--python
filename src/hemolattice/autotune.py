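"""Automatic selection of spatial/temporal resolution from stability limits.

The lattice solver is stable while the nondimensional viscosity stays above
``nu_min`` and the nondimensional speed below ``u_lim``.  Writing both for
physical quantities gives a (dx, dt) stability wedge

    dt > (nu_min / nu) dx^2        (viscosity floor)
    dt < (u_lim / u_max) dx        (velocity ceiling)

whose upper intersection is the coarsest stable pair.  The shipped
thresholds ``u_lim = 0.15`` and ``nu_min = 1.0e-3`` sit strictly inside the
published MRT limits (0.19 and 2.54e-3).  The selected dx is additionally
clamped so the minimum vessel diameter keeps at least 15 nodes, and a 20%
performance coarsening is applied to the initial (reduced-order-model
based) estimate; if the running simulation then exceeds the velocity
ceiling, the plan is recomputed from the observed velocity and the
simulation restarts from t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "StabilityError",
    "ResolutionPlan",
    "stability_bounds",
    "select_resolution",
    "monitor_and_refine",
    "U_LIM_DEFAULT",
    "NU_MIN_DEFAULT",
]

U_LIM_DEFAULT = 0.15
NU_MIN_DEFAULT = 1.0e-3
MIN_NODES_PER_DIAMETER = 15


class StabilityError(RuntimeError):
    """Raised when no stable resolution fits the configured budget."""


@dataclass(frozen=True)
class ResolutionPlan:
    """Selected unit scales and the stability margins backing them."""

    dx: float                 # m
    dt: float                 # s
    dm: float                 # kg
    nu_lbm: float
    u_lbm_pred: float         # predicted peak lattice velocity
    u_max_phys: float         # m/s estimate the plan is based on
    u_lim: float = U_LIM_DEFAULT
    nu_min: float = NU_MIN_DEFAULT
    d_min: float | None = None
    nodes_per_dmin: float | None = None
    clamped_by_diameter: bool = False
    coarsening: float = 1.0   # heuristic factor applied to dx*
    history: tuple = field(default_factory=tuple)

    def audit(self) -> dict:
        """JSON-ready report of the plan and its refinement history."""
        return {
            "dx_m": self.dx,
            "dt_s": self.dt,
            "dm_kg": self.dm,
            "nu_lbm": self.nu_lbm,
            "u_lbm_pred": self.u_lbm_pred,
            "u_max_phys": self.u_max_phys,
            "u_lim": self.u_lim,
            "nu_min": self.nu_min,
            "d_min_m": self.d_min,
            "nodes_per_dmin": self.nodes_per_dmin,
            "clamped_by_diameter": self.clamped_by_diameter,
            "coarsening": self.coarsening,
            "history": [dict(h) for h in self.history],
        }


def stability_bounds(nu: float, u_max_phys: float, dx: float,
                     u_lim: float = U_LIM_DEFAULT,
                     nu_min: float = NU_MIN_DEFAULT):
    """Admissible (dt_lower, dt_upper) at spacing ``dx``.

    ``dt_lower = (nu_min/nu) dx^2`` and ``dt_upper = (u_lim/u_max) dx``;
    the interval is empty above the intersection spacing.
    """
    dt_lower = (nu_min / nu) * dx * dx
    dt_upper = (u_lim / u_max_phys) * dx
    return dt_lower, dt_upper


def select_resolution(
    nu: float,
    rho: float,
    u_max_phys: float,
    d_min: float | None = None,
    u_lim: float = U_LIM_DEFAULT,
    nu_min: float = NU_MIN_DEFAULT,
    coarsening: float = 1.2,
    dt_safety: float = 1.01,
    min_nodes: int = MIN_NODES_PER_DIAMETER,
    node_budget: float | None = None,
    bbox_volume: float | None = None,
) -> ResolutionPlan:
    """Coarsest stable (dx, dt, dm) for the estimated peak velocity.

    ``dx* = u_lim nu / (nu_min u_max)`` (the wedge intersection) is scaled
    by the performance ``coarsening`` (1.2 for the initial estimate: a
    deliberately coarser grid that may trigger 1-2 refinements), then
    clamped so ``d_min/dx >= min_nodes``.  ``dt`` sits just above the
    viscosity floor (``dt_safety``) and ``dm = rho dx^3``.
    """
    if min(nu, rho, u_max_phys) <= 0:
        raise ValueError("nu, rho and u_max must be positive")
    dx_star = u_lim * nu / (nu_min * u_max_phys)
    dx = coarsening * dx_star
    clamped = False
    if d_min is not None and dx > d_min / min_nodes:
        dx = d_min / min_nodes
        clamped = True
    if node_budget is not None and bbox_volume is not None:
        needed = bbox_volume / dx**3
        if needed > node_budget:
            raise StabilityError(
                f"grid would need {needed:.3g} nodes, budget {node_budget:.3g}"
            )
    dt = dt_safety * (nu_min / nu) * dx * dx
    nu_lbm = nu * dt / dx**2
    return ResolutionPlan(
        dx=dx,
        dt=dt,
        dm=rho * dx**3,
        nu_lbm=nu_lbm,
        u_lbm_pred=u_max_phys * dt / dx,
        u_max_phys=u_max_phys,
        u_lim=u_lim,
        nu_min=nu_min,
        d_min=d_min,
        nodes_per_dmin=(d_min / dx) if d_min is not None else None,
        clamped_by_diameter=clamped,
        coarsening=coarsening,
    )


def monitor_and_refine(
    plan: ResolutionPlan,
    observed_u_lbm: float,
    rho: float,
    nu: float,
    safety: float = 1.05,
    max_refinements: int = 5,
    flow_ratio: float = 1.0,
    min_shrink: float = 0.85,
) -> ResolutionPlan | None:
    """Decide whether the running simulation must restart on a finer plan.

    Returns ``None`` to continue, or the refined plan (restart from t = 0).
    The observed peak velocity is converted back to physical units,
    inflated by ``safety`` to avoid oscillating refinements, and fed back
    through :func:`select_resolution` without the initial-estimate
    coarsening.  ``flow_ratio`` projects an observation made partway up the
    inflow waveform to the cycle peak (velocities scale roughly with the
    instantaneous flow rate), so one restart normally suffices instead of
    one per crossing of the ceiling during the systolic rise.
    """
    if observed_u_lbm <= plan.u_lim:
        return None
    if len(plan.history) >= max_refinements:
        raise StabilityError(
            f"velocity {observed_u_lbm:.3g} still exceeds u_lim after "
            f"{len(plan.history)} refinements"
        )
    flow_ratio = min(max(flow_ratio, 1.0), 2.0)
    u_phys = observed_u_lbm * (plan.dx / plan.dt) * safety * flow_ratio
    u_phys = max(u_phys, plan.u_max_phys)
    # enforce a minimum stride: marginal ceiling crossings would otherwise
    # shrink dx by only a few percent per restart while the resolved peak
    # velocity creeps up comparably, cascading restarts
    dx_cap = min_shrink * plan.dx
    u_for_cap = plan.u_lim * nu / (plan.nu_min * dx_cap)
    u_phys = max(u_phys, u_for_cap)
    new = select_resolution(
        nu=nu,
        rho=rho,
        u_max_phys=u_phys,
        d_min=plan.d_min,
        u_lim=plan.u_lim,
        nu_min=plan.nu_min,
        coarsening=1.0,
    )
    event = {
        "old_dx": plan.dx,
        "old_dt": plan.dt,
        "new_dx": new.dx,
        "new_dt": new.dt,
        "observed_u_lbm": observed_u_lbm,
    }
    return replace(new, history=plan.history + (event,))
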