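"""Linear compartmental simulation with discrete delay elements.

The engine implements the three building blocks used by whole-body
vitamin A kinetic models in the SAAM tradition:

* **compartments** — well-mixed pools exchanging material through
  fractional transfer coefficients ``L(I,J)`` (fraction of pool J moved
  to component I per day),
* **delay elements** — pure time shifts: the flow leaving a delay at
  time *t* equals the flow that entered it ``DT`` days earlier,
* **sinks** — terminal accumulators for irreversible loss.

Transfers with ``to_id=0`` follow the SAAM convention ``L(0,J)`` of loss
to the environment; the environment is tracked as a cumulative state so
that mass balance closes exactly.

The integrator is a fixed-step classical Runge-Kutta scheme with a
cubic-Hermite history buffer, i.e. the method of steps for the delay
terms: delayed flows are evaluated by interpolating the stored state at
``t - DT``.  The internal step must not exceed the shortest delay.

Rates are per day, masses in μmol (tracee) or fraction of dose (tracer),
times in days.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COMPARTMENT",
    "DELAY",
    "SINK",
    "OUTSIDE_ID",
    "ComponentSpec",
    "Transfer",
    "ExternalInput",
    "CompartmentalSystem",
    "SteadyState",
    "Trajectory",
    "EngineError",
    "ValidationError",
    "SteadyStateError",
    "SimulationError",
    "build_system",
    "steady_state_solve",
    "simulate",
    "delay_output",
]

COMPARTMENT = "compartment"
DELAY = "delay"
SINK = "sink"

#: conventional id for loss to the environment (``L(0,J)``)
OUTSIDE_ID = 0


class EngineError(Exception):
    """Base class for engine failures."""


class ValidationError(EngineError):
    """A system definition is inconsistent."""


class SteadyStateError(EngineError):
    """The balance equations are singular or force negative masses."""


class SimulationError(EngineError):
    """The integrator produced an invalid state."""


@dataclass(frozen=True)
class ComponentSpec:
    """One node of the model graph.

    Parameters
    ----------
    id : int
        Numeric label, unique within a system (0 is reserved for the
        environment).
    kind : str
        ``"compartment"``, ``"delay"`` or ``"sink"``.
    delay_time : float, optional
        ``DT(I)`` in days; required for delays, forbidden otherwise.
    observable : bool
        Marks plasma sampling sites.
    label : str
        Free-text annotation.
    """

    id: int
    kind: str = COMPARTMENT
    delay_time: float | None = None
    observable: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in (COMPARTMENT, DELAY, SINK):
            raise ValidationError(f"unknown component kind {self.kind!r}")
        if self.id == OUTSIDE_ID:
            raise ValidationError("component id 0 is reserved for the environment")
        if self.kind == DELAY:
            if self.delay_time is None or not self.delay_time > 0:
                raise ValidationError(
                    f"delay component {self.id} requires delay_time > 0"
                )
        elif self.delay_time is not None:
            raise ValidationError(
                f"component {self.id} is not a delay but has a delay_time"
            )


@dataclass(frozen=True)
class Transfer:
    """A directed flow ``from_id -> to_id``.

    For a compartment source the flow is ``base_rate * modifier *
    M(from)``; ``base_rate`` is the fractional transfer coefficient
    ``L(to, from)`` in 1/day.  For a delay source the transfer routes the
    delayed throughput and ``base_rate`` must be ``None`` (a delay
    releases exactly what entered it ``DT`` days before).

    ``modifier`` optionally names a time/state-dependent multiplier that
    is supplied at simulation time (control laws, perturbations).
    """

    to_id: int
    from_id: int
    base_rate: float | None
    modifier: str | None = None


@dataclass(frozen=True)
class ExternalInput:
    """De-novo input ``U(into_id)`` in μmol/day (or dose units/day).

    ``rate`` may be a nonnegative constant or a function of time.
    """

    into_id: int
    rate: float | Callable[[float], float]
    label: str = ""

    def rate_at(self, t: float) -> float:
        return self.rate(t) if callable(self.rate) else float(self.rate)

    @property
    def is_constant(self) -> bool:
        return not callable(self.rate)


class CompartmentalSystem:
    """A validated, immutable compartmental model.

    Build with :func:`build_system`; direct construction skips no
    validation but is not the intended entry point.
    """

    def __init__(
        self,
        components: Sequence[ComponentSpec],
        transfers: Sequence[Transfer],
        inputs: Sequence[ExternalInput] = (),
        initial_state: Mapping[int, float] | None = None,
    ) -> None:
        self.components: tuple[ComponentSpec, ...] = tuple(components)
        self.transfers: tuple[Transfer, ...] = tuple(transfers)
        self.inputs: tuple[ExternalInput, ...] = tuple(inputs)
        self.initial_state: dict[int, float] = dict(initial_state or {})
        self._by_id = {c.id: c for c in self.components}

    # -- introspection -------------------------------------------------
    def component(self, cid: int) -> ComponentSpec:
        return self._by_id[cid]

    @property
    def ids(self) -> list[int]:
        return [c.id for c in self.components]

    def of_kind(self, kind: str) -> list[ComponentSpec]:
        return [c for c in self.components if c.kind == kind]

    def outflows(self, cid: int) -> list[Transfer]:
        return [t for t in self.transfers if t.from_id == cid]

    def inflows(self, cid: int) -> list[Transfer]:
        return [t for t in self.transfers if t.to_id == cid]

    def with_initial_state(self, state: Mapping[int, float]) -> "CompartmentalSystem":
        return CompartmentalSystem(self.components, self.transfers, self.inputs, state)

    def replace_transfer(self, to_id: int, from_id: int, **changes) -> "CompartmentalSystem":
        """Return a copy with one transfer's fields replaced."""
        out, hit = [], False
        for t in self.transfers:
            if t.to_id == to_id and t.from_id == from_id:
                out.append(
                    Transfer(
                        to_id,
                        from_id,
                        changes.get("base_rate", t.base_rate),
                        changes.get("modifier", t.modifier),
                    )
                )
                hit = True
            else:
                out.append(t)
        if not hit:
            raise ValidationError(f"no transfer ({to_id},{from_id}) to replace")
        return CompartmentalSystem(self.components, out, self.inputs, self.initial_state)

    def modifier_names(self) -> set[str]:
        return {t.modifier for t in self.transfers if t.modifier is not None}


def build_system(
    components: Iterable[ComponentSpec],
    transfers: Iterable[Transfer],
    inputs: Iterable[ExternalInput] = (),
    initial_state: Mapping[int, float] | None = None,
) -> CompartmentalSystem:
    """Validate and assemble a :class:`CompartmentalSystem`.

    Raises
    ------
    ValidationError
        Dangling component references, duplicate ids, negative rates,
        delays without delay times, outflows from sinks, or delay
        elements chained directly into other delays.
    """
    comps = tuple(components)
    trans = tuple(transfers)
    ids = [c.id for c in comps]
    if len(ids) != len(set(ids)):
        raise ValidationError("component ids are not unique")
    by_id = {c.id: c for c in comps}

    for t in trans:
        for cid in (t.to_id, t.from_id):
            if cid != OUTSIDE_ID and cid not in by_id:
                raise ValidationError(f"transfer references unknown component id {cid}")
        if t.from_id == OUTSIDE_ID:
            raise ValidationError("the environment (id 0) cannot be a source")
        src = by_id[t.from_id]
        if src.kind == SINK:
            raise ValidationError(f"sink {t.from_id} cannot have outflows")
        if src.kind == DELAY:
            if t.base_rate is not None:
                raise ValidationError(
                    f"transfer out of delay {t.from_id} must have base_rate=None"
                )
            if t.to_id != OUTSIDE_ID and by_id[t.to_id].kind == DELAY:
                raise ValidationError("delay-to-delay transfers are not supported")
        else:
            if t.base_rate is None or t.base_rate < 0:
                raise ValidationError(
                    f"transfer ({t.to_id},{t.from_id}) needs base_rate >= 0"
                )

    for d in (c for c in comps if c.kind == DELAY):
        n_out = sum(1 for t in trans if t.from_id == d.id)
        if n_out != 1:
            raise ValidationError(
                f"delay {d.id} must have exactly one outgoing transfer, found {n_out}"
            )

    for u in inputs:
        if u.into_id not in by_id:
            raise ValidationError(f"input targets unknown component id {u.into_id}")
        if by_id[u.into_id].kind == SINK:
            raise ValidationError("external input into a sink is not meaningful")

    init = dict(initial_state or {})
    for cid, m in init.items():
        if cid not in by_id:
            raise ValidationError(f"initial state references unknown component {cid}")
        if m < 0:
            raise ValidationError(f"initial mass of component {cid} is negative")
    return CompartmentalSystem(comps, trans, tuple(inputs), init)


# ---------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------


@dataclass
class SteadyState:
    """Equilibrium solution of a linear system.

    Attributes
    ----------
    masses : dict
        ``M(I)`` per component id, in μmol; delay entries hold the
        material resident in the delay (throughput × DT).
    flows : dict
        ``R(I,J)`` per (to, from) transfer in μmol/day, including the
        pass-through flow released by each delay.
    inputs : dict
        ``U(I)`` per input target, in μmol/day (scaled so the anchored
        mass is matched exactly).
    input_scale : float
        Factor applied to the declared input pattern.
    """

    masses: dict[int, float]
    flows: dict[tuple[int, int], float]
    inputs: dict[int, float]
    input_scale: float

    def mass(self, cid: int) -> float:
        return self.masses[cid]

    def flow(self, to_id: int, from_id: int) -> float:
        return self.flows[(to_id, from_id)]

    def to_initial_state(self) -> dict[int, float]:
        return dict(self.masses)

    def sustained_system(self, system: "CompartmentalSystem") -> "CompartmentalSystem":
        """The same system with inputs scaled to sustain this equilibrium
        and the equilibrium set as initial state — simulating it
        unperturbed holds every pool constant."""
        inputs = [
            ExternalInput(u.into_id, u.rate_at(0.0) * self.input_scale, u.label)
            for u in system.inputs
        ]
        return CompartmentalSystem(
            system.components, system.transfers, inputs, self.to_initial_state()
        )

    def residual(self, system: CompartmentalSystem) -> float:
        """Largest relative flow imbalance over non-sink components."""
        worst = 0.0
        for c in system.components:
            if c.kind == SINK:
                continue
            inflow = sum(r for (to, _), r in self.flows.items() if to == c.id)
            inflow += self.inputs.get(c.id, 0.0)
            outflow = sum(r for (_, fr), r in self.flows.items() if fr == c.id)
            scale = max(inflow, outflow, 1e-30)
            worst = max(worst, abs(inflow - outflow) / scale)
        return worst


def _delay_terminus(system: CompartmentalSystem, delay_id: int) -> int:
    (out,) = [t for t in system.transfers if t.from_id == delay_id]
    return out.to_id


def steady_state_solve(
    system: CompartmentalSystem, anchor: tuple[int, float]
) -> SteadyState:
    """Solve the flow-balance equations of a linear system.

    The network is solved with every modifier at its reference value of
    one.  All declared external inputs are scaled by a common unknown
    factor chosen so that the anchored compartment's mass equals the
    anchor exactly (the WinSAAM workflow: assign the plasma pool, let
    the steady-state solution return the other pool sizes and the
    sustaining dietary input).

    Parameters
    ----------
    anchor : (component id, mass in μmol)
        Must reference a compartment with a positive mass.

    Raises
    ------
    SteadyStateError
        Singular balance system, no constant inputs, or an anchor that
        forces negative masses.
    """
    anchor_id, anchor_mass = anchor
    try:
        if system.component(anchor_id).kind != COMPARTMENT:
            raise SteadyStateError(f"anchor {anchor_id} is not a compartment")
    except KeyError:
        raise SteadyStateError(f"anchor references unknown component {anchor_id}")
    if anchor_mass <= 0:
        raise SteadyStateError("anchor mass must be positive")
    if not system.inputs:
        raise SteadyStateError("system has no external inputs; equilibrium is trivial")
    for u in system.inputs:
        if not u.is_constant:
            raise SteadyStateError("steady-state solve requires constant input rates")

    comp_ids = [c.id for c in system.of_kind(COMPARTMENT)]
    n = len(comp_ids)
    col = {cid: k for k, cid in enumerate(comp_ids)}

    # balance matrix over compartments, delays collapsed to their terminus
    A = np.zeros((n, n))
    for t in system.transfers:
        src = system.component(t.from_id)
        if src.kind == DELAY:
            continue
        rate = float(t.base_rate)
        A[col[t.from_id], col[t.from_id]] -= rate
        target = t.to_id
        if target != OUTSIDE_ID and system.component(target).kind == DELAY:
            target = _delay_terminus(system, target)
        if target != OUTSIDE_ID and system.component(target).kind == COMPARTMENT:
            A[col[target], col[t.from_id]] += rate

    b = np.zeros(n)
    for u in system.inputs:
        b[col[u.into_id]] += u.rate_at(0.0)
    if not np.any(b):
        raise SteadyStateError("all input rates are zero")

    # unknowns: masses of non-anchor compartments + the input scale
    free = [cid for cid in comp_ids if cid != anchor_id]
    m = len(free)
    M = np.zeros((n, m + 1))
    for k, cid in enumerate(free):
        M[:, k] = A[:, col[cid]]
    M[:, m] = b
    rhs = -A[:, col[anchor_id]] * anchor_mass
    sol, res, rank, sv = np.linalg.lstsq(M, rhs, rcond=None)
    if rank < m + 1:
        raise SteadyStateError("balance system is singular (rank deficient)")
    fitted = M @ sol
    if not np.allclose(fitted, rhs, rtol=1e-8, atol=1e-10 * max(1.0, abs(anchor_mass))):
        raise SteadyStateError("balance equations are inconsistent")

    masses = {anchor_id: float(anchor_mass)}
    for k, cid in enumerate(free):
        masses[cid] = float(sol[k])
    scale = float(sol[m])
    if scale <= 0 or any(v < -1e-9 * anchor_mass for v in masses.values()):
        raise SteadyStateError("anchor forces negative masses or input")
    masses = {cid: max(v, 0.0) for cid, v in masses.items()}

    flows: dict[tuple[int, int], float] = {}
    for t in system.transfers:
        if system.component(t.from_id).kind == DELAY:
            continue
        flows[(t.to_id, t.from_id)] = float(t.base_rate) * masses[t.from_id]
    # delay throughput, resident mass, and released flow
    for d in system.of_kind(DELAY):
        thru = sum(r for (to, _), r in flows.items() if to == d.id)
        masses[d.id] = thru * d.delay_time
        flows[(_delay_terminus(system, d.id), d.id)] = thru
    for s in system.of_kind(SINK):
        masses.setdefault(s.id, 0.0)

    inputs = {u.into_id: u.rate_at(0.0) * scale for u in system.inputs}
    return SteadyState(masses=masses, flows=flows, inputs=inputs, input_scale=scale)


# ---------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------


class StateView:
    """Read-only mapping from component id to current value."""

    __slots__ = ("_index", "_x")

    def __init__(self, index: Mapping[int, int], x: np.ndarray) -> None:
        self._index = index
        self._x = x

    def __getitem__(self, cid: int) -> float:
        return float(self._x[self._index[cid]])


Modifier = Callable[[float, StateView], float]

_CUMIN = "__cumulative_input__"


@dataclass
class Trajectory:
    """Time-indexed simulation output on a regular grid.

    ``states`` rows follow ``times``; columns follow ``index`` which maps
    component ids (plus :data:`OUTSIDE_ID` and an internal
    cumulative-input column) to column positions.
    """

    times: np.ndarray
    states: np.ndarray
    index: dict
    system: CompartmentalSystem
    modifiers: dict[str, Modifier] = field(default_factory=dict)

    def series(self, cid) -> np.ndarray:
        """Time series of one component (delay ids give resident mass)."""
        return self.states[:, self.index[cid]]

    def at(self, cid, t: float) -> float:
        """Value of a component at time ``t`` (nearest grid point)."""
        k = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[k] - t) > 0.51 * self._dt():
            raise KeyError(f"time {t} outside trajectory grid")
        return float(self.states[k, self.index[cid]])

    def _dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else np.inf

    def modifier_series(self, name: str) -> np.ndarray:
        fn = self.modifiers[name]
        out = np.empty(len(self.times))
        for k, t in enumerate(self.times):
            out[k] = fn(t, StateView(self.index, self.states[k]))
        return out

    def flux(self, to_id: int, from_id: int) -> np.ndarray:
        """Instantaneous flow R(to,from)(t) for a compartment-source transfer."""
        (tr,) = [
            t
            for t in self.system.transfers
            if t.to_id == to_id and t.from_id == from_id
        ]
        if self.system.component(from_id).kind == DELAY:
            raise ValueError("flux() supports compartment sources only")
        out = float(tr.base_rate) * self.series(from_id).copy()
        if tr.modifier is not None:
            out *= self.modifier_series(tr.modifier)
        return out

    def total_mass(self) -> np.ndarray:
        """System mass including delay content, sinks and environment."""
        cols = [c for cid, c in self.index.items() if cid != _CUMIN]
        return self.states[:, cols].sum(axis=1)

    def cumulative_input(self) -> np.ndarray:
        return self.states[:, self.index[_CUMIN]]

    def mass_balance_residual(self) -> float:
        """Max |total mass − initial mass − cumulative input| (abs units)."""
        total = self.total_mass()
        drift = total - total[0] - (self.cumulative_input() - self.cumulative_input()[0])
        return float(np.max(np.abs(drift)))

    def to_frame(self, pool_kind: str = "tracee_umol") -> pd.DataFrame:
        """Tidy export: (time_d, component_id, pool_kind, value)."""
        rows = []
        for c in self.system.components:
            rows.append(
                pd.DataFrame(
                    {
                        "time_d": self.times,
                        "component_id": c.id,
                        "pool_kind": pool_kind,
                        "value": self.series(c.id),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _hermite(y0, f0, y1, f1, h, theta):
    t2 = theta * theta
    t3 = t2 * theta
    return (
        (2 * t3 - 3 * t2 + 1) * y0
        + (t3 - 2 * t2 + theta) * h * f0
        + (-2 * t3 + 3 * t2) * y1
        + (t3 - t2) * h * f1
    )


def simulate(
    system: CompartmentalSystem,
    duration: float,
    *,
    start: float = 0.0,
    step: float = 0.01,
    out_step: float = 0.1,
    modifiers: Mapping[str, Modifier] | None = None,
    input_overrides: Mapping[int, Callable[[float], float]] | None = None,
    events: Mapping[float, Mapping[int, float]] | None = None,
) -> Trajectory:
    """Integrate the system over ``[start, start + duration]``.

    Classical RK4 on a fixed internal ``step`` (days) with delayed flows
    read from a cubic-Hermite history buffer; the step must not exceed
    the shortest delay time.  Output is recorded every ``out_step`` days.

    Parameters
    ----------
    modifiers : mapping name -> f(t, state) -> multiplier
        Implementations for every modifier name referenced by the
        system's transfers (control laws, perturbation multipliers).
    input_overrides : mapping component id -> rate function
        Replaces the declared external input into that component.
    events : mapping time -> {component id: mass increment}
        Instantaneous state jumps (e.g. a tracer dose given mid-run);
        event times must fall on internal grid nodes.

    Raises
    ------
    SimulationError
        Negative state beyond tolerance (a modeling error) or events off
        the internal grid.
    ValidationError
        A referenced modifier has no implementation.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    mods = dict(modifiers or {})
    missing = system.modifier_names() - set(mods)
    if missing:
        raise ValidationError(f"no implementation for modifiers {sorted(missing)}")

    delays = system.of_kind(DELAY)
    min_dt = min((d.delay_time for d in delays), default=np.inf)
    if step > min_dt + 1e-12:
        raise ValueError(
            f"internal step {step} exceeds the shortest delay time {min_dt}"
        )
    n_steps = int(round(duration / step))
    if abs(n_steps * step - duration) > 1e-9:
        raise ValueError("duration must be a multiple of the internal step")
    out_every = int(round(out_step / step))
    if abs(out_every * step - out_step) > 1e-12 or out_every < 1:
        raise ValueError("out_step must be a positive multiple of the internal step")

    # ---- compile ------------------------------------------------------
    ids = [c.id for c in system.components] + [OUTSIDE_ID, _CUMIN]
    index = {cid: k for k, cid in enumerate(ids)}
    ns = len(ids)
    kind = {c.id: c.kind for c in system.components}

    mod_names = sorted(system.modifier_names())
    mod_col = {name: k for k, name in enumerate(mod_names)}
    nm = len(mod_names)

    # vectorized direct transfers (compartment source)
    src_idx, dst_idx, rates, mcols = [], [], [], []
    for t in system.transfers:
        if kind[t.from_id] == DELAY:
            continue
        src_idx.append(index[t.from_id])
        dst_idx.append(index[t.to_id])
        rates.append(float(t.base_rate))
        mcols.append(mod_col[t.modifier] if t.modifier else nm)
    src_idx = np.array(src_idx, dtype=np.intp)
    dst_idx = np.array(dst_idx, dtype=np.intp)
    rates = np.array(rates)
    mcols = np.array(mcols, dtype=np.intp)

    # per-delay: inbound transfers (for the lagged release) and routing
    delay_info = []
    for d in delays:
        inbound = [
            (index[t.from_id], float(t.base_rate), t.modifier)
            for t in system.inflows(d.id)
        ]
        delay_info.append(
            (index[d.id], float(d.delay_time), index[_delay_terminus(system, d.id)], inbound)
        )

    input_fns: list[tuple[int, Callable[[float], float] | float]] = []
    overrides = dict(input_overrides or {})
    for u in system.inputs:
        if u.into_id in overrides:
            input_fns.append((index[u.into_id], overrides.pop(u.into_id)))
        else:
            input_fns.append((index[u.into_id], u.rate))
    for cid, fn in overrides.items():  # override may introduce a new input
        input_fns.append((index[cid], fn))

    y0 = np.zeros(ns)
    for cid, m in system.initial_state.items():
        y0[index[cid]] = m

    # ---- history ------------------------------------------------------
    Y = np.empty((n_steps + 1, ns))
    F = np.empty((n_steps + 1, ns))
    Y[0] = y0
    filled = 0  # highest node with a stored derivative

    def hist(tq: float) -> np.ndarray:
        if tq <= start + 1e-12:
            return Y[0]
        pos = (tq - start) / step
        k = min(int(pos + 1e-9), filled)
        theta = pos - k
        if theta <= 1e-9 or k >= filled:
            return Y[k]
        # states are nonnegative; clamp cubic undershoot (sharp fronts,
        # dose events) so delayed fluxes stay physical
        return np.maximum(
            _hermite(Y[k], F[k], Y[k + 1], F[k + 1], step, theta), 0.0
        )

    mvals = np.empty(nm + 1)
    mvals[nm] = 1.0

    def rhs(t: float, x: np.ndarray) -> np.ndarray:
        dx = np.zeros(ns)
        view = StateView(index, x)
        for name in mod_names:
            mvals[mod_col[name]] = mods[name](t, view)
        flux = rates * mvals[mcols] * x[src_idx]
        np.subtract.at(dx, src_idx, flux)
        np.add.at(dx, dst_idx, flux)
        for content_i, dtv, target_i, inbound in delay_info:
            if t - dtv < start - 1e-12:
                # before one delay time has elapsed the release is set by
                # the element's initial loading (uniform along the pipe):
                # zero when started empty, the steady through-flow when
                # initialized at equilibrium
                out = y0[content_i] / dtv
            else:
                xl = hist(t - dtv)
                lview = StateView(index, xl)
                out = 0.0
                for si, rate, mname in inbound:
                    mult = mods[mname](t - dtv, lview) if mname else 1.0
                    out += rate * mult * xl[si]
            dx[content_i] -= out
            dx[target_i] += out
        cum = 0.0
        for into_i, fn in input_fns:
            r = fn(t) if callable(fn) else fn
            dx[into_i] += r
            cum += r
        dx[index[_CUMIN]] += cum
        return dx

    # ---- events -------------------------------------------------------
    ev_at: dict[int, dict[int, float]] = {}
    for te, deltas in (events or {}).items():
        node = int(round((te - start) / step))
        if abs(start + node * step - te) > 1e-9 or not (0 <= node <= n_steps):
            raise SimulationError(f"event time {te} is off the internal grid")
        ev_at.setdefault(node, {}).update(deltas)
    if 0 in ev_at:
        for cid, dm in ev_at[0].items():
            Y[0, index[cid]] += dm

    # ---- march --------------------------------------------------------
    # small negative undershoot at sharp tracer fronts is integrator
    # ringing, not model error; clip it, fail on anything larger
    neg_clip = 1e-5
    h = step
    for k in range(n_steps):
        t = start + k * h
        yk = Y[k]
        F[k] = rhs(t, yk)
        filled = k
        k2 = rhs(t + h / 2, yk + (h / 2) * F[k])
        k3 = rhs(t + h / 2, yk + (h / 2) * k2)
        k4 = rhs(t + h, yk + h * k3)
        ynew = yk + (h / 6) * (F[k] + 2 * k2 + 2 * k3 + k4)
        low = ynew.min()
        if low < -neg_clip:
            bad = ids[int(np.argmin(ynew))]
            raise SimulationError(
                f"state of component {bad} went negative ({low:.3e}) at t={t + h:.3f}"
            )
        np.clip(ynew, 0.0, None, out=ynew)
        if k + 1 in ev_at:
            for cid, dm in ev_at[k + 1].items():
                ynew[index[cid]] += dm
        Y[k + 1] = ynew
    F[n_steps] = rhs(start + n_steps * h, Y[n_steps])
    filled = n_steps

    sel = np.arange(0, n_steps + 1, out_every)
    times = start + sel * h
    return Trajectory(
        times=times,
        states=Y[sel].copy(),
        index=index,
        system=system,
        modifiers=dict(mods),
    )


def delay_output(
    times: np.ndarray,
    input_flow: Callable[[float], float] | np.ndarray,
    delay_time: float,
    *,
    initial: str = "empty",
) -> np.ndarray:
    """Output flow of an ideal delay element: ``out(t) = in(t - DT)``.

    ``input_flow`` is either a callable on ``[times[0], times[-1]]`` or an
    array aligned with ``times`` (linearly interpolated).  Before one
    delay time has elapsed the element releases nothing when started
    empty (``initial="empty"``) or the flow it held at equilibrium
    (``initial="steady"``, i.e. the input at ``times[0]``).
    """
    times = np.asarray(times, dtype=float)
    if delay_time <= 0:
        raise ValueError("delay_time must be positive")
    if callable(input_flow):
        u = input_flow
    else:
        vals = np.asarray(input_flow, dtype=float)

        def u(tq: float) -> float:
            return float(np.interp(tq, times, vals))

    t0 = times[0]
    out = np.empty_like(times)
    for k, t in enumerate(times):
        tq = t - delay_time
        if tq < t0 - 1e-12:
            out[k] = u(t0) if initial == "steady" else 0.0
        else:
            out[k] = u(max(tq, t0))
    return out
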