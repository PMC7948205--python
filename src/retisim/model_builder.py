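"""Construct tracer, tracee and linked retinol–RBP models from a deck.

Topology (tracer ids / tracee ids):

* gut lumen 1/11 — site of the oral dose and dietary vitamin A, and of
  unabsorbed loss ``L(0,1)``; the absorption efficiency *a* is the split
  ``a = L(2,1) / (L(2,1) + L(0,1))``,
* 2/12 → digestion/absorption delay 3/13 → plasma chylomicron pool
  10/20 → chylomicron-remnant uptake delay 25/35 → hepatocyte retinol
  4/14,
* hepatocyte secretion 4→5 / 14→15 into plasma retinol (5/15, the
  sampling site), exchange with a large storage pool (6/16, hepatic
  stellate cells) and a small extravascular pool (7/17), irreversible
  disposal 6→9 / 16→19.

Embedded RBP sub-model (shared by both isotope forms): apo-RBP is
synthesized into hepatocyte pool 43 at rate U(43); a fraction binds
diet-derived retinol from 14 and enters plasma holo-RBP pool 45, the
rest transfers to the stellate pool 44 where it binds stored retinol
from 16.  Retinol cannot leave the liver without RBP, so the secretion
coefficients are scaled by the apo-RBP pools relative to their steady
state::

    L(15,14)(t) = L(15,14) · M43(t)/M43_ss      (same multiplier on L(5,4))
    L(15,16)(t) = L(15,16) · M44(t)/M44_ss      (same multiplier on L(5,6))

and, stoichiometrically, apo-RBP leaves 43 (resp. 44) as holo-RBP at
exactly the molar rate retinol enters plasma from 14 (resp. 16).
Plasma holo-RBP (45) is cleared first order, sized so M45_ss equals the
plasma retinol pool (1:1 molar ratio in circulation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .engine import (
    COMPARTMENT,
    DELAY,
    SINK,
    OUTSIDE_ID,
    CompartmentalSystem,
    ComponentSpec,
    ExternalInput,
    SteadyState,
    Trajectory,
    Transfer,
    ValidationError,
    build_system,
    steady_state_solve,
)
from .subjects import SubjectDeck

__all__ = [
    "TRACER_TO_TRACEE",
    "TRACER_STORES",
    "TRACEE_STORES",
    "RBPRouting",
    "ControlLaw",
    "LinkedModel",
    "build_tracer_model",
    "build_tracee_model",
    "build_linked_model",
    "rbp_split_fractions",
    "stellate_share_timecourse",
]

#: tracer component id -> parallel tracee id
TRACER_TO_TRACEE = {1: 11, 2: 12, 3: 13, 10: 20, 25: 35, 4: 14, 5: 15, 6: 16, 7: 17, 9: 19}

#: compartments counted as "stores" (post-absorptive, non-plasma)
TRACER_STORES = (4, 6, 7)
TRACEE_STORES = (14, 16, 17)

# modifier names bound by the linked model
MOD_APO_HEP = "apo_rbp_hepatocyte"     # M43 / M43_ss, scales L(5,4) & L(15,14)
MOD_APO_STELL = "apo_rbp_stellate"     # M44 / M44_ss, scales L(5,6) & L(15,16)
MOD_RET_HEP = "hepatocyte_retinol"     # M14 / M14_ss, scales holo output of 43
MOD_RET_STORE = "store_retinol"        # M16 / M16_ss, scales holo output of 44

RBP_HEPATOCYTE = 43
RBP_STELLATE = 44
PLASMA_HOLO_RBP = 45
RBP_CLEARANCE_SINK = 46


@dataclass(frozen=True)
class RBPRouting:
    """Split of newly made apo-RBP between the two secretion pathways."""

    hepatocyte_fraction: float
    stellate_fraction: float

    def __post_init__(self) -> None:
        if self.hepatocyte_fraction < 0 or self.stellate_fraction < 0:
            raise ValueError("routing fractions must be nonnegative")
        if abs(self.hepatocyte_fraction + self.stellate_fraction - 1.0) > 1e-9:
            raise ValueError("routing fractions must sum to 1")


@dataclass(frozen=True)
class ControlLaw:
    """A secretion coefficient slaved to an apo-RBP pool.

    The multiplier is ``M(pool)(t) / reference_mass`` — unity at steady
    state, proportional to available apo-RBP otherwise.
    """

    transfer: tuple[int, int]       # (to, from) of the controlled transfer
    controlling_pool: int           # 43 or 44
    reference_mass: float           # steady-state mass of the pool, μmol
    name: str                       # modifier name bound in the system


def _tracer_components(deck: SubjectDeck) -> list[ComponentSpec]:
    return [
        ComponentSpec(1, label="gut lumen (dose site)"),
        ComponentSpec(2, label="absorption/chylomicron production"),
        ComponentSpec(3, DELAY, deck.DT(3), label="digestion delay"),
        ComponentSpec(10, observable=True, label="plasma chylomicron RE"),
        ComponentSpec(25, DELAY, deck.DT(25), label="remnant uptake delay"),
        ComponentSpec(4, label="hepatocyte retinol"),
        ComponentSpec(5, observable=True, label="plasma retinol"),
        ComponentSpec(6, label="storage pool (stellate)"),
        ComponentSpec(7, label="small extravascular pool"),
        ComponentSpec(9, SINK, label="irreversible loss"),
    ]


def _tracer_transfers(
    deck: SubjectDeck, *, controlled: bool, absorption: float | None = None
) -> list[Transfer]:
    a = deck.absorption_efficiency if absorption is None else absorption
    if not 0 < a <= 1:
        raise ValueError("absorption efficiency must be in (0, 1]")
    # the total exit rate from the gut lumen is a property of digestion and
    # stays fixed; absorption only moves the split between the absorptive
    # path and unabsorbed loss, so post-gut tracer curves scale exactly
    # with the absorbed fraction
    gut_exit = deck.L(2, 1) / deck.absorption_efficiency
    out = [
        Transfer(2, 1, a * gut_exit),
        Transfer(3, 2, deck.L(3, 2)),
        Transfer(10, 3, None),
        Transfer(25, 10, deck.L(25, 10)),
        Transfer(4, 25, None),
        Transfer(5, 4, deck.L(5, 4), MOD_APO_HEP if controlled else None),
        Transfer(6, 5, deck.L(6, 5)),
        Transfer(7, 5, deck.L(7, 5)),
        Transfer(5, 6, deck.L(5, 6), MOD_APO_STELL if controlled else None),
        Transfer(5, 7, deck.L(5, 7)),
        Transfer(9, 6, deck.L(9, 6)),
    ]
    if a < 1.0:
        out.append(Transfer(OUTSIDE_ID, 1, (1.0 - a) * gut_exit))
    return out


def build_tracer_model(
    deck: SubjectDeck, *, absorption: float | None = None
) -> CompartmentalSystem:
    """The stand-alone (linear) tracer model with a unit dose in the gut.

    Secretion coefficients carry no control laws here — this is the
    steady-state tracer model used for RID coefficient generation and
    for absorption experiments (``absorption`` overrides the deck's
    tracer absorption efficiency without touching anything else, so
    trajectories of all post-gut components scale exactly with the
    absorbed fraction).
    """
    return build_system(
        _tracer_components(deck),
        _tracer_transfers(deck, controlled=False, absorption=absorption),
        [],
        {1: 1.0},
    )


def _map_tracee(tid: int) -> int:
    return TRACER_TO_TRACEE.get(tid, tid) if tid != OUTSIDE_ID else OUTSIDE_ID


def build_tracee_model(deck: SubjectDeck) -> CompartmentalSystem:
    """The parallel tracee model: identical coefficients, dietary input.

    Mirrors every tracer component and transfer one-for-one onto the
    tracee ids; dietary vitamin A enters the gut (11) at the deck's
    intake (or a unit pattern when the intake is to be solved).
    """
    comps = []
    for c in _tracer_components(deck):
        comps.append(
            ComponentSpec(
                _map_tracee(c.id), c.kind, c.delay_time, c.observable, c.label
            )
        )
    trans = [
        Transfer(_map_tracee(t.to_id), _map_tracee(t.from_id), t.base_rate, t.modifier)
        for t in _tracer_transfers(deck, controlled=False)
    ]
    diet = deck.dietary_intake if deck.dietary_intake is not None else 1.0
    return build_system(comps, trans, [ExternalInput(11, diet, "dietary vitamin A")])


@dataclass
class LinkedModel:
    """Tracer + tracee + RBP systems with bound control laws.

    ``system`` is the combined executable model (one state vector);
    ``steady`` its full equilibrium, used both as initial condition and
    as the reference for every control law.  ``modifiers`` holds the
    control-law implementations to pass to :func:`retisim.engine.simulate`.
    """

    deck: SubjectDeck
    system: CompartmentalSystem
    steady: SteadyState
    modifiers: dict
    control_laws: tuple[ControlLaw, ...]
    routing: RBPRouting
    steady_p43: float                 # R(15,14)+R(15,16), μmol/d
    tracer_stores: tuple[int, ...] = TRACER_STORES
    tracee_stores: tuple[int, ...] = TRACEE_STORES

    @property
    def plasma_tracer(self) -> int:
        return 5

    @property
    def plasma_tracee(self) -> int:
        return 15

    @property
    def tbs_steady(self) -> float:
        return sum(self.steady.mass(c) for c in self.tracee_stores)

    def simulate(
        self,
        duration: float = 30.0,
        *,
        dose: float = 1.0,
        dose_day: float = 0.0,
        u43: "float | None | object" = None,
        step: float = 0.01,
        out_step: float = 0.1,
    ) -> Trajectory:
        """Simulate the linked model from its steady state.

        The tracer dose (fraction-of-dose units, normally 1) is placed
        in the gut at ``dose_day``.  ``u43`` optionally replaces the
        constant steady apo-RBP input with a function of time (an
        inflammation forcing); the tracee and RBP pools start at steady
        state so with no forcing every pool stays flat.
        """
        from .engine import simulate as _simulate

        overrides = {}
        if u43 is not None:
            overrides[RBP_HEPATOCYTE] = u43 if callable(u43) else (lambda t: float(u43))
        events = {dose_day: {1: dose}} if dose > 0 else None
        return _simulate(
            self.system,
            duration,
            step=step,
            out_step=out_step,
            modifiers=self.modifiers,
            input_overrides=overrides,
            events=events,
        )


def rbp_split_fractions(steady: SteadyState) -> RBPRouting:
    """Apo-RBP routing from the steady flows of retinol into plasma.

    The hepatocyte fraction is ``R(15,14) / (R(15,14)+R(15,16))`` — the
    share of plasma retinol input that is diet-derived secretion — and
    the stellate fraction its complement (the recycled share).
    """
    r_hep = steady.flows.get((15, 14), 0.0)
    r_stell = steady.flows.get((15, 16), 0.0)
    total = r_hep + r_stell
    if total <= 0:
        raise ValueError("no retinol input into plasma; routing undefined")
    return RBPRouting(r_hep / total, r_stell / total)


def build_linked_model(
    deck: SubjectDeck, *, include_plasma_in_stores: bool = False
) -> LinkedModel:
    """Assemble the full tracer+tracee+RBP model for one subject.

    Steps: solve the tracee steady state anchored at the assigned
    plasma pool; derive the basal apo-RBP input ``P(43) = R(15,14) +
    R(15,16)`` and its hepatocyte/stellate routing from the steady
    flows; size the apo-RBP pools from the deck's mean residence times;
    bind the control laws; and set steady-state initial conditions
    everywhere (tracer compartments start empty).

    Raises
    ------
    ValueError
        Zero steady-state flow on a required secretion path (the
        routing and control laws would be undefined).
    """
    tracee = build_tracee_model(deck)
    ss = steady_state_solve(tracee, (15, deck.plasma_pool))
    r_hep = ss.flow(15, 14)
    r_stell = ss.flow(15, 16)
    p43 = r_hep + r_stell
    if r_hep <= 0:
        raise ValueError("zero hepatocyte secretion flow; apo-RBP routing undefined")
    routing = rbp_split_fractions(ss)

    m43_ss = deck.rbp_residence["43"] * p43
    m44_ss = deck.rbp_residence["44"] * r_stell if r_stell > 0 else None
    m14_ss = ss.mass(14)
    m16_ss = ss.mass(16)
    m15_ss = ss.mass(15)

    comps = _tracer_components(deck)
    comps += [
        ComponentSpec(
            _map_tracee(c.id), c.kind, c.delay_time, c.observable, "tracee " + c.label
        )
        for c in _tracer_components(deck)
    ]
    comps += [
        ComponentSpec(RBP_HEPATOCYTE, label="hepatocyte apo-RBP"),
        ComponentSpec(PLASMA_HOLO_RBP, observable=True, label="plasma holo-RBP"),
        ComponentSpec(RBP_CLEARANCE_SINK, SINK, label="holo-RBP clearance"),
    ]

    controlled = _tracer_transfers(deck, controlled=True)
    trans = list(controlled)
    trans += [
        Transfer(_map_tracee(t.to_id), _map_tracee(t.from_id), t.base_rate, t.modifier)
        for t in controlled
    ]
    # RBP sub-model: holo secretion mirrors the retinol fluxes 1:1
    trans.append(
        Transfer(PLASMA_HOLO_RBP, RBP_HEPATOCYTE, r_hep / m43_ss, MOD_RET_HEP)
    )
    laws = [
        ControlLaw((5, 4), RBP_HEPATOCYTE, m43_ss, MOD_APO_HEP),
        ControlLaw((15, 14), RBP_HEPATOCYTE, m43_ss, MOD_APO_HEP),
    ]
    if r_stell > 0:
        comps.append(ComponentSpec(RBP_STELLATE, label="stellate-cell apo-RBP"))
        trans.append(Transfer(RBP_STELLATE, RBP_HEPATOCYTE, r_stell / m43_ss))
        trans.append(
            Transfer(PLASMA_HOLO_RBP, RBP_STELLATE, r_stell / m44_ss, MOD_RET_STORE)
        )
        laws += [
            ControlLaw((5, 6), RBP_STELLATE, m44_ss, MOD_APO_STELL),
            ControlLaw((15, 16), RBP_STELLATE, m44_ss, MOD_APO_STELL),
        ]
    trans.append(Transfer(RBP_CLEARANCE_SINK, PLASMA_HOLO_RBP, p43 / m15_ss))

    inputs = [
        ExternalInput(11, ss.inputs[11], "dietary vitamin A"),
        ExternalInput(RBP_HEPATOCYTE, p43, "apo-RBP synthesis U(43)"),
    ]

    init = ss.to_initial_state()
    init = {cid: m for cid, m in init.items() if m > 0 or cid in TRACEE_STORES}
    init[RBP_HEPATOCYTE] = m43_ss
    init[PLASMA_HOLO_RBP] = m15_ss
    if r_stell > 0:
        init[RBP_STELLATE] = m44_ss

    modifiers = {
        MOD_APO_HEP: lambda t, v: v[RBP_HEPATOCYTE] / m43_ss,
        MOD_RET_HEP: lambda t, v: v[14] / m14_ss,
    }
    if r_stell > 0:
        modifiers[MOD_APO_STELL] = lambda t, v: v[RBP_STELLATE] / m44_ss
        modifiers[MOD_RET_STORE] = lambda t, v: v[16] / m16_ss
    else:
        # degenerate deck without storage recycling: multiplier unused but
        # the tracer transfer L(5,6)=0 still references it
        modifiers[MOD_APO_STELL] = lambda t, v: 1.0
        modifiers[MOD_RET_STORE] = lambda t, v: 1.0

    system = build_system(comps, trans, inputs, init)

    # extend the steady state with the RBP pools for reporting
    masses = dict(ss.masses)
    masses[RBP_HEPATOCYTE] = m43_ss
    masses[PLASMA_HOLO_RBP] = m15_ss
    flows = dict(ss.flows)
    flows[(PLASMA_HOLO_RBP, RBP_HEPATOCYTE)] = r_hep
    flows[(RBP_CLEARANCE_SINK, PLASMA_HOLO_RBP)] = p43
    if r_stell > 0:
        masses[RBP_STELLATE] = m44_ss
        flows[(RBP_STELLATE, RBP_HEPATOCYTE)] = r_stell
        flows[(PLASMA_HOLO_RBP, RBP_STELLATE)] = r_stell
    inputs_ss = dict(ss.inputs)
    inputs_ss[RBP_HEPATOCYTE] = p43
    full_ss = SteadyState(masses, flows, inputs_ss, ss.input_scale)

    tracer_stores = TRACER_STORES + ((5,) if include_plasma_in_stores else ())
    tracee_stores = TRACEE_STORES + ((15,) if include_plasma_in_stores else ())
    return LinkedModel(
        deck=deck,
        system=system,
        steady=full_ss,
        modifiers=modifiers,
        control_laws=tuple(laws),
        routing=routing,
        steady_p43=p43,
        tracer_stores=tracer_stores,
        tracee_stores=tracee_stores,
    )


def stellate_share_timecourse(traj: Trajectory) -> np.ndarray:
    """Fraction of plasma retinol input arriving via the stellate path.

    ``share(t) = R(15,16)(t) / [R(15,14)(t) + R(15,16)(t)]``; undefined
    points (zero total flux) are reported as NaN.
    """
    r_stell = traj.flux(15, 16)
    r_hep = traj.flux(15, 14)
    total = r_hep + r_stell
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(total > 0, r_stell / np.where(total > 0, total, 1.0), np.nan)
    return share
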