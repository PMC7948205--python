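"""Subject parameter decks: schema, I/O, the subject-2 replica, and a
random plausible-subject generator.

A *deck* is the complete kinetic parameterization of one theoretical
subject: fractional transfer coefficients ``L(I,J)`` of the tracer
model, delay times ``DT(I)``, the assigned plasma retinol pool size
(the steady-state anchor), vitamin A absorption efficiency, and the
mean residence times of the two apo-RBP pools.  Decks serialize to JSON
with the field labels used in compartmental-modeling practice
(``"L(5,4)"``, ``"DT(3)"`` ...).

The packaged **subject-2 replica** is a deck calibrated once so that
its steady state and its acute-inflammation response reproduce the
published landmark values for that subject (plasma pool 5 μmol, total
body stores 980 μmol, apo-RBP demand 14 μmol/d, 90% stellate share of
plasma retinol input, 74% absorption, and the tracer/tracee response
ratios under acute inflammation).  The original per-subject transfer
coefficients are not public; the replica is defined by those anchors
(see ``scripts/calibrate_replica.py`` for the fit and its residuals).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "TRACER_TRANSFER_KEYS",
    "DELAY_KEYS",
    "SubjectDeck",
    "SubjectRanges",
    "make_deck",
    "subject2_replica",
    "generate_subject",
    "load_deck",
    "save_deck",
    "deck_to_table",
    "deck_from_table",
]

#: transfer coefficients a tracer deck must provide (Fig.-1A-style ids)
TRACER_TRANSFER_KEYS = (
    "L(2,1)",   # gut lumen -> absorptive/chylomicron-producing pool
    "L(3,2)",   # into the digestion/absorption delay
    "L(25,10)", # plasma chylomicron clearance into the remnant-uptake delay
    "L(5,4)",   # hepatocyte retinol secretion into plasma (RBP-dependent)
    "L(6,5)",   # plasma -> large (stellate) storage pool
    "L(7,5)",   # plasma -> small extravascular pool
    "L(5,6)",   # storage mobilization into plasma (RBP-dependent)
    "L(5,7)",   # small pool return to plasma
    "L(9,6)",   # irreversible disposal from the storage pool
)
DELAY_KEYS = ("DT(3)", "DT(25)")

SCHEMA_VERSION = 1


class SubjectDeck(BaseModel):
    """Full kinetic parameterization of one subject (tracer-model labels)."""

    model_config = {"frozen": True}

    schema_version: int = SCHEMA_VERSION
    subject_id: str
    plasma_pool: float = Field(gt=0, description="assigned M(5), μmol")
    tbs_assigned: float = Field(gt=0, description="assigned total body stores, μmol")
    absorption_efficiency: float = Field(gt=0, le=1)
    transfer_set: dict[str, float]
    delay_times: dict[str, float]
    dietary_intake: float | None = Field(
        default=None, description="μmol/d into the gut; solved from the steady state if absent"
    )
    rbp_residence: dict[str, float] = Field(
        default={"43": 0.4, "44": 1.8},
        description="mean residence time (days) of apo-RBP in hepatocytes (43) and stellate cells (44)",
    )

    @field_validator("transfer_set")
    @classmethod
    def _check_transfers(cls, v: dict[str, float]) -> dict[str, float]:
        missing = [k for k in TRACER_TRANSFER_KEYS if k not in v]
        if missing:
            raise ValueError(f"transfer_set is missing {missing}")
        for k, val in v.items():
            if val < 0:
                raise ValueError(f"{k} must be >= 0, got {val}")
        return v

    @field_validator("delay_times")
    @classmethod
    def _check_delays(cls, v: dict[str, float]) -> dict[str, float]:
        missing = [k for k in DELAY_KEYS if k not in v]
        if missing:
            raise ValueError(f"delay_times is missing {missing}")
        for k, val in v.items():
            if val <= 0:
                raise ValueError(f"{k} must be > 0, got {val}")
        return v

    @model_validator(mode="after")
    def _check_rbp(self) -> "SubjectDeck":
        for key in ("43", "44"):
            if key not in self.rbp_residence:
                raise ValueError(f"rbp_residence is missing pool {key!r}")
            if self.rbp_residence[key] <= 0:
                raise ValueError("rbp_residence must be positive")
        return self

    # -- convenience ---------------------------------------------------
    def L(self, to_id: int, from_id: int) -> float:
        return self.transfer_set[f"L({to_id},{from_id})"]

    def DT(self, cid: int) -> float:
        return self.delay_times[f"DT({cid})"]

    @property
    def unabsorbed_loss_rate(self) -> float:
        """L(0,1): a = L(2,1) / (L(2,1) + L(0,1))."""
        a = self.absorption_efficiency
        return self.L(2, 1) * (1.0 - a) / a


def make_deck(
    subject_id: str,
    *,
    plasma_pool: float,
    tbs: float,
    absorption: float,
    stellate_share: float = 0.90,
    rbp_input: float = 14.0,
    hepatocyte_mass: float = 1.0,
    small_pool_mass: float = 25.0,
    small_pool_exchange: float = 2.0,
    gut_emptying: float = 3.0,
    chylomicron_production: float = 6.0,
    dt_absorption: float = 0.25,
    chylomicron_clearance: float = 12.0,
    dt_remnant: float = 0.1,
    rbp_residence: Mapping[str, float] | None = None,
) -> SubjectDeck:
    """Build a deck from physiological state variables.

    The transfer coefficients are chosen so that, anchored at
    ``plasma_pool``, the steady state reproduces the requested total
    body stores, stellate-cell share of plasma retinol input and
    RBP-mediated plasma input rate exactly:

    * ``rbp_input`` (μmol/d) is the total retinol flow into plasma
      carried by RBP, i.e. hepatocyte secretion plus storage recycling;
    * ``stellate_share`` is the recycled fraction of that flow;
    * ``hepatocyte_mass`` and ``small_pool_mass`` (μmol) size the
      hepatocyte and small extravascular pools; the storage pool takes
      the remainder of ``tbs``;
    * ``small_pool_exchange`` (μmol/d) is the plasma/small-pool
      exchange flow.

    Dietary intake follows from absorption: at steady state disposal
    equals absorbed intake equals hepatocyte secretion.
    """
    if not 0 < stellate_share < 1:
        raise ValueError("stellate_share must be in (0, 1)")
    m6 = tbs - hepatocyte_mass - small_pool_mass
    if m6 <= 0:
        raise ValueError("tbs too small for the requested hepatocyte/small pools")
    r54 = (1.0 - stellate_share) * rbp_input   # diet-derived secretion, μmol/d
    r56 = stellate_share * rbp_input           # storage recycling, μmol/d
    transfers = {
        "L(2,1)": absorption * gut_emptying,
        "L(3,2)": chylomicron_production,
        "L(25,10)": chylomicron_clearance,
        "L(5,4)": r54 / hepatocyte_mass,
        "L(6,5)": rbp_input / plasma_pool,
        "L(7,5)": small_pool_exchange / plasma_pool,
        "L(5,6)": r56 / m6,
        "L(5,7)": small_pool_exchange / small_pool_mass,
        "L(9,6)": r54 / m6,
    }
    return SubjectDeck(
        subject_id=subject_id,
        plasma_pool=plasma_pool,
        tbs_assigned=tbs,
        absorption_efficiency=absorption,
        transfer_set=transfers,
        delay_times={"DT(3)": dt_absorption, "DT(25)": dt_remnant},
        dietary_intake=r54 / absorption,
        rbp_residence=dict(rbp_residence) if rbp_residence else {"43": 0.4, "44": 1.8},
    )


# ---------------------------------------------------------------------
# packaged replica
# ---------------------------------------------------------------------


def subject2_replica() -> SubjectDeck:
    """The packaged subject-2 replica deck (calibrated, frozen)."""
    text = resources.files("retisim.data").joinpath("subject2_replica.json").read_text()
    return SubjectDeck.model_validate_json(text)


# ---------------------------------------------------------------------
# random plausible subjects
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectRanges:
    """Sampling ranges for the plausible-subject generator.

    Defaults span healthy adults with normal plasma retinol: plasma pool
    3–8 μmol, total body stores 100–1500 μmol, absorption 50–90%, and
    kinetic rates bracketing the replica's values.  All ranges are
    (low, high) with low < high or low == high for a pinned value.
    """

    plasma_pool: tuple[float, float] = (3.0, 8.0)
    tbs: tuple[float, float] = (100.0, 1500.0)
    absorption: tuple[float, float] = (0.50, 0.90)
    plasma_turnover: tuple[float, float] = (1.8, 3.6)      # RBP-borne inflow / plasma pool, 1/d
    stellate_share: tuple[float, float] = (0.80, 0.95)
    hepatocyte_residence: tuple[float, float] = (0.4, 1.2)  # days, hepatocyte retinol
    small_pool_equil_days: tuple[float, float] = (0.8, 2.5)  # small-pool turnover time, d
    exchange_turnover: tuple[float, float] = (1.0, 4.0)    # plasma->small pool, 1/d
    rbp_residence_43: tuple[float, float] = (0.10, 0.40)   # days
    rbp_residence_44: tuple[float, float] = (0.08, 0.40)   # days

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.__dict__.items():
            if not (0 < lo <= hi):
                raise ValueError(f"range {name} must satisfy 0 < low <= high")


def _draw(rng: np.random.Generator, lo_hi: tuple[float, float]) -> float:
    lo, hi = lo_hi
    return float(rng.uniform(lo, hi))


def generate_subject(
    ranges: SubjectRanges | None = None, seed: int = 0, *, max_rejections: int = 1000
) -> SubjectDeck:
    """Draw a random subject deck with a solvable, positive steady state.

    Deterministic for a fixed seed.  Candidates whose steady state fails
    to solve (or balances poorly) are rejected and redrawn; after
    ``max_rejections`` consecutive rejections the ranges are declared
    infeasible.
    """
    from . import model_builder  # deferred: circular at import time
    from .engine import SteadyStateError, ValidationError, steady_state_solve

    ranges = ranges or SubjectRanges()
    rng = np.random.default_rng(seed)
    for attempt in range(max_rejections):
        plasma = _draw(rng, ranges.plasma_pool)
        tbs = _draw(rng, ranges.tbs)
        rbp_input = plasma * _draw(rng, ranges.plasma_turnover)
        share = _draw(rng, ranges.stellate_share)
        m4 = (1.0 - share) * rbp_input * _draw(rng, ranges.hepatocyte_residence)
        exch = plasma * _draw(rng, ranges.exchange_turnover)
        m7 = exch * _draw(rng, ranges.small_pool_equil_days)
        try:
            deck = make_deck(
                f"random-{seed}" if attempt == 0 else f"random-{seed}.{attempt}",
                plasma_pool=plasma,
                tbs=tbs,
                absorption=_draw(rng, ranges.absorption),
                stellate_share=share,
                rbp_input=rbp_input,
                hepatocyte_mass=m4,
                small_pool_mass=m7,
                small_pool_exchange=exch,
                gut_emptying=float(rng.uniform(3.0, 9.0)),
                chylomicron_production=float(rng.uniform(5.0, 14.0)),
                dt_absorption=float(rng.uniform(0.15, 0.35)),
                chylomicron_clearance=float(rng.uniform(10.0, 20.0)),
                dt_remnant=float(rng.uniform(0.1, 0.2)),
                rbp_residence={
                    "43": _draw(rng, ranges.rbp_residence_43),
                    "44": _draw(rng, ranges.rbp_residence_44),
                },
            )
            system = model_builder.build_tracee_model(deck)
            ss = steady_state_solve(system, (15, deck.plasma_pool))
            if ss.residual(system) > 1e-8:
                continue
        except (ValueError, ValidationError, SteadyStateError):
            continue
        return deck
    raise RuntimeError(
        f"no feasible subject found in {max_rejections} draws; ranges are infeasible"
    )


# ---------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------


def load_deck(path: str | Path) -> SubjectDeck:
    """Read and validate a deck from JSON (field-level error messages)."""
    return SubjectDeck.model_validate_json(Path(path).read_text())


def save_deck(deck: SubjectDeck, path: str | Path) -> None:
    """Write a deck as canonical, sorted-key JSON (load→save is stable)."""
    Path(path).write_text(
        json.dumps(deck.model_dump(), indent=2, sort_keys=True) + "\n"
    )


def deck_to_table(deck: SubjectDeck) -> pd.DataFrame:
    """Long-format parameter table (parameter, value) for CSV export."""
    rows = [
        ("subject_id", deck.subject_id),
        ("schema_version", deck.schema_version),
        ("plasma_pool", deck.plasma_pool),
        ("tbs_assigned", deck.tbs_assigned),
        ("absorption_efficiency", deck.absorption_efficiency),
        ("dietary_intake", deck.dietary_intake),
    ]
    rows += sorted(deck.transfer_set.items())
    rows += sorted(deck.delay_times.items())
    rows += [(f"rbp_residence({k})", v) for k, v in sorted(deck.rbp_residence.items())]
    return pd.DataFrame(rows, columns=["parameter", "value"])


def deck_from_table(table: pd.DataFrame) -> SubjectDeck:
    """Rebuild a deck from :func:`deck_to_table` output (round-trip)."""
    kv = dict(zip(table["parameter"], table["value"]))
    transfers = {k: float(v) for k, v in kv.items() if k.startswith("L(")}
    delays = {k: float(v) for k, v in kv.items() if k.startswith("DT(")}
    rbp = {
        k[len("rbp_residence("):-1]: float(v)
        for k, v in kv.items()
        if k.startswith("rbp_residence(")
    }
    diet = kv.get("dietary_intake")
    if diet is not None and (isinstance(diet, float) and math.isnan(diet)):
        diet = None
    return SubjectDeck(
        schema_version=int(float(kv["schema_version"])),
        subject_id=str(kv["subject_id"]),
        plasma_pool=float(kv["plasma_pool"]),
        tbs_assigned=float(kv["tbs_assigned"]),
        absorption_efficiency=float(kv["absorption_efficiency"]),
        transfer_set=transfers,
        delay_times=delays,
        dietary_intake=None if diet is None else float(diet),
        rbp_residence=rbp,
    )
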