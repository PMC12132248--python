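"""Circuit topologies, kinetic parameters, state, and the ODE right-hand side.

The model describes two fluorescent-reporter modules (GFP, RFP) competing for a
shared, finite gene-expression resource pool inside a cell, plus a serine
integrase / excisionase pair that can flip the RFP promoter between its two
orientations:

* ``LR`` orientation — the promoter drives RFP (and, bicistronically,
  excisionase);
* ``BP`` orientation — RFP is off and, in the feedforward variant, the flipped
  promoter reads through toward GFP instead.

Free integrase alone resets flipped promoters back to the LR orientation;
the integrase–excisionase complex flips LR promoters to BP.  Because
excisionase is co-expressed with RFP, high RFP activity produces complex,
flips promoters off, and thereby relieves the resource load RFP places on
GFP — a recombinase-mediated negative feedback.  The feedforward variant
additionally compensates GFP from the flipped promoter.

Resource competition enters as a single lumped pool: every promoter activity
``u`` carries a demand weight ``w``, and all synthesis rates are multiplied by
the shared availability factor ``phi = 1 / (1 + sum(w_i * u_i))``.

Promoter orientation is treated as a continuous mean-field fraction
``P_LR`` in [0, 1] over plasmid copies, so the whole system is a smooth
6-dimensional ODE suitable for deterministic steady-state analysis.
"""

from __future__ import annotations

import enum
import hashlib
import json
import math
from dataclasses import dataclass, fields, replace

import numpy as np

__all__ = [
    "CircuitTopology",
    "CircuitParameters",
    "SystemState",
    "PromoterActivities",
    "hill_activation",
    "promoter_activities",
    "resource_share",
    "ode_rhs",
    "rhs_array",
    "closed_form_fixed_point",
]


class CircuitTopology(str, enum.Enum):
    """The four circuit variants analysed throughout the package.

    NO_CONTROLLER
        Reference circuit without recombinase genes: zero integrase /
        excisionase synthesis and zero recombinase resource weight; the
        promoter never flips.
    OPEN_LOOP_MUT
        Recombinase genes expressed (so their resource load is present) but
        recombination is disabled — the experimental analogue is a central
        dinucleotide mutation in the attR site that blocks re-ligation.  The
        promoter-orientation fraction is pinned at its initial value.
    RE_NF
        Recombinase negative feedback active (flipping on), no feedforward
        read-through toward GFP.
    RE_NF_FF
        Negative feedback plus feedforward: flipped (BP) promoters
        additionally drive GFP with strength ``beta_FF``.
    """

    NO_CONTROLLER = "NO_CONTROLLER"
    OPEN_LOOP_MUT = "OPEN_LOOP_MUT"
    RE_NF = "RE_NF"
    RE_NF_FF = "RE_NF_FF"

    @property
    def expresses_recombinase(self) -> bool:
        return self is not CircuitTopology.NO_CONTROLLER

    @property
    def flipping_active(self) -> bool:
        return self in (CircuitTopology.RE_NF, CircuitTopology.RE_NF_FF)

    @property
    def feedforward_active(self) -> bool:
        return self is CircuitTopology.RE_NF_FF


@dataclass(frozen=True)
class CircuitParameters:
    """Kinetic, resource, and recombinase constants.

    Units: synthesis rates ``k_*`` in a.u. concentration per hour; removal
    rates ``d_*`` in 1/h; ``K_L`` in % w/v L-arabinose; flip rate constants
    ``V_on``/``V_off`` per a.u. of free integrase / complex per hour;
    ``k_on`` in 1/(a.u.·h), ``k_off`` in 1/h; everything else dimensionless.

    ``V_off`` is the negative-feedback strength (LR→BP flipping per unit
    integrase–excisionase complex) and ``d_X`` the excisionase removal rate —
    the two knobs the tuning analyses sweep.  ``copy_gain`` scales all
    synthesis rates to emulate plasmid copy number.
    """

    k_G: float = 100.0
    k_R: float = 100.0
    k_X: float = 50.0
    k_I: float = 10.0
    d_G: float = 1.0
    d_R: float = 1.0
    d_X: float = 1.0
    d_I: float = 1.0
    d_C: float = 1.0
    K_L: float = 6.25e-4
    n_H: float = 2.0
    leak: float = 0.0
    w_G: float = 1.0
    w_R: float = 1.0
    w_I: float = 0.2
    V_on: float = 1.0
    V_off: float = 0.75
    k_on: float = 10.0
    k_off: float = 1.0
    beta_FF: float = 1.0
    copy_gain: float = 1.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {f.name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"parameter {f.name} must be >= 0, got {v!r}")
        for name in ("d_G", "d_R", "d_X", "d_I", "d_C"):
            if getattr(self, name) <= 0:
                raise ValueError(f"removal rate {name} must be > 0")
        if self.n_H < 1:
            raise ValueError("Hill coefficient n_H must be >= 1")
        if not 0 <= self.leak < 1:
            raise ValueError("leak must lie in [0, 1)")
        if self.copy_gain <= 0:
            raise ValueError("copy_gain must be > 0")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "CircuitParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter name(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))

    def with_value(self, name: str, value: float) -> "CircuitParameters":
        if name not in self.field_names():
            raise ValueError(f"unknown parameter field {name!r}")
        return replace(self, **{name: value})

    @property
    def digest(self) -> str:
        """Short opaque identifier of this parameterization."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


@dataclass
class SystemState:
    """Concentrations (a.u.) plus the LR-orientation promoter fraction.

    ``P_LR`` is the fraction of promoters in the RFP-driving (LR)
    orientation; ``1 - P_LR`` is the flipped (BP) fraction.
    """

    G: float = 0.0
    R: float = 0.0
    X: float = 0.0
    I: float = 0.0
    C: float = 0.0
    P_LR: float = 1.0

    def validate(self) -> None:
        arr = self.to_array()
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite state entries: {self}")
        if min(self.G, self.R, self.X, self.I, self.C) < 0:
            raise ValueError(f"negative concentration in state: {self}")
        if not 0.0 <= self.P_LR <= 1.0:
            raise ValueError(f"P_LR outside [0, 1]: {self.P_LR}")

    def to_array(self) -> np.ndarray:
        return np.array([self.G, self.R, self.X, self.I, self.C, self.P_LR])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "SystemState":
        return cls(*(float(v) for v in y))


@dataclass(frozen=True)
class PromoterActivities:
    """Dimensionless promoter activities of the GFP, RFP, and integrase genes."""

    u_G: float
    u_R: float
    u_I: float


def hill_activation(dose: float, params: CircuitParameters) -> float:
    """Inducer (L-arabinose) activation of the Pbad promoter.

    ``leak + (1 - leak) * dose^n / (K_L^n + dose^n)``; lies in
    ``[leak, 1)`` and is non-decreasing in dose.
    """
    if not math.isfinite(dose) or dose < 0:
        raise ValueError(f"inducer dose must be finite and >= 0, got {dose!r}")
    if dose == 0.0:
        return params.leak
    x = (dose / params.K_L) ** params.n_H
    return params.leak + (1.0 - params.leak) * x / (1.0 + x)


def promoter_activities(
    state: SystemState,
    dose: float,
    params: CircuitParameters,
    topology: CircuitTopology,
) -> PromoterActivities:
    """Promoter activities given the current orientation fraction.

    RFP is driven only by LR-oriented promoters (``u_R = hill * P_LR``).
    In the feedforward topology the flipped fraction reads through toward
    GFP: ``u_G = 1 + beta_FF * hill * (1 - P_LR)``; otherwise GFP is purely
    constitutive (``u_G = 1``).  The integrase promoter is constitutive
    (``u_I = 1``) whenever recombinase genes are present.
    """
    h = hill_activation(dose, params)
    u_R = h * state.P_LR
    if topology.feedforward_active:
        u_G = 1.0 + params.beta_FF * h * (1.0 - state.P_LR)
    else:
        u_G = 1.0
    u_I = 1.0 if topology.expresses_recombinase else 0.0
    return PromoterActivities(u_G=u_G, u_R=u_R, u_I=u_I)


def resource_share(acts: PromoterActivities, params: CircuitParameters) -> float:
    """Fraction of the shared expression-resource pool available per promoter.

    ``phi = 1 / (1 + w_G*u_G + w_R*u_R + w_I*u_I)``, in (0, 1], strictly
    decreasing in each weighted demand.
    """
    load = params.w_G * acts.u_G + params.w_R * acts.u_R + params.w_I * acts.u_I
    return 1.0 / (1.0 + load)


def rhs_array(
    y: np.ndarray,
    dose: float,
    params: CircuitParameters,
    topology: CircuitTopology,
) -> np.ndarray:
    """Time derivative of ``[G, R, X, I, C, P_LR]`` (array fast path).

    State order matches :meth:`SystemState.to_array`.  Topology reductions
    are applied bit-exactly: the feedforward term is dropped unless the
    topology has it, recombinase synthesis is zeroed for ``NO_CONTROLLER``,
    and ``dP_LR`` is forced to zero whenever flipping is inactive.
    """
    G, R, X, I, C, P_LR = y
    h = hill_activation(dose, params)

    u_R = h * P_LR
    if topology.feedforward_active:
        u_G = 1.0 + params.beta_FF * h * (1.0 - P_LR)
    else:
        u_G = 1.0
    if topology.expresses_recombinase:
        u_I, k_X, k_I, w_I = 1.0, params.k_X, params.k_I, params.w_I
    else:
        u_I = k_X = k_I = w_I = 0.0

    phi = 1.0 / (1.0 + params.w_G * u_G + params.w_R * u_R + w_I * u_I)
    cg = params.copy_gain
    assoc = params.k_on * X * I
    dissoc = params.k_off * C

    dG = cg * params.k_G * u_G * phi - params.d_G * G
    dR = cg * params.k_R * u_R * phi - params.d_R * R
    dX = cg * k_X * u_R * phi - params.d_X * X - assoc + dissoc
    dI = cg * k_I * u_I * phi - params.d_I * I - assoc + dissoc
    dC = assoc - (params.k_off + params.d_C) * C
    if topology.flipping_active:
        dP = params.V_on * I * (1.0 - P_LR) - params.V_off * C * P_LR
    else:
        dP = 0.0
    return np.array([dG, dR, dX, dI, dC, dP])


def ode_rhs(
    state: SystemState,
    dose: float,
    params: CircuitParameters,
    topology: CircuitTopology,
) -> SystemState:
    """Time derivative of the system state (see :func:`rhs_array`).

    The vector field leaves the invariant box forward-invariant: every
    concentration derivative is non-negative on its zero boundary and the
    orientation fraction cannot leave [0, 1].
    """
    y = state.to_array()
    if not np.all(np.isfinite(y)):
        raise ValueError(f"non-finite state entries: {state}")
    return SystemState.from_array(rhs_array(y, dose, params, topology))


def closed_form_fixed_point(
    params: CircuitParameters,
    topology: CircuitTopology,
    dose: float,
    P_LR: float = 1.0,
) -> SystemState:
    """Analytic fixed point in the decoupled limit.

    Valid only when all resource weights are zero (``phi = 1``), complex
    chemistry is off (``k_on = 0``) and flipping is inactive (non-flipping
    topology or ``V_on = V_off = 0``); then every species settles at
    ``copy_gain * k * u / d`` and the complex at zero.

    Raises ``ValueError`` if called outside that regime.
    """
    if params.w_G or params.w_R or params.w_I:
        raise ValueError("closed form requires all resource weights = 0")
    if params.k_on != 0:
        raise ValueError("closed form requires k_on = 0 (no complex formation)")
    if topology.flipping_active and (params.V_on or params.V_off):
        raise ValueError("closed form requires flipping off (V_on = V_off = 0)")
    ref = SystemState(P_LR=P_LR)
    acts = promoter_activities(ref, dose, params, topology)
    cg = params.copy_gain
    k_X = params.k_X if topology.expresses_recombinase else 0.0
    k_I = params.k_I if topology.expresses_recombinase else 0.0
    return SystemState(
        G=cg * params.k_G * acts.u_G / params.d_G,
        R=cg * params.k_R * acts.u_R / params.d_R,
        X=cg * k_X * acts.u_R / params.d_X,
        I=cg * k_I * acts.u_I / params.d_I,
        C=0.0,
        P_LR=P_LR,
    )
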