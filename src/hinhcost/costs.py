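"""Deterministic annual net-cost model for the Hospital in the Nursing Home (HiNH) program.

The model compares one year of running an ED-nurse-led outreach program for
residential aged care facility (RACF) patients against current practice.  Net
cost is

    C = A + B

where ``A`` is the annual program cost (staffing plus non-staff running costs)
and ``B`` values the changes in acute hospital utilisation attributable to the
program:

    B = [(e*c + a*g)*k + (f*d + b*h)*l + (e*i)*m] * j * 12

with the utilisation parameters ``a``-``m`` defined on :class:`ParameterSet`.
A negative ``C`` means the program is cost-saving to the health service
provider.  All monetary values are Australian dollars per annum.

Every arithmetic routine accepts either scalar parameters or NumPy arrays of
equal length, so the probabilistic sensitivity analysis can evaluate the whole
ledger on a vector of sampled parameter sets in one call.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

MONTHS_PER_YEAR = 12

__all__ = [
    "ParameterSet",
    "CostBreakdown",
    "annualize_equipment",
    "program_costs",
    "utilisation_costs",
    "net_cost",
]


def _as_float(x):
    """Pass arrays through; collapse python/numpy scalars to float."""
    arr = np.asarray(x, dtype=float)
    return float(arr) if arr.ndim == 0 else arr


@dataclass(frozen=True)
class ParameterSet:
    """Full parameter vector of the cost analysis.

    Program-cost items (AU$/year unless noted)
    ------------------------------------------
    hinh_staff : program nursing staff salaries including on-costs
    in_kind : time in kind from other health professionals
    travel, admin_training, stationery, telephone, office_space : running costs
    equipment_price : purchase price of program equipment (AU$, capital)
    equipment_life : useful life of the equipment in years
    discount_rate : annual discount rate used to annuitize the equipment

    Utilisation parameters
    ----------------------
    a : ED presentations per 1,000 RACF beds per month (without intervention)
    b : inpatient admissions via ED per 1,000 RACF beds per month
    c : ED length of stay per presentation, hours
    d : inpatient length of stay per admission, hours
    e : change in ED presentation rate attributable to the program
    f : change in admission rate
    g : change in ED LOS per presentation, hours
    h : change in inpatient LOS per admission, hours
    i : fraction of ED presentations arriving by ambulance (0-1)
    j : RACF beds in the catchment, in thousands of beds

    Unit costs (AU$)
    ----------------
    k : ED cost per bed-hour
    l : inpatient cost per bed-hour
    m : ambulance cost per incident
    """

    hinh_staff: float
    in_kind: float
    travel: float
    admin_training: float
    stationery: float
    telephone: float
    equipment_price: float
    office_space: float
    equipment_life: float
    discount_rate: float
    a: float
    b: float
    c: float
    d: float
    e: float
    f: float
    g: float
    h: float
    i: float
    j: float
    k: float
    l: float
    m: float

    _PROGRAM_ITEMS = (
        "hinh_staff",
        "in_kind",
        "travel",
        "admin_training",
        "stationery",
        "telephone",
        "equipment_price",
        "office_space",
    )
    _STRICTLY_POSITIVE = ("a", "b", "c", "d", "j", "k", "l", "m")

    def __post_init__(self):
        for name in self._PROGRAM_ITEMS:
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"program cost item {name!r} must be non-negative")
        for name in self._STRICTLY_POSITIVE:
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"parameter {name!r} must be strictly positive")
        if np.any(np.asarray(self.i) < 0) or np.any(np.asarray(self.i) > 1):
            raise ValueError("ambulance fraction 'i' must lie in [0, 1]")
        if np.any(np.asarray(self.discount_rate) < 0):
            raise ValueError("discount_rate must be non-negative")
        if np.any(np.asarray(self.equipment_life) < 0):
            raise ValueError("equipment_life must be non-negative")

    def replace(self, **changes) -> "ParameterSet":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class CostBreakdown:
    """Ledger of annual costs and savings (AU$/year, negative = saving).

    Identities ``A = A1 + A2``, ``B1 = B1a + B1b``, ``B2 = B2a + B2b``,
    ``B = B1 + B2 + B3`` and ``C = A + B`` hold exactly by construction.
    """

    A1: float  # staffing subtotal
    A2: float  # non-staff subtotal (equipment annuitized)
    A: float  # program cost subtotal
    B1a: float  # avoided ED presentation bed-hours      (e*c*k)*j*12
    B1b: float  # shortened ED presentation bed-hours    (a*g*k)*j*12
    B1: float
    B2a: float  # avoided inpatient admission bed-hours  (f*d*l)*j*12
    B2b: float  # shortened inpatient stay bed-hours     (b*h*l)*j*12
    B2: float
    B3: float  # ambulance transports                    (e*i*m)*j*12
    B: float  # utilisation subtotal
    C: float  # net cost

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def annualize_equipment(price, life, rate):
    """Equivalent annual cost of a capital purchase.

    Spreads ``price`` over ``life`` years using the annuity factor
    ``AF(L, r) = (1 - (1+r)^-L) / r`` (``AF = L`` when ``r = 0``).  Lives
    below one year are clamped to one year: the deterministic base case
    treats the equipment as bought and discarded within the year, which is
    the worst-cost assumption, and it keeps the sensitivity range for the
    life parameter (which starts at zero) well defined.
    """
    price = np.asarray(price, dtype=float)
    life = np.asarray(life, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if np.any(price < 0):
        raise ValueError("equipment price must be non-negative")
    if np.any(life < 0):
        raise ValueError("equipment life must be non-negative")
    if np.any(rate < 0):
        raise ValueError("discount rate must be non-negative")
    clamped = np.maximum(life, 1.0)
    safe_rate = np.where(rate > 0, rate, 1.0)
    # -expm1(-L*log1p(r))/r is the annuity factor written to stay accurate
    # as r -> 0+, where the naive form cancels catastrophically
    factor = np.where(
        rate > 0,
        -np.expm1(-clamped * np.log1p(safe_rate)) / safe_rate,
        clamped,
    )
    return _as_float(price / factor)


def program_costs(params: ParameterSet):
    """Annual program cost: ``(A1, A2, A)``.

    A1 sums the staffing items; A2 sums the non-staff running costs with the
    equipment entered at its equivalent annual cost.
    """
    p = params
    A1 = p.hinh_staff + p.in_kind
    A2 = (
        p.travel
        + p.admin_training
        + p.stationery
        + p.telephone
        + p.office_space
        + annualize_equipment(p.equipment_price, p.equipment_life, p.discount_rate)
    )
    return _as_float(A1), _as_float(A2), _as_float(A1 + A2)


def utilisation_costs(params: ParameterSet):
    """Annual utilisation cost differences: ``(B1a, B1b, B2a, B2b, B3, B)``.

    Each component is a (rate or LOS change) x (volume) x (unit cost) product
    scaled to the catchment (``j`` thousand beds) and to a full year.
    """
    p = params
    scale = p.j * MONTHS_PER_YEAR
    B1a = p.e * p.c * p.k * scale
    B1b = p.a * p.g * p.k * scale
    B2a = p.f * p.d * p.l * scale
    B2b = p.b * p.h * p.l * scale
    B3 = p.e * p.i * p.m * scale
    B = B1a + B1b + B2a + B2b + B3
    return tuple(_as_float(x) for x in (B1a, B1b, B2a, B2b, B3, B))


def net_cost(params: ParameterSet) -> CostBreakdown:
    """Evaluate the full ledger; ``C < 0`` means the program is cost-saving."""
    A1, A2, A = program_costs(params)
    B1a, B1b, B2a, B2b, B3, _ = utilisation_costs(params)
    # subtotals are summed in ledger order so the identities hold exactly
    B1 = B1a + B1b
    B2 = B2a + B2b
    B = B1 + B2 + B3
    return CostBreakdown(
        A1=A1,
        A2=A2,
        A=A,
        B1a=B1a,
        B1b=B1b,
        B1=_as_float(B1),
        B2a=B2a,
        B2b=B2b,
        B2=_as_float(B2),
        B3=B3,
        B=_as_float(B),
        C=_as_float(A + B),
    )
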