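"""Direct-method binding enthalpy.

ΔH = <E>_complex + <E>_solvent - <E>_receptor - <E>_ligand, computed from
four independent leg simulations whose atom counts must balance exactly
between the bound (complex + solvent) and unbound (receptor + ligand) sides.
The PV contribution is negligible for condensed-phase binding and omitted.
Leg SEMs combine in quadrature (the legs are independent simulations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .io_formats import LEGS, ThermoRecord
from .reblocking import LegEstimate

SPECIES = ("protein", "ligand", "water", "ions")


@dataclass(frozen=True)
class AtomBalanceSheet:
    """Per-leg species counts: {leg: {species: count}}."""

    counts: dict

    def __post_init__(self):
        missing = [leg for leg in LEGS if leg not in self.counts]
        if missing:
            raise ValueError(f"missing leg(s) in atom balance sheet: {missing}")
        for leg, by_species in self.counts.items():
            for species, n in by_species.items():
                if n < 0:
                    raise ValueError(f"negative count for {species} in {leg}")


@dataclass(frozen=True)
class BalanceReport:
    passed: bool
    deficits: dict  # species -> bound-side minus unbound-side count


def check_atom_balance(sheet: AtomBalanceSheet) -> BalanceReport:
    """Pass iff count(complex) + count(solvent) == count(receptor) + count(ligand)
    for every species."""
    species = set()
    for by_species in sheet.counts.values():
        species.update(by_species)
    deficits = {}
    for sp in sorted(species):
        bound = sheet.counts["complex"].get(sp, 0) + sheet.counts["solvent"].get(sp, 0)
        unbound = sheet.counts["receptor"].get(sp, 0) + sheet.counts["ligand"].get(sp, 0)
        if bound != unbound:
            deficits[sp] = bound - unbound
    return BalanceReport(passed=not deficits, deficits=deficits)


@dataclass(frozen=True)
class EnthalpyEstimate:
    """Binding enthalpy with quadrature-propagated SEM (kcal/mol)."""

    dH: float
    sem: float
    legs: dict  # leg -> LegEstimate
    condition: str = "all"  # all | ZA1 | ZA2 | combined
    system_id: str = ""

    def __post_init__(self):
        if not math.isfinite(self.dH):
            raise ValueError("dH must be finite")
        if self.sem < 0:
            raise ValueError("sem must be >= 0")


def combine_legs(*estimates: LegEstimate, condition: str = "all", system_id: str = "") -> EnthalpyEstimate:
    """Combine the four leg estimates into a binding enthalpy.

    Inputs may arrive in any order; each must carry a distinct leg label and
    all four legs must be present.
    """
    by_leg: dict[str, LegEstimate] = {}
    for est in estimates:
        if est.leg in by_leg:
            raise ValueError(f"duplicated leg {est.leg!r}")
        by_leg[est.leg] = est
    missing = [leg for leg in LEGS if leg not in by_leg]
    if missing:
        raise ValueError(f"missing leg(s): {missing}")
    dH = by_leg["complex"].mean + by_leg["solvent"].mean - by_leg["receptor"].mean - by_leg["ligand"].mean
    sem = math.sqrt(sum(by_leg[leg].sem ** 2 for leg in LEGS))
    return EnthalpyEstimate(dH=dH, sem=sem, legs=by_leg, condition=condition, system_id=system_id)


def absolute_deviation(estimate: EnthalpyEstimate, experiment: ThermoRecord) -> float:
    """|dH_estimate - dH_experiment| in kcal/mol for the same system."""
    if estimate.system_id != experiment.system_id:
        raise ValueError(
            f"system_id mismatch: {estimate.system_id!r} vs {experiment.system_id!r}"
        )
    return abs(estimate.dH - experiment.dH)
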