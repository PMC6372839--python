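"""Fermentation carbon accounting.

Each fermentation product's share of the glucose consumed is computed
against the molar potential of its biosynthetic pathway — the maximum
moles of product obtainable per mole of glucose (1 mol glucose yields
2 mol ethanol through the Entner-Doudoroff pathway, 1 mol gluconate by
direct oxidation, and so on). Biomass carbon is estimated from the OD600
gain via a cell-dry-weight conversion (0.41 g CDW per liter per OD600
unit) and a fixed carbon mass fraction (48% of CDW), divided by the
carbon supplied as glucose (72.06 g C per mol, 6 x 12.011). Whatever the
products and biomass do not cover is reported as unaccounted; CO2 is
deliberately excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class BalanceError(ValueError):
    pass


#: mol product per mol glucose by pathway stoichiometry (ED glycolysis
#: yields pyruvate and GAP 1:1; ethanol/acetate/lactate derive 2:1)
DEFAULT_MOLAR_POTENTIALS: dict[str, float] = {
    "ethanol": 2.0,
    "gluconate": 1.0,
    "acetate": 2.0,
    "pyruvate": 2.0,
    "lactate": 2.0,
    "succinate": 1.0,
    "shikimate": 1.0,
}

#: g carbon per mol glucose (6 x 12.011)
GLUCOSE_CARBON_G_PER_MOL = 72.06


@dataclass(frozen=True)
class BiomassParams:
    """Constants converting OD gain to biomass carbon."""

    cdw_per_od: float = 0.41  # g CDW per liter per OD600 unit
    carbon_fraction: float = 0.48  # mass fraction of carbon in CDW
    glucose_carbon: float = GLUCOSE_CARBON_G_PER_MOL

    def __post_init__(self) -> None:
        if not self.cdw_per_od > 0:
            raise BalanceError("cdw_per_od must be positive")
        if not 0 < self.carbon_fraction < 1:
            raise BalanceError("carbon_fraction must lie in (0, 1)")


@dataclass
class CarbonBalanceReport:
    glucose_consumed_mM: float
    products: dict[str, dict[str, float]]  # product -> {mM, potential, percent}
    biomass_percent: float
    unaccounted_percent: float
    flags: list[str] = field(default_factory=list)


def product_percent(
    product_mM: float, glucose_consumed_mM: float, potential: float
) -> float:
    """Percent of consumed glucose carbon captured by one product:
    100 * product / (glucose * potential)."""
    if not glucose_consumed_mM > 0:
        raise BalanceError("glucose consumed must be positive")
    if product_mM < 0:
        raise BalanceError("product concentration must be non-negative")
    if not potential > 0:
        raise BalanceError("molar potential must be positive")
    return 100.0 * product_mM / (glucose_consumed_mM * potential)


def biomass_percent(
    od600_gain: float,
    volume_l: float,
    glucose_consumed_mol: float,
    params: BiomassParams = BiomassParams(),
) -> float:
    """Percent of consumed glucose carbon fixed as biomass, from the
    final-minus-initial OD gain."""
    if od600_gain < 0 or volume_l < 0:
        raise BalanceError("od600_gain and volume must be non-negative")
    if not glucose_consumed_mol > 0:
        raise BalanceError("glucose consumed must be positive")
    carbon_g = od600_gain * volume_l * params.cdw_per_od * params.carbon_fraction
    return 100.0 * carbon_g / (glucose_consumed_mol * params.glucose_carbon)


def balance_report(
    products: dict[str, float],
    glucose_consumed_mM: float,
    od600_gain: float = 0.0,
    volume_l: float = 1.0,
    potentials: dict[str, float] | None = None,
    params: BiomassParams = BiomassParams(),
) -> CarbonBalanceReport:
    """Full accounting: per-product percents (every product listed, even
    below 0.1%), biomass percent, and the unaccounted remainder
    100 - sum. A negative remainder flags ``overclosure``."""
    potentials = DEFAULT_MOLAR_POTENTIALS if potentials is None else potentials
    unknown = sorted(set(products) - set(potentials))
    if unknown:
        raise BalanceError(f"no molar potential for product(s): {unknown}")
    entries = {}
    total = 0.0
    for name in sorted(products):
        pct = product_percent(products[name], glucose_consumed_mM, potentials[name])
        entries[name] = {
            "mM": products[name],
            "potential": potentials[name],
            "percent": pct,
        }
        total += pct
    bm = biomass_percent(
        od600_gain, volume_l, glucose_consumed_mM / 1000.0 * volume_l, params
    ) if od600_gain > 0 else 0.0
    unaccounted = 100.0 - total - bm
    flags = ["overclosure"] if unaccounted < 0 else []
    return CarbonBalanceReport(
        glucose_consumed_mM=glucose_consumed_mM,
        products=entries,
        biomass_percent=bm,
        unaccounted_percent=unaccounted,
        flags=flags,
    )
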