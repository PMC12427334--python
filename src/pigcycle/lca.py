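"""Cradle-to-farm-gate carbon footprint for pig production.

The system boundary covers feed production (cultivation + processing +
transport), farm energy use, enteric fermentation and manure management;
the functional unit is kg CO2-eq per kg of live pig leaving the gate.
Totals are the plain sum of five linear components:

    CF_T = CF_forage + CF_transport + CF_enteric + CF_energy + CF_manure
    CF   = CF_T / W_live

Gases are aggregated with 100-year global warming potentials (CO2 = 1,
CH4 = 28, N2O = 298).  Nitrous-oxide flows are tracked as N2O-N and
converted to N2O mass with the molecular ratio 44/28 before the GWP is
applied.  Every component is degree-1 homogeneous in its activity data,
so footprints of merged ledgers add exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "EmissionFactorSet",
    "ActivityLedger",
    "TransportLeg",
    "BreedInventory",
    "ManureRecord",
    "FootprintBreakdown",
    "cf_forage",
    "cf_transport",
    "enteric_factor",
    "cf_enteric",
    "cf_energy",
    "cf_manure",
    "total_footprint",
    "n2o_from_applied_n",
    "sem",
]

N2O_N_TO_N2O = 44.0 / 28.0

# Direct N2O emission factors by manure management system (kg N2O-N per kg
# managed N).
MANURE_SYSTEM_N2O_FACTORS = {
    "Open Lagoon": 0.0,
    "Indoor Storage": 0.002,
    "Solid Storage": 0.005,
    "Liquid/Slurry (Natural Crust)": 0.005,
    "Liquid/Slurry (No Natural Crust)": 0.0,
    "Anaerobic Digester": 0.0,
    "Aerobic Treatment (Natural Vent.)": 0.01,
    "Aerobic Treatment (Forced Vent.)": 0.005,
    "Composting (Container)": 0.006,
    "Composting (Intensive Turned)": 0.1,
    "Composting (Passive Stack)": 0.01,
}


class UnitError(ValueError):
    """Raised when an emission-factor set fails its dimension audit."""


@dataclass(frozen=True)
class EmissionFactorSet:
    """Emission factors with their units pinned in field names.

    Defaults are the IPCC-2019-style set for a Chinese fattening unit:
    per-kg feed carbon intensities, fertilizer/pesticide/film production
    factors, N2O pathways from applied and managed nitrogen, energy
    carrier factors, per-tonne-km transport factors and a live-weight
    scaled enteric methane factor referenced to a 105 kg market pig.
    """

    gwp: Mapping[str, float] = field(
        default_factory=lambda: {"CO2": 1.0, "CH4": 28.0, "N2O": 298.0}
    )
    # aggregate feed chain intensities, kg CO2-eq per kg feed
    feed_cf_per_kg: Mapping[str, float] = field(
        default_factory=lambda: {
            "corn": 0.37,
            "soybean_meal": 0.11,
            "wheat_bran": 0.26,
            "compound_and_other": 0.37,
        }
    )
    # fertilizer production, t CO2-eq per t nutrient
    fertilizer_production: Mapping[str, float] = field(
        default_factory=lambda: {"N": 2.12, "P": 0.64, "K": 0.18}
    )
    n2o_direct_factor: float = 0.01        # t N2O-N per t applied N
    n2o_indirect_factor: float = 0.003     # t N2O-N per t volatilised N
    volatilization_rate_cultivation: float = 0.05  # t volatile N per t applied N
    urea_co2: float = 0.02                 # t CO2 per t urea
    pesticide_cf: float = 12.44            # t CO2-eq per t
    film_cf: float = 22.72                 # t CO2-eq per t
    irrigation_kwh_per_ha: Mapping[str, float] = field(
        default_factory=lambda: {"corn": 368.7, "soybean": 38.7, "wheat": 839.4}
    )
    fuel_l_per_ha: Mapping[str, float] = field(
        default_factory=lambda: {"corn": 67.85, "soybean": 45.96, "wheat": 78.8}
    )
    # energy carriers: electricity t CO2-eq/MWh, coal and diesel t CO2-eq/t
    energy_cf: Mapping[str, float] = field(
        default_factory=lambda: {"electricity": 0.88, "coal": 2.05, "diesel": 3.18}
    )
    byproduct_energy_mj_per_kg: Mapping[str, float] = field(
        default_factory=lambda: {"soybean_meal": 13.82, "wheat_bran": 4.15}
    )
    # kg CO2-eq per tonne-km by vehicle class
    transport_ef: Mapping[str, float] = field(
        default_factory=lambda: {"light": 0.185, "medium": 0.197, "heavy": 0.321}
    )
    enteric_baseline: float = 1.00         # kg CH4 per head per year at reference weight
    reference_weight: float = 105.0        # kg, market pig
    manure_ch4_factor: float = 0.005       # kg CH4 per kg managed N (upper end of 0-0.005)
    manure_n2o_direct_by_system: Mapping[str, float] = field(
        default_factory=lambda: dict(MANURE_SYSTEM_N2O_FACTORS)
    )
    volatilization_rate_manure: float = 0.01  # kg volatile N per kg managed N
    leaching_rate_manure: float = 0.05        # kg leached N per kg managed N
    leaching_n2o_factor: float = 0.0075       # kg N2O-N per kg leached N
    diesel_density_kg_per_l: float = 0.84
    strict_printed_manure_gwp: bool = False   # apply N2O GWP to the manure CH4 term

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Dimension/sign audit; a malformed factor set is a hard error."""
        for name in ("CO2", "CH4", "N2O"):
            if name not in self.gwp:
                raise UnitError(f"gwp missing {name}")
        scalar_fields = {
            "n2o_direct_factor": self.n2o_direct_factor,
            "n2o_indirect_factor": self.n2o_indirect_factor,
            "volatilization_rate_cultivation": self.volatilization_rate_cultivation,
            "urea_co2": self.urea_co2,
            "pesticide_cf": self.pesticide_cf,
            "film_cf": self.film_cf,
            "enteric_baseline": self.enteric_baseline,
            "reference_weight": self.reference_weight,
            "manure_ch4_factor": self.manure_ch4_factor,
            "volatilization_rate_manure": self.volatilization_rate_manure,
            "leaching_rate_manure": self.leaching_rate_manure,
            "leaching_n2o_factor": self.leaching_n2o_factor,
        }
        for name, value in scalar_fields.items():
            if value < 0:
                raise UnitError(f"{name} must be >= 0, got {value}")
        if self.reference_weight <= 0:
            raise UnitError("reference_weight must be positive")
        for rate_name in ("volatilization_rate_cultivation", "volatilization_rate_manure",
                          "leaching_rate_manure"):
            if getattr(self, rate_name) > 1:
                raise UnitError(f"{rate_name} is a fraction; got > 1")
        for mapping_name in ("feed_cf_per_kg", "energy_cf", "transport_ef",
                             "manure_n2o_direct_by_system", "fertilizer_production"):
            for key, value in getattr(self, mapping_name).items():
                if value < 0:
                    raise UnitError(f"{mapping_name}[{key}] must be >= 0, got {value}")
        if self.energy_cf.get("electricity", 0) > 5:
            raise UnitError("energy_cf['electricity'] looks like kg/MWh; expected t CO2-eq/MWh")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EmissionFactorSet":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# ledger containers


@dataclass(frozen=True)
class TransportLeg:
    distance_km: float
    tonnes: float
    vehicle_class: str

    def __post_init__(self) -> None:
        if self.distance_km < 0 or self.tonnes < 0:
            raise ValueError("transport distance and tonnage must be >= 0")


@dataclass(frozen=True)
class BreedInventory:
    breed: str
    head: int
    avg_weight_kg: float
    days: float

    def __post_init__(self) -> None:
        if self.head < 0 or self.avg_weight_kg <= 0:
            raise ValueError("head count must be >= 0 and avg weight > 0")
        if self.days < 0:
            raise ValueError("days on farm must be >= 0")


@dataclass(frozen=True)
class ManureRecord:
    breed: str
    n_managed_kg: float
    system_fractions: Mapping[str, float]
    mass_kg: float = 0.0  # wet manure mass; informational, emissions key off N

    def __post_init__(self) -> None:
        if self.n_managed_kg < 0 or self.mass_kg < 0:
            raise ValueError("managed N and manure mass must be >= 0")
        if not self.system_fractions:
            raise ValueError("management-system fractions must be non-empty")
        total = sum(self.system_fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"management-system fractions sum to {total}, expected 1")


@dataclass
class ActivityLedger:
    """One accounting period of farm activity data."""

    feed_tonnes_by_breed: dict[str, dict[str, float]]
    transport_legs: list[TransportLeg]
    inventory: list[BreedInventory]
    energy_use: dict[str, float]
    manure: list[ManureRecord]
    total_live_weight_kg: float

    def __post_init__(self) -> None:
        for breed, feeds in self.feed_tonnes_by_breed.items():
            for ing, t in feeds.items():
                if t < 0:
                    raise ValueError(f"feed tonnage {breed}/{ing} must be >= 0")
        for carrier, qty in self.energy_use.items():
            if qty < 0:
                raise ValueError(f"energy use {carrier} must be >= 0")
        if self.total_live_weight_kg < 0:
            raise ValueError("total live weight must be >= 0")

    def feed_totals(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for feeds in self.feed_tonnes_by_breed.values():
            for ing, t in feeds.items():
                out[ing] = out.get(ing, 0.0) + t
        return out

    def to_csv_dir(self, out_dir: str | Path) -> None:
        """Serialise the ledger as a directory of plain CSV tables."""
        import pandas as pd

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [
                {"breed": b, "ingredient": ing, "tonnes": t}
                for b, feeds in self.feed_tonnes_by_breed.items()
                for ing, t in feeds.items()
            ]
        ).to_csv(out / "ledger_feed.csv", index=False)
        pd.DataFrame([asdict(l) for l in self.transport_legs]).to_csv(
            out / "ledger_transport.csv", index=False
        )
        pd.DataFrame([asdict(i) for i in self.inventory]).to_csv(
            out / "ledger_inventory.csv", index=False
        )
        pd.DataFrame(
            [{"carrier": c, "quantity": q} for c, q in self.energy_use.items()]
        ).to_csv(out / "ledger_energy.csv", index=False)
        pd.DataFrame(
            [
                {
                    "breed": m.breed,
                    "n_managed_kg": m.n_managed_kg,
                    "mass_kg": m.mass_kg,
                    "system": s,
                    "fraction": f,
                }
                for m in self.manure
                for s, f in m.system_fractions.items()
            ]
        ).to_csv(out / "ledger_manure.csv", index=False)
        (out / "ledger_meta.json").write_text(
            json.dumps({"total_live_weight_kg": self.total_live_weight_kg})
        )

    @classmethod
    def from_csv_dir(cls, in_dir: str | Path) -> "ActivityLedger":
        import pandas as pd

        src = Path(in_dir)
        feed = pd.read_csv(src / "ledger_feed.csv")
        by_breed: dict[str, dict[str, float]] = {}
        for _, row in feed.iterrows():
            by_breed.setdefault(row["breed"], {})[row["ingredient"]] = float(row["tonnes"])
        legs = [
            TransportLeg(**row)
            for row in pd.read_csv(src / "ledger_transport.csv").to_dict("records")
        ]
        inventory = [
            BreedInventory(**row)
            for row in pd.read_csv(src / "ledger_inventory.csv").to_dict("records")
        ]
        energy = {
            row["carrier"]: float(row["quantity"])
            for row in pd.read_csv(src / "ledger_energy.csv").to_dict("records")
        }
        manure_df = pd.read_csv(src / "ledger_manure.csv")
        if "mass_kg" not in manure_df.columns:
            manure_df["mass_kg"] = 0.0
        manure = []
        for (breed, n_kg, mass_kg), grp in manure_df.groupby(
            ["breed", "n_managed_kg", "mass_kg"]
        ):
            manure.append(
                ManureRecord(
                    breed=breed,
                    n_managed_kg=float(n_kg),
                    system_fractions=dict(zip(grp["system"], grp["fraction"])),
                    mass_kg=float(mass_kg),
                )
            )
        meta = json.loads((src / "ledger_meta.json").read_text())
        return cls(
            feed_tonnes_by_breed=by_breed,
            transport_legs=legs,
            inventory=inventory,
            energy_use=energy,
            manure=manure,
            total_live_weight_kg=meta["total_live_weight_kg"],
        )


@dataclass(frozen=True)
class FootprintBreakdown:
    """Component-wise footprint, total and per-kg normalisation (kg CO2-eq)."""

    cf_forage: float
    cf_transport: float
    cf_enteric: float
    cf_energy: float
    cf_manure: float
    live_weight: float

    @property
    def cf_total(self) -> float:
        return self.cf_forage + self.cf_transport + self.cf_enteric + self.cf_energy + self.cf_manure

    @property
    def cf_per_kg(self) -> float:
        return self.cf_total / self.live_weight

    def components(self) -> dict[str, float]:
        return {
            "forage": self.cf_forage,
            "transport": self.cf_transport,
            "enteric": self.cf_enteric,
            "energy": self.cf_energy,
            "manure": self.cf_manure,
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            **{f"cf_{k}_kgco2eq": v for k, v in self.components().items()},
            "cf_total_kgco2eq": self.cf_total,
            "live_weight_kg": self.live_weight,
            "cf_per_kg_live_weight": self.cf_per_kg,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# components (all return kg CO2-eq)


@dataclass(frozen=True)
class DetailedForageParams:
    """Per-crop cultivation inputs for the detailed forage pathway.

    Everything is per hectare except ``yield_t_per_ha`` which converts
    areas to masses; ``process_energy`` maps each feed to energy-carrier
    use per tonne processed; ``product_energy_mj_per_kg`` is the main
    product's energy content for by-product allocation.
    """

    yield_t_per_ha: Mapping[str, float]
    fertilizer_t_per_ha: Mapping[str, Mapping[str, float]]  # crop -> {N, P, K}
    urea_t_per_ha: Mapping[str, float]
    pesticide_t_per_ha: Mapping[str, float]
    film_t_per_ha: Mapping[str, float]
    process_energy_per_t: Mapping[str, Mapping[str, float]]  # feed -> {carrier: qty/t}
    product_energy_mj_per_kg: Mapping[str, float]
    byproduct_share: Mapping[str, float]  # feed -> mass fraction of process output


FEED_CROP = {"corn": "corn", "soybean_meal": "soybean", "wheat_bran": "wheat"}


def n2o_from_applied_n(applied_n_t: float, factors: EmissionFactorSet) -> tuple[float, float]:
    """(direct, indirect) field N2O from applied N, in t CO2-eq.

    Direct: applied N x 0.01 t N2O-N/t N.  Indirect: applied N x
    volatilisation rate x 0.003 t N2O-N/t volatile N.  Both converted to
    N2O mass by 44/28 and weighted by the N2O GWP.
    """
    gwp = factors.gwp["N2O"]
    direct = applied_n_t * factors.n2o_direct_factor * N2O_N_TO_N2O * gwp
    indirect = (
        applied_n_t
        * factors.volatilization_rate_cultivation
        * factors.n2o_indirect_factor
        * N2O_N_TO_N2O
        * gwp
    )
    return direct, indirect


def cf_forage(
    ledger: ActivityLedger,
    factors: EmissionFactorSet,
    mode: str = "aggregate",
    detailed: DetailedForageParams | None = None,
) -> float:
    """Feed-chain emissions (cultivation + processing), kg CO2-eq.

    ``aggregate`` multiplies each ingredient mass by its per-kg chain
    factor.  ``detailed`` rebuilds cultivation from per-hectare inputs
    (fertilizer production, field N2O, urea, pesticide, film, irrigation
    electricity, machinery diesel) plus processing energy, with
    by-product emissions allocated by energy content.
    """
    totals = ledger.feed_totals()
    if mode == "aggregate":
        out = 0.0
        for ing, tonnes in totals.items():
            if ing not in factors.feed_cf_per_kg:
                raise KeyError(
                    f"no feed factor for '{ing}'; known: {sorted(factors.feed_cf_per_kg)}"
                )
            out += tonnes * 1000.0 * factors.feed_cf_per_kg[ing]
        return out
    if mode != "detailed":
        raise ValueError("mode must be 'aggregate' or 'detailed'")
    if detailed is None:
        raise ValueError("detailed mode requires DetailedForageParams (missing: yields per crop)")

    total_t_co2 = 0.0
    for ing, tonnes in totals.items():
        crop = FEED_CROP.get(ing)
        if crop is None:
            continue  # compound feeds have no crop pathway; covered by aggregate factors
        if crop not in detailed.yield_t_per_ha:
            raise ValueError(f"detailed mode: missing yield_t_per_ha['{crop}']")
        ha = tonnes / detailed.yield_t_per_ha[crop]
        cult = 0.0
        fert = detailed.fertilizer_t_per_ha.get(crop, {})
        for nutrient, t_per_ha in fert.items():
            cult += ha * t_per_ha * factors.fertilizer_production[nutrient]
        n_applied = ha * fert.get("N", 0.0)
        direct, indirect = n2o_from_applied_n(n_applied, factors)
        cult += direct + indirect
        cult += ha * detailed.urea_t_per_ha.get(crop, 0.0) * factors.urea_co2
        cult += ha * detailed.pesticide_t_per_ha.get(crop, 0.0) * factors.pesticide_cf
        cult += ha * detailed.film_t_per_ha.get(crop, 0.0) * factors.film_cf
        cult += (
            ha * factors.irrigation_kwh_per_ha[crop] / 1000.0 * factors.energy_cf["electricity"]
        )
        diesel_t = ha * factors.fuel_l_per_ha[crop] * factors.diesel_density_kg_per_l / 1000.0
        cult += diesel_t * factors.energy_cf["diesel"]

        proc = 0.0
        for carrier, qty_per_t in detailed.process_energy_per_t.get(ing, {}).items():
            if carrier not in factors.energy_cf:
                raise KeyError(f"unknown energy carrier '{carrier}'")
            proc += tonnes * qty_per_t * factors.energy_cf[carrier]

        # energy allocation: share of process emissions carried by this feed
        # when it is a by-product of the crop's main output
        if ing in factors.byproduct_energy_mj_per_kg and ing in detailed.byproduct_share:
            share = detailed.byproduct_share[ing]
            e_by = factors.byproduct_energy_mj_per_kg[ing] * share
            e_main = detailed.product_energy_mj_per_kg.get(ing, 0.0) * (1 - share)
            alloc = e_by / (e_by + e_main) if (e_by + e_main) > 0 else 1.0
            cult *= alloc
            proc *= alloc
        total_t_co2 += cult + proc
    return total_t_co2 * 1000.0


def cf_transport(ledger: ActivityLedger, factors: EmissionFactorSet) -> float:
    """Transport emissions: sum over legs of distance x tonnage x class EF.

    The class factor is interpreted per tonne-km, the only dimensionally
    coherent reading of a distance x tonnage product.
    """
    out = 0.0
    for leg in ledger.transport_legs:
        if leg.vehicle_class not in factors.transport_ef:
            raise KeyError(
                f"unknown vehicle class '{leg.vehicle_class}'; "
                f"valid: {sorted(factors.transport_ef)}"
            )
        out += leg.distance_km * leg.tonnes * factors.transport_ef[leg.vehicle_class]
    return out


def enteric_factor(avg_weight: float, factors: EmissionFactorSet) -> float:
    """Live-weight scaled enteric methane factor, kg CH4/head/year.

    The baseline factor applies to a reference market pig (105 kg); a
    breed's factor scales linearly with its average body weight.
    """
    if avg_weight <= 0:
        raise ValueError("average weight must be positive")
    return factors.enteric_baseline * avg_weight / factors.reference_weight


def cf_enteric(inventory: list[BreedInventory], factors: EmissionFactorSet) -> float:
    """Enteric fermentation emissions, kg CO2-eq, prorated by days on farm."""
    out = 0.0
    for group in inventory:
        out += (
            enteric_factor(group.avg_weight_kg, factors)
            * group.head
            * factors.gwp["CH4"]
            * group.days
            / 365.0
        )
    return out


def cf_energy(ledger: ActivityLedger, factors: EmissionFactorSet) -> float:
    """Farm energy emissions: consumption x carrier factor, kg CO2-eq.

    Electricity is metered in MWh, coal and diesel in tonnes; all carrier
    factors are t CO2-eq per unit.
    """
    out = 0.0
    for carrier, qty in ledger.energy_use.items():
        if carrier not in factors.energy_cf:
            raise KeyError(
                f"unknown energy carrier '{carrier}'; valid: {sorted(factors.energy_cf)}"
            )
        out += qty * factors.energy_cf[carrier] * 1000.0
    return out


def cf_manure(manure: list[ManureRecord], factors: EmissionFactorSet) -> float:
    """Manure management emissions (CH4 + direct and indirect N2O), kg CO2-eq.

    CH4: managed N x CH4-per-N factor x GWP_CH4.  Direct N2O: managed N
    split over management systems, each with its own N2O-N factor.
    Indirect N2O: volatilisation and leaching pathways.  All N2O-N flows
    are converted by 44/28 before the GWP weighting.
    """
    ch4_gwp = factors.gwp["N2O"] if factors.strict_printed_manure_gwp else factors.gwp["CH4"]
    n2o_gwp = factors.gwp["N2O"]
    out = 0.0
    for rec in manure:
        out += rec.n_managed_kg * factors.manure_ch4_factor * ch4_gwp
        direct_n2o_n = 0.0
        for system, frac in rec.system_fractions.items():
            if system not in factors.manure_n2o_direct_by_system:
                raise KeyError(
                    f"unknown manure system '{system}'; "
                    f"valid: {sorted(factors.manure_n2o_direct_by_system)}"
                )
            direct_n2o_n += rec.n_managed_kg * frac * factors.manure_n2o_direct_by_system[system]
        indirect_n2o_n = rec.n_managed_kg * (
            factors.volatilization_rate_manure * factors.n2o_indirect_factor
            + factors.leaching_rate_manure * factors.leaching_n2o_factor
        )
        out += (direct_n2o_n + indirect_n2o_n) * N2O_N_TO_N2O * n2o_gwp
    return out


def total_footprint(
    cf_forage_kg: float,
    cf_transport_kg: float,
    cf_enteric_kg: float,
    cf_energy_kg: float,
    cf_manure_kg: float,
    live_weight: float,
) -> FootprintBreakdown:
    """Assemble the component sums into a normalised breakdown."""
    if live_weight <= 0:
        raise ValueError("live weight must be positive")
    return FootprintBreakdown(
        cf_forage=cf_forage_kg,
        cf_transport=cf_transport_kg,
        cf_enteric=cf_enteric_kg,
        cf_energy=cf_energy_kg,
        cf_manure=cf_manure_kg,
        live_weight=live_weight,
    )


def footprint_from_ledger(
    ledger: ActivityLedger,
    factors: EmissionFactorSet,
    forage_mode: str = "aggregate",
    detailed: DetailedForageParams | None = None,
) -> FootprintBreakdown:
    """Convenience wrapper: all five components from one ledger."""
    return total_footprint(
        cf_forage(ledger, factors, mode=forage_mode, detailed=detailed),
        cf_transport(ledger, factors),
        cf_enteric(ledger.inventory, factors),
        cf_energy(ledger, factors),
        cf_manure(ledger.manure, factors),
        ledger.total_live_weight_kg,
    )


def sem(values) -> float:
    """Standard error of the mean, SD/sqrt(n) (sample SD, ddof=1)."""
    import numpy as np

    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("SEM needs at least two values")
    return float(arr.std(ddof=1) / np.sqrt(arr.size))
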