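"""In-silico seawater medium for the holobiont simulations.

The medium combines deep-sea inorganic chemistry (literature seawater values,
except oxygen which is a site measurement, 6.7 mg/L) with host-derived
organics. Only the ammonium multiplier is anchored by the study (growth of the
ammonia oxidizer needs roughly 20x the ambient deep-sea concentration); the
ambient baseline itself is a configurable default of 1 umol/L, flagged as such
in the provenance. Default organic magnitudes are set from the measured flux
ratios: taurine ~ creatine at a reference level C0 = 10 umol/L, DMSP = C0/15,
betaine = C0/1e4, choline = C0/1e5.

Concentrations are mmol/L keyed by extracellular metabolite id; diffusion
rates are per-cycle grid-mixing fractions in [0, 1] used by the arena.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .symbiont_models import MOLAR_MASS

__all__ = [
    "Medium",
    "MediumSpec",
    "build_seawater_medium",
    "medium_from_measurements",
    "medium_uptake_bounds",
    "ANALYTE_TO_METABOLITE",
    "DEFAULT_AFFINITY",
]

ANALYTE_TO_METABOLITE = {
    "betaine": "bet_e", "choline": "cho_e", "creatine": "crea_e",
    "dmsp": "dmsp_e", "taurine": "taur_e",
}

#: linear transporter affinity kappa (L gDW^-1 h^-1) mapping an ambient
#: concentration C (mmol/L) to a single-cell uptake bound kappa*C
#: (mmol gDW^-1 h^-1) in medium-based growth tests.
DEFAULT_AFFINITY = 2500.0

#: per-cycle 4-neighborhood mixing fraction; macromolecules diffuse slower
_DIFFUSION_DEFAULT = 0.5
_DIFFUSION_SLOW = {"orgmat_e": 0.2}

#: per-cycle first-order environmental loss of dissolved lysate products:
#: the host takes up dissolved organic matter, and cobalamin is chemically
#: labile in oxic seawater. Applied by the arena after diffusion.
_DECAY_DEFAULT = {"b12_e": 0.05, "orgmat_e": 0.05}

_REFERENCE_ORGANIC_C0 = 0.01  # mmol/L, taurine ~ creatine reference level


@dataclass
class Medium:
    """Extracellular pool: concentrations, arena diffusion, provenance."""

    concentrations: dict[str, float] = field(default_factory=dict)
    diffusion_rate: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)
    decay_rate: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for met, conc in self.concentrations.items():
            if conc < 0:
                raise ValueError(f"negative concentration for {met}: {conc}")
        for met, d in self.diffusion_rate.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"diffusion fraction for {met} outside [0,1]: {d}")
        for met, d in self.decay_rate.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"decay fraction for {met} outside [0,1]: {d}")

    def scaled(self, factor: float) -> "Medium":
        return Medium({k: v * factor for k, v in self.concentrations.items()},
                      dict(self.diffusion_rate), dict(self.provenance),
                      dict(self.decay_rate))

    def merged(self, other: "Medium") -> "Medium":
        conc = {**self.concentrations, **other.concentrations}
        diff = {**self.diffusion_rate, **other.diffusion_rate}
        prov = {**self.provenance, **other.provenance}
        decay = {**self.decay_rate, **other.decay_rate}
        return Medium(conc, diff, prov, decay)

    def to_tsv(self) -> str:
        lines = ["metabolite\tconcentration_mmol_per_L\tdiffusion_fraction\t"
                 "decay_fraction\tprovenance"]
        for met in sorted(self.concentrations):
            lines.append(f"{met}\t{self.concentrations[met]!r}\t"
                         f"{self.diffusion_rate.get(met, _DIFFUSION_DEFAULT)!r}\t"
                         f"{self.decay_rate.get(met, 0.0)!r}\t"
                         f"{self.provenance.get(met, '')}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "Medium":
        df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str, keep_default_na=False)
        return cls(
            {r["metabolite"]: float(r["concentration_mmol_per_L"]) for _, r in df.iterrows()},
            {r["metabolite"]: float(r["diffusion_fraction"]) for _, r in df.iterrows()},
            {r["metabolite"]: r["provenance"] for _, r in df.iterrows()},
            {r["metabolite"]: float(r.get("decay_fraction", 0.0))
             for _, r in df.iterrows()},
        )


@dataclass
class MediumSpec:
    """Configuration for the in-silico seawater medium."""

    oxygen_mg_per_L: float = 6.7          # site measurement
    ammonium_baseline: float = 1e-3        # mmol/L ambient deep-sea default
    ammonium_multiplier: float = 20.0      # host-derived enrichment factor
    organics: Mapping[str, float] | str = "default-profile"  # met id -> mmol/L

    def __post_init__(self) -> None:
        if self.ammonium_multiplier <= 0:
            raise ValueError("ammonium_multiplier must be > 0")
        for value in (self.oxygen_mg_per_L, self.ammonium_baseline):
            if value < 0:
                raise ValueError("concentrations must be >= 0")
        if not isinstance(self.organics, str):
            for met, conc in self.organics.items():
                if conc < 0:
                    raise ValueError(f"negative organic concentration for {met}")


def _default_organics() -> dict[str, float]:
    c0 = _REFERENCE_ORGANIC_C0
    return {"taur_e": c0, "crea_e": c0, "dmsp_e": c0 / 15.0,
            "bet_e": c0 / 1e4, "cho_e": c0 / 1e5}


def build_seawater_medium(spec: MediumSpec | None = None) -> Medium:
    """Assemble the full simulation medium from a :class:`MediumSpec`."""
    spec = spec or MediumSpec()
    conc: dict[str, float] = {}
    prov: dict[str, str] = {}

    conc["o2_e"] = spec.oxygen_mg_per_L / MOLAR_MASS["o2"]
    prov["o2_e"] = f"measured at the deep-sea site, {spec.oxygen_mg_per_L} mg/L / 32 g/mol"
    conc["nh4_e"] = spec.ammonium_baseline * spec.ammonium_multiplier
    prov["nh4_e"] = (f"ambient baseline {spec.ammonium_baseline} mmol/L (config "
                     f"default, not a site measurement) x {spec.ammonium_multiplier} "
                     "host-derived enrichment")
    # literature seawater inorganics
    conc["co2_e"] = 2.3
    prov["co2_e"] = "dissolved inorganic carbon, literature seawater value"
    conc["so4_e"] = 28.0
    prov["so4_e"] = "sulfate, literature seawater value"
    conc["po4_e"] = 2e-3
    prov["po4_e"] = "phosphate, literature deep-sea value (not consumed by the models)"

    organics = (_default_organics() if isinstance(spec.organics, str)
                else dict(spec.organics))
    for met, c in organics.items():
        conc[met] = c
        prov.setdefault(met, "synthetic default organic profile (reverse-engineered "
                             "from reported uptake-flux ratios)")

    # tracked but initially absent exchange pools
    for met in ("fum_e", "form_e", "ac_e", "no2_e", "dms_e", "h2o2_e",
                "b12_e", "orgmat_e"):
        conc.setdefault(met, 0.0)
        prov.setdefault(met, "initially absent; produced within the arena")

    diffusion = {met: _DIFFUSION_SLOW.get(met, _DIFFUSION_DEFAULT) for met in conc}
    decay = {met: d for met, d in _DECAY_DEFAULT.items() if met in conc}
    return Medium(conc, diffusion, prov, decay)


def medium_from_measurements(table: pd.DataFrame | str | Path,
                             volume_normalization: float = 1.0) -> Medium:
    """Convert a UHPLC analyte x specimen table (ppb) into medium organics.

    Per-analyte concentration is the mean over specimen columns after unit
    conversion from ppb (ug/L, aqueous density 1 g/mL assumed) to mmol/L using
    the analyte molar mass, scaled by ``volume_normalization``. Provenance
    records the number of specimens and the coefficient of variation.
    """
    if isinstance(table, (str, Path)):
        table = pd.read_csv(table, sep="\t", index_col=0)
    if "clipped" in table.columns:  # generator QC flag, not a specimen
        table = table.drop(columns="clipped")
    if table.shape[1] < 1 or table.shape[0] < 1:
        raise ValueError("measurement table needs >= 1 analyte row and specimen column")
    conc: dict[str, float] = {}
    prov: dict[str, str] = {}
    for analyte, row in table.iterrows():
        key = str(analyte).strip().lower()
        if key not in ANALYTE_TO_METABOLITE:
            raise ValueError(f"unknown analyte {analyte!r}; expected one of "
                             f"{sorted(ANALYTE_TO_METABOLITE)}")
        values = row.astype(float)
        if (values < 0).any():
            raise ValueError(f"negative measurement for analyte {analyte!r}")
        met = ANALYTE_TO_METABOLITE[key]
        token = met[:-2]
        mmol_per_l = values.mean() * 1e-3 / MOLAR_MASS[token] * volume_normalization
        conc[met] = float(mmol_per_l)
        cv = float(values.std(ddof=1) / values.mean()) if len(values) > 1 and values.mean() > 0 else 0.0
        prov[met] = (f"UHPLC quantification, mean of n={len(values)} specimens, "
                     f"cv={cv:.3f}, ppb -> mmol/L via {MOLAR_MASS[token]} g/mol")
    diffusion = {met: _DIFFUSION_SLOW.get(met, _DIFFUSION_DEFAULT) for met in conc}
    return Medium(conc, diffusion, prov)


def medium_uptake_bounds(medium: Medium,
                         affinity: float = DEFAULT_AFFINITY) -> dict[str, float]:
    """Single-cell uptake bounds (mmol gDW^-1 h^-1) for medium-based FBA.

    Uses the linear low-concentration transporter limit u = kappa * C. The
    arena does not use this map; there, uptake is capped by local substrate
    availability instead.
    """
    return {met: affinity * c for met, c in medium.concentrations.items() if c > 0}
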