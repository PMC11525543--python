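"""Compact metabolic-model data structures, validation and serialization.

A :class:`MetabolicModel` is the unit that flux balance analysis operates on:
metabolites (cytosolic or extracellular), stoichiometric reactions with flux
bounds, exactly one biomass pseudo-reaction, and a biomass composition used to
convert lysed biomass back into extracellular metabolites.

Conventions fixed package-wide
------------------------------
* Fluxes are in mmol gDW\ :sup:`-1` h\ :sup:`-1`, concentrations in
  mmol L\ :sup:`-1`, biomass in gDW.
* Exchange reactions are written export-positive: the exchanged extracellular
  metabolite carries coefficient -1, so positive flux secretes it into the
  medium and uptake appears as negative flux.
* Lumped curated reactions may omit elemental formulas; they are exempt from
  elemental balancing but must carry an ``evidence`` note.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ValidationReport",
    "ModelFormatError",
    "parse_formula",
    "validate_model",
    "build_stoichiometric_matrix",
    "load_model",
    "save_model",
    "export_sbml",
    "import_sbml",
]

COMPARTMENTS = ("extracellular", "cytosol")
REACTION_KINDS = ("internal", "exchange", "transport", "biomass")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


class ModelFormatError(ValueError):
    """Raised when a model file cannot be parsed or violates its schema."""


def parse_formula(formula: str) -> dict[str, float]:
    """Parse a Hill-style elemental formula such as ``C2H7NO3S``."""
    if not formula or not re.fullmatch(r"(?:[A-Z][a-z]?\d*\.?\d*)+", formula):
        raise ValueError(f"cannot parse elemental formula {formula!r}")
    counts: dict[str, float] = {}
    for element, num in _FORMULA_TOKEN.findall(formula):
        if element:
            counts[element] = counts.get(element, 0.0) + (float(num) if num else 1.0)
    return counts


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "cytosol"
    elemental_formula: dict[str, float] | None = None
    charge: int | None = None
    molar_mass: float | None = None  # g/mol; required for lysis release accounting

    def __post_init__(self) -> None:
        if isinstance(self.elemental_formula, str):
            self.elemental_formula = parse_formula(self.elemental_formula)


@dataclass
class Reaction:
    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    kind: str = "internal"
    pathway_tag: str = ""
    evidence: str = ""

    def metabolite_ids(self) -> list[str]:
        return list(self.stoichiometry)


@dataclass
class MetabolicModel:
    organism_id: str
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    biomass_reaction_id: str = ""
    biomass_composition: dict[str, float] = field(default_factory=dict)

    # -- lookups ---------------------------------------------------------
    @property
    def metabolites_by_id(self) -> dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    @property
    def reactions_by_id(self) -> dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.kind == "exchange"]

    def exchanged_metabolite(self, reaction: Reaction) -> str:
        """Metabolite id moved by an exchange reaction (must touch exactly one)."""
        mets = reaction.metabolite_ids()
        if reaction.kind != "exchange" or len(mets) != 1:
            raise ValueError(f"{reaction.id} is not a single-metabolite exchange")
        return mets[0]

    def exchange_by_metabolite(self) -> dict[str, Reaction]:
        out: dict[str, Reaction] = {}
        for r in self.exchange_reactions():
            mets = r.metabolite_ids()
            if len(mets) == 1:
                out[mets[0]] = r
        return out

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            organism_id=self.organism_id,
            metabolites=[
                Metabolite(m.id, m.name, m.compartment,
                           dict(m.elemental_formula) if m.elemental_formula else None,
                           m.charge, m.molar_mass)
                for m in self.metabolites
            ],
            reactions=[
                Reaction(r.id, r.name, dict(r.stoichiometry), r.lower_bound,
                         r.upper_bound, r.kind, r.pathway_tag, r.evidence)
                for r in self.reactions
            ],
            biomass_reaction_id=self.biomass_reaction_id,
            biomass_composition=dict(self.biomass_composition),
        )

    def to_dict(self) -> dict:
        return {
            "organism_id": self.organism_id,
            "metabolites": [asdict(m) for m in self.metabolites],
            "reactions": [asdict(r) for r in self.reactions],
            "biomass_reaction_id": self.biomass_reaction_id,
            "biomass_composition": dict(self.biomass_composition),
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "MetabolicModel":
        try:
            model = cls(
                organism_id=data["organism_id"],
                metabolites=[Metabolite(**m) for m in data["metabolites"]],
                reactions=[Reaction(**r) for r in data["reactions"]],
                biomass_reaction_id=data["biomass_reaction_id"],
                biomass_composition=dict(data["biomass_composition"]),
            )
        except (KeyError, TypeError) as exc:
            raise ModelFormatError(f"malformed model document: {exc}") from exc
        _raise_on_duplicates(model)
        return model


@dataclass
class ValidationReport:
    """Violations are data, not exceptions; an empty list means valid."""

    violations: list[str] = field(default_factory=list)
    unchecked: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.violations

    def to_json(self) -> str:
        return json.dumps({"violations": self.violations, "unchecked": self.unchecked},
                          indent=1)


def _raise_on_duplicates(model: MetabolicModel) -> None:
    seen: set[str] = set()
    for m in model.metabolites:
        if m.id in seen:
            raise ModelFormatError(f"duplicate metabolite id {m.id!r}")
        seen.add(m.id)
    seen = set()
    for r in model.reactions:
        if r.id in seen:
            raise ModelFormatError(f"duplicate reaction id {r.id!r}")
        seen.add(r.id)


def validate_model(model: MetabolicModel) -> ValidationReport:
    """Check every structural invariant of the model.

    Elemental balance is checked for internal and transport reactions in which
    all participating metabolites carry formulas; lumped reactions with missing
    formulas are skipped and listed under ``unchecked`` (they must carry an
    evidence note instead).
    """
    rep = ValidationReport()
    mets = model.metabolites_by_id
    if len(mets) != len(model.metabolites):
        rep.violations.append("duplicate metabolite ids")
    rxns = model.reactions_by_id
    if len(rxns) != len(model.reactions):
        rep.violations.append("duplicate reaction ids")

    for m in model.metabolites:
        if m.compartment not in COMPARTMENTS:
            rep.violations.append(
                f"metabolite {m.id}: compartment {m.compartment!r} not in {COMPARTMENTS}")

    n_biomass = 0
    for r in model.reactions:
        if r.kind not in REACTION_KINDS:
            rep.violations.append(f"reaction {r.id}: unknown kind {r.kind!r}")
        if r.lower_bound > r.upper_bound:
            rep.violations.append(
                f"reaction {r.id}: lower_bound {r.lower_bound} > upper_bound {r.upper_bound}")
        unknown = [k for k in r.stoichiometry if k not in mets]
        if unknown:
            rep.violations.append(f"reaction {r.id}: undeclared metabolites {unknown}")
        if r.kind == "biomass":
            n_biomass += 1
        if r.kind == "exchange":
            ext = [k for k in r.stoichiometry
                   if k in mets and mets[k].compartment == "extracellular"]
            if len(r.stoichiometry) != 1 or len(ext) != 1:
                rep.violations.append(
                    f"reaction {r.id}: exchange must touch exactly one extracellular "
                    f"metabolite, touches {sorted(r.stoichiometry)}")
        if r.kind in ("internal", "transport") and not unknown:
            participants = [mets[k] for k in r.stoichiometry]
            if all(p.elemental_formula is not None for p in participants):
                imbalance = _elemental_imbalance(r, mets)
                if imbalance:
                    rep.violations.append(
                        f"reaction {r.id}: elemental imbalance {imbalance}")
            else:
                rep.unchecked.append(r.id)
                if r.kind == "internal" and not r.evidence:
                    rep.violations.append(
                        f"reaction {r.id}: lumped reaction without evidence note")

    if n_biomass != 1:
        rep.violations.append(f"model must have exactly 1 biomass reaction, found {n_biomass}")
    if model.biomass_reaction_id not in rxns:
        rep.violations.append(f"biomass_reaction_id {model.biomass_reaction_id!r} not found")
    elif rxns[model.biomass_reaction_id].kind != "biomass":
        rep.violations.append(
            f"reaction {model.biomass_reaction_id} is not of kind 'biomass'")

    unknown_comp = [k for k in model.biomass_composition if k not in mets]
    if unknown_comp:
        rep.violations.append(f"biomass_composition references unknown metabolites {unknown_comp}")
    total = sum(model.biomass_composition.values())
    if model.biomass_composition and abs(total - 1.0) > 1e-9:
        rep.violations.append(
            f"biomass_composition fractions sum to {total!r}, expected 1 +- 1e-9")
    if any(v < 0 for v in model.biomass_composition.values()):
        rep.violations.append("biomass_composition contains negative fractions")
    return rep


def _elemental_imbalance(reaction: Reaction,
                         mets: Mapping[str, Metabolite]) -> dict[str, float]:
    balance: dict[str, float] = {}
    for met_id, coef in reaction.stoichiometry.items():
        for element, count in (mets[met_id].elemental_formula or {}).items():
            balance[element] = balance.get(element, 0.0) + coef * count
    return {el: round(v, 9) for el, v in balance.items() if abs(v) > 1e-6}


def build_stoichiometric_matrix(model: MetabolicModel) -> pd.DataFrame:
    """Stoichiometric matrix restricted to internal (cytosolic) metabolites.

    Rows are cytosolic metabolite ids, columns reaction ids, entries the signed
    coefficients. The flux-balance module balances extracellular species too;
    this matrix is the steady-state core every optimal flux vector must close.
    """
    if not model.metabolites and not model.reactions:
        return pd.DataFrame()  # degenerate empty model -> 0 x 0 matrix
    report = validate_model(model)
    if not report.valid:
        raise ValueError("invalid model: " + "; ".join(report.violations))
    internal = [m.id for m in model.metabolites if m.compartment == "cytosol"]
    rxn_ids = [r.id for r in model.reactions]
    mat = pd.DataFrame(0.0, index=internal, columns=rxn_ids)
    for r in model.reactions:
        for met_id, coef in r.stoichiometry.items():
            if met_id in mat.index:
                mat.loc[met_id, r.id] = coef
    return mat


# ---------------------------------------------------------------------------
# Native serialization: JSON (canonical) and a TSV reaction-table dialect.
# ---------------------------------------------------------------------------

def save_model(model: MetabolicModel, path: str | Path,
               dialect: str = "native-json") -> None:
    path = Path(path)
    if dialect == "native-json":
        path.write_text(json.dumps(model.to_dict(), indent=1, sort_keys=True) + "\n")
    elif dialect == "native-tsv":
        _save_tsv(model, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def load_model(path: str | Path, dialect: str = "native-json") -> MetabolicModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "native-json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ModelFormatError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}")
        model = MetabolicModel.from_dict(data)
    elif dialect == "native-tsv":
        model = _load_tsv(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    report = validate_model(model)
    if not report.valid:
        raise ModelFormatError(f"{path}: " + "; ".join(report.violations))
    return model


def _stoich_to_text(stoich: Mapping[str, float]) -> str:
    return ";".join(f"{k}:{v!r}" for k, v in sorted(stoich.items()))


def _stoich_from_text(text: str, where: str) -> dict[str, float]:
    out: dict[str, float] = {}
    if not text:
        return out
    for token in text.split(";"):
        try:
            key, val = token.rsplit(":", 1)
            out[key] = float(val)
        except ValueError:
            raise ModelFormatError(f"{where}: cannot parse stoichiometry token {token!r}")
    return out


def _save_tsv(model: MetabolicModel, path: Path) -> None:
    """TSV dialect: three tab-separated tables sharing the path stem."""
    stem = path.with_suffix("")
    met_rows = []
    for m in model.metabolites:
        met_rows.append({
            "id": m.id, "name": m.name, "compartment": m.compartment,
            "elemental_formula": _stoich_to_text(m.elemental_formula or {}),
            "charge": "" if m.charge is None else m.charge,
            "molar_mass": "" if m.molar_mass is None else repr(m.molar_mass),
        })
    pd.DataFrame(met_rows).to_csv(f"{stem}.metabolites.tsv", sep="\t", index=False)
    rxn_rows = []
    for r in model.reactions:
        rxn_rows.append({
            "id": r.id, "name": r.name,
            "stoichiometry": _stoich_to_text(r.stoichiometry),
            "lower_bound": repr(r.lower_bound), "upper_bound": repr(r.upper_bound),
            "kind": r.kind, "pathway_tag": r.pathway_tag, "evidence": r.evidence,
        })
    pd.DataFrame(rxn_rows).to_csv(path, sep="\t", index=False)
    header = {
        "organism_id": model.organism_id,
        "biomass_reaction_id": model.biomass_reaction_id,
        "biomass_composition": dict(model.biomass_composition),
    }
    Path(f"{stem}.header.json").write_text(json.dumps(header, indent=1, sort_keys=True) + "\n")


def _load_tsv(path: Path) -> MetabolicModel:
    stem = path.with_suffix("")
    try:
        header = json.loads(Path(f"{stem}.header.json").read_text())
        met_df = pd.read_csv(f"{stem}.metabolites.tsv", sep="\t",
                             dtype=str, keep_default_na=False)
        rxn_df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError, json.JSONDecodeError) as exc:
        raise ModelFormatError(f"{path}: {exc}") from exc
    metabolites = []
    for _, row in met_df.iterrows():
        formula = _stoich_from_text(row["elemental_formula"], f"metabolite {row['id']}")
        metabolites.append(Metabolite(
            id=row["id"], name=row["name"], compartment=row["compartment"],
            elemental_formula=formula or None,
            charge=None if row["charge"] == "" else int(row["charge"]),
            molar_mass=None if row["molar_mass"] == "" else float(row["molar_mass"]),
        ))
    reactions = []
    for _, row in rxn_df.iterrows():
        reactions.append(Reaction(
            id=row["id"], name=row["name"],
            stoichiometry=_stoich_from_text(row["stoichiometry"], f"reaction {row['id']}"),
            lower_bound=float(row["lower_bound"]), upper_bound=float(row["upper_bound"]),
            kind=row["kind"], pathway_tag=row["pathway_tag"], evidence=row["evidence"],
        ))
    model = MetabolicModel(
        organism_id=header["organism_id"], metabolites=metabolites, reactions=reactions,
        biomass_reaction_id=header["biomass_reaction_id"],
        biomass_composition={k: float(v) for k, v in header["biomass_composition"].items()},
    )
    _raise_on_duplicates(model)
    return model


# ---------------------------------------------------------------------------
# SBML Level 3 export/import, through cobrapy/libsbml.
# ---------------------------------------------------------------------------

def _to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model(model.organism_id)
    comp_codes = {"extracellular": "e", "cytosol": "c"}
    cobra_mets = {}
    for m in model.metabolites:
        met = cobra.Metabolite(m.id, name=m.name,
                               compartment=comp_codes[m.compartment])
        if m.elemental_formula:
            met.formula = "".join(
                f"{el}{int(n) if float(n).is_integer() else n}"
                for el, n in sorted(m.elemental_formula.items()))
        if m.charge is not None:
            met.charge = m.charge
        cobra_mets[m.id] = met
    cm.add_metabolites(list(cobra_mets.values()))
    for r in model.reactions:
        rx = cobra.Reaction(r.id, name=r.name,
                            lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cm.add_reactions([rx])
        rx.add_metabolites({cobra_mets[k]: v for k, v in r.stoichiometry.items()})
        rx.notes["kind"] = r.kind
        if r.pathway_tag:
            rx.notes["pathway_tag"] = r.pathway_tag
        if r.evidence:
            rx.notes["evidence"] = r.evidence
        if r.kind == "exchange":
            # cobra treats single-metabolite reactions as boundary automatically
            pass
    cm.objective = model.biomass_reaction_id
    return cm


def export_sbml(model: MetabolicModel, path: str | Path) -> None:
    """Write a schema-valid SBML Level 3 (fbc) document with flux bounds."""
    report = validate_model(model)
    if not report.valid:
        raise ValueError("invalid model: " + "; ".join(report.violations))
    from cobra.io import write_sbml_model

    write_sbml_model(_to_cobra(model), str(path))


def import_sbml(path: str | Path) -> MetabolicModel:
    """Read an SBML model back into the native representation.

    Stoichiometry and bounds round-trip exactly; reaction kinds and evidence
    notes are recovered from SBML notes when present, otherwise inferred from
    reaction structure (single extracellular metabolite => exchange; the
    objective reaction => biomass). Biomass composition does not live in SBML
    and comes back empty.
    """
    from cobra.io import read_sbml_model
    from cobra.util.solver import linear_reaction_coefficients

    cm = read_sbml_model(str(path))
    comp_names = {"e": "extracellular", "c": "cytosol"}
    metabolites = []
    for met in cm.metabolites:
        formula = None
        if met.formula:
            try:
                formula = parse_formula(met.formula)
            except ValueError:
                formula = None
        metabolites.append(Metabolite(
            id=met.id, name=met.name or "",
            compartment=comp_names.get(met.compartment, "cytosol"),
            elemental_formula=formula, charge=met.charge))
    objective_ids = {r.id for r in linear_reaction_coefficients(cm)}
    mets_by_id = {m.id: m for m in metabolites}
    reactions = []
    for rx in cm.reactions:
        stoich = {met.id: coef for met, coef in rx.metabolites.items()}
        kind = rx.notes.get("kind")
        if kind not in REACTION_KINDS:
            if rx.id in objective_ids:
                kind = "biomass"
            elif (len(stoich) == 1 and
                  mets_by_id[next(iter(stoich))].compartment == "extracellular"):
                kind = "exchange"
            else:
                kind = "internal"
        reactions.append(Reaction(
            id=rx.id, name=rx.name or "", stoichiometry=stoich,
            lower_bound=rx.lower_bound, upper_bound=rx.upper_bound, kind=kind,
            pathway_tag=rx.notes.get("pathway_tag", ""),
            evidence=rx.notes.get("evidence", "")))
    biomass_id = next(iter(objective_ids), "")
    return MetabolicModel(organism_id=cm.id or "model", metabolites=metabolites,
                          reactions=reactions, biomass_reaction_id=biomass_id)
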