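"""Model serialization: native JSON schema and SBML Level 3 interchange.

The JSON schema mirrors the in-memory types field-for-field and
round-trips losslessly.  SBML export goes through COBRApy so the files
interoperate with standard constraint-based tooling; package-specific
annotations (balanced/clamped designation, carbon atoms, Gibbs energies)
travel in SBML notes.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

from .model import (
    MetabolicModel,
    MetaboliteSpec,
    ReactionSpec,
    model_from_dict,
    model_to_dict,
)

__all__ = ["read_model", "write_model"]


def write_model(model: MetabolicModel, path, format: str = "json") -> None:
    """Serialize a model to ``path`` as ``json`` or ``sbml``."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(model_to_dict(model), indent=1) + "\n")
    elif format == "sbml":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown model format {format!r}")


def read_model(path, format: str | None = None) -> MetabolicModel:
    """Read a model from JSON or SBML (inferred from the suffix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no model file at {path}")
    if format is None:
        format = "sbml" if path.suffix.lower() in (".xml", ".sbml") else "json"
    if format == "json":
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as err:
            raise ValueError(
                f"malformed model JSON at {path}: line {err.lineno}, "
                f"column {err.colno}: {err.msg}") from None
        return model_from_dict(payload)
    if format == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown model format {format!r}")


# ---------------------------------------------------------------------------
# SBML via COBRApy
# ---------------------------------------------------------------------------

def _write_sbml(model: MetabolicModel, path: Path) -> None:
    import cobra

    cm = cobra.Model(model.name or "model")
    cm.compartments = {"c": "cytosol", "e": "extracellular"}
    mets = {}
    for m in model.metabolites:
        cmet = cobra.Metabolite(
            m.id, name=m.name, compartment="c" if m.internal else "e")
        if m.formula:
            cmet.formula = m.formula
        notes = {"internal": str(m.internal)}
        if m.carbon_atoms is not None:
            notes["carbon_atoms"] = str(m.carbon_atoms)
        if m.dG_f is not None:
            notes["dG_f"] = repr(m.dG_f)
        cmet.notes = notes
        mets[m.id] = cmet
    cm.add_metabolites(list(mets.values()))
    for r in model.reactions:
        crxn = cobra.Reaction(r.id, name=r.name,
                              lower_bound=r.lower_bound,
                              upper_bound=r.upper_bound)
        cm.add_reactions([crxn])
        crxn.add_metabolites({mets[k]: v for k, v in r.stoichiometry.items()})
        notes = {"reversible_flag": str(r.reversible)}
        if r.dG0 is not None:
            notes["dG0"] = repr(r.dG0)
        crxn.notes = notes
    if cm.reactions:
        # the fbc package requires a non-empty objective
        cm.objective = cm.reactions[-1]
    cobra.io.write_sbml_model(cm, str(path))


def _read_sbml(path: Path) -> MetabolicModel:
    import cobra

    try:
        cm = cobra.io.read_sbml_model(str(path))
    except Exception as err:     # cobra wraps libsbml parse errors
        raise ValueError(f"malformed SBML at {path}: {err}") from None

    def _float(x):
        v = float(x)
        return v if math.isfinite(v) else None

    mets = []
    for m in cm.metabolites:
        notes = {k: str(v) for k, v in (m.notes or {}).items()}
        internal = notes.get("internal", str(m.compartment == "c")) == "True"
        carbon = notes.get("carbon_atoms")
        dgf = notes.get("dG_f")
        mets.append(MetaboliteSpec(
            id=m.id, name=m.name or "", internal=internal,
            carbon_atoms=int(carbon) if carbon is not None else None,
            formula=m.formula or None,
            dG_f=_float(dgf) if dgf is not None else None,
        ))
    rxns = []
    for r in cm.reactions:
        notes = {k: str(v) for k, v in (r.notes or {}).items()}
        dg0 = notes.get("dG0")
        rxns.append(ReactionSpec(
            id=r.id, name=r.name or "",
            stoichiometry={m.id: coef for m, coef in r.metabolites.items()},
            reversible=notes.get("reversible_flag", "False") == "True",
            lower_bound=r.lower_bound, upper_bound=r.upper_bound,
            dG0=_float(dg0) if dg0 is not None else None,
        ))
    return MetabolicModel(mets, rxns, name=cm.id or "")
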