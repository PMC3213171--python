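"""Minimal SBML reader for the core constructs a reaction graph needs.

Reads species, reactions (with reversibility), reactant/product
stoichiometry and modifier species from SBML Level 2 or 3 files and casts
them into a :class:`~shrednet.model.StoichiometricModel`.  Matching is done
on XML local names, so any SBML namespace version parses.  Modifier species
become regulatory-matrix entries (+1 — core SBML does not encode the sign
of a modifier's effect, and the sign never changes the graph topology).

Constructs outside this subset (kinetic laws, rules, events, compartment
semantics) are irrelevant to graph construction and ignored; *malformed*
core constructs — a reaction without an id, a reference to an undeclared
species, an unparseable stoichiometry — are reported through
:class:`SBMLWarning` rather than silently skipped, or raised in strict
mode.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from lxml import etree

from .model import ModelError, StoichiometricModel

__all__ = ["SBMLWarning", "read_sbml"]


class SBMLWarning(UserWarning):
    """A recoverable problem found while reading an SBML file."""


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _findall(elem, name: str):
    return [c for c in elem.iter() if isinstance(c.tag, str) and _local(c.tag) == name]


def _children(elem, name: str):
    return [c for c in elem if isinstance(c.tag, str) and _local(c.tag) == name]


def _report(msg: str, strict: bool) -> None:
    if strict:
        raise ModelError(msg)
    warnings.warn(msg, SBMLWarning, stacklevel=3)


def read_sbml(path: str | Path, *, strict: bool = False) -> StoichiometricModel:
    """Parse an SBML file into a stoichiometric model.

    Species occurring on both sides of a reaction are netted into a single
    signed coefficient.  Reversibility defaults follow the standard: absent
    ``reversible`` attributes mean reversible in Level 2 and are reported
    in Level 3 (where the attribute is required).
    """
    try:
        tree = etree.parse(str(path))
    except (OSError, etree.XMLSyntaxError) as exc:
        raise ModelError(f"cannot parse SBML file {path}: {exc}") from exc
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise ModelError(f"{path} is not an SBML document (root <{_local(root.tag)}>)")
    level = root.get("level", "2")

    models = _children(root, "model")
    if not models:
        raise ModelError(f"{path} contains no <model> element")
    model_el = models[0]

    species_ids: list[str] = []
    for lo in _children(model_el, "listOfSpecies"):
        for sp in _children(lo, "species"):
            sid = sp.get("id") or sp.get("name")
            if not sid:
                _report("species without id skipped", strict)
                continue
            species_ids.append(sid)
    sp_index = {s: i for i, s in enumerate(species_ids)}

    reaction_els = []
    for lo in _children(model_el, "listOfReactions"):
        reaction_els.extend(_children(lo, "reaction"))

    reaction_ids: list[str] = []
    reversible: list[bool] = []
    kept: list = []
    for k, rx in enumerate(reaction_els):
        rid = rx.get("id") or rx.get("name")
        if not rid:
            _report(f"reaction #{k} has no id; skipped", strict)
            continue
        rev_attr = rx.get("reversible")
        if rev_attr is None:
            if level == "3":
                _report(f"reaction {rid!r}: missing required reversible attribute; "
                        "assuming irreversible", strict)
                rev = False
            else:
                rev = True  # SBML L2 default
        else:
            rev = rev_attr.strip().lower() == "true"
        reaction_ids.append(rid)
        reversible.append(rev)
        kept.append(rx)

    S = np.zeros((len(species_ids), len(reaction_ids)))
    R = np.zeros_like(S)
    for j, rx in enumerate(kept):
        rid = reaction_ids[j]
        for list_name, sign in (("listOfReactants", -1.0), ("listOfProducts", +1.0)):
            for lo in _children(rx, list_name):
                for ref in _children(lo, "speciesReference"):
                    sid = ref.get("species")
                    if sid not in sp_index:
                        _report(f"reaction {rid!r}: reference to undeclared species "
                                f"{sid!r} skipped", strict)
                        continue
                    try:
                        coeff = float(ref.get("stoichiometry", "1"))
                    except ValueError:
                        _report(f"reaction {rid!r}: unparseable stoichiometry "
                                f"{ref.get('stoichiometry')!r}; using 1", strict)
                        coeff = 1.0
                    S[sp_index[sid], j] += sign * coeff
        for lo in _children(rx, "listOfModifiers"):
            for ref in _children(lo, "modifierSpeciesReference"):
                sid = ref.get("species")
                if sid not in sp_index:
                    _report(f"reaction {rid!r}: modifier references undeclared "
                            f"species {sid!r}; skipped", strict)
                    continue
                R[sp_index[sid], j] = 1.0

    return StoichiometricModel(
        species_ids=tuple(species_ids),
        reaction_ids=tuple(reaction_ids),
        S=S,
        reversible=tuple(reversible),
        R=R,
    )
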