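"""Network-config serialization and run manifests.

A network is stored as structured text (YAML) with three blocks::

    species:
      - {name: OH, initial_conc: 0.0, role: radiolytic_primary}
      - {name: "(SCN)2-", role: product, extinction: {472.0: 7100.0}}
    reactions:
      - {eq: "SCN- + OH -> SCN + OH-", k: 2.8e+10, label: thiocyanate oxidation}
      - "SCN- + SCN -> (SCN)2- : 7.0e+09"        # compact string form
    g_yield: {OH: 0.287, e_aq: 0.27, H: 0.055}
    tags:
      peptide_units: {P1: 1.0}

Stoichiometric counts > 1 are written as a numeric prefix (``2 R1``).
Round-tripping a network through this format is lossless.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import yaml

from .core import GYield, Reaction, ReactionNetwork, Species, _parse_side

__all__ = [
    "network_to_dict",
    "network_from_dict",
    "save_network",
    "load_network",
    "write_manifest",
]


def _side_to_str(terms: list[tuple[str, int]]) -> str:
    return " + ".join(f"{n} {s}" if n > 1 else s for s, n in terms)


def network_to_dict(net: ReactionNetwork) -> dict:
    species = []
    for sp in net.species.values():
        entry: dict = {"name": sp.name}
        if sp.initial_conc:
            entry["initial_conc"] = sp.initial_conc
        if sp.role != "solute":
            entry["role"] = sp.role
        if sp.extinction:
            entry["extinction"] = {float(w): float(e) for w, e in sp.extinction.items()}
        species.append(entry)
    reactions = []
    for rx in net.reactions:
        entry = {
            "eq": f"{_side_to_str(rx.reactants)} -> {_side_to_str(rx.products)}",
            "k": rx.k,
        }
        if rx.label:
            entry["label"] = rx.label
        reactions.append(entry)
    out: dict = {
        "species": species,
        "reactions": reactions,
        "g_yield": dict(net.g_yield.yields),
    }
    if net.tags:
        out["tags"] = {t: dict(w) for t, w in net.tags.items()}
    return out


def _parse_reaction_entry(entry) -> Reaction:
    if isinstance(entry, str):
        head, _, k_part = entry.rpartition(":")
        if not head:
            raise ValueError(f"reaction string {entry!r} lacks ': k'")
        eq, k, label = head.strip(), float(k_part), ""
    else:
        eq, k, label = entry["eq"], float(entry["k"]), entry.get("label", "")
    lhs, arrow, rhs = eq.partition("->")
    if not arrow:
        raise ValueError(f"reaction {eq!r} lacks '->'")
    return Reaction(_parse_side(lhs), _parse_side(rhs), k, label)


def network_from_dict(data: dict) -> ReactionNetwork:
    net = ReactionNetwork(g_yield=GYield(dict(data.get("g_yield", {}))))
    for entry in data.get("species", []):
        ext = {float(w): float(e) for w, e in entry.get("extinction", {}).items()}
        net.add_species(
            Species(
                entry["name"],
                float(entry.get("initial_conc", 0.0)),
                entry.get("role", "solute"),
                ext,
            )
        )
    for entry in data.get("reactions", []):
        net.add_reaction(_parse_reaction_entry(entry))
    for tag, weights in data.get("tags", {}).items():
        net.tags[tag] = {s: float(w) for s, w in weights.items()}
    return net


def save_network(net: ReactionNetwork, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(network_to_dict(net), sort_keys=False, width=100)
    )


def load_network(path) -> ReactionNetwork:
    return network_from_dict(yaml.safe_load(Path(path).read_text()))


def write_manifest(path, command: str, params: dict, outputs: list[str]) -> None:
    """JSON run manifest: resolved parameters + outputs, for regenerability."""
    manifest = {
        "command": command,
        "parameters": params,
        "outputs": outputs,
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
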