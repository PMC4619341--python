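"""Packaged construct designs: the mini-peptide family and 2HR/2.5HR/3HR.

The sequences are a synthetic reconstruction (see the data file header):
the experimentally studied sequences are not available in machine-readable
form, so the fixtures shipped here were engineered to satisfy every
documented constraint — mini length 36 aa, the residue identities the
mutation names imply (E7, T15, G19, S23, E27, R30, E34), peptide 2 overall
charge −2, the terminal arginine, and the ProtParam molecular weights of
the 2.5HR and 3HR expression constructs.  Peptides 2–11 are generated from
peptide 1 by their defining mutation lists.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .constructs import Construct, apply_mutations, parse_mutations

__all__ = ["load_designs", "mini_peptide", "full_length_construct", "MINI_MUTATIONS"]

_CACHE: dict | None = None

#: Mutation lists defining peptides 2..11 from peptide 1.
MINI_MUTATIONS = {
    2: "S23T",
    3: "T15C/S23C",
    4: "S23N",
    5: "S23T/E7A",
    6: "T15C/S23C/E7A",
    7: "S23T/R30E",
    8: "T15C/S23C/R30E",
    9: "E7A",
    10: "R30E",
    11: "E7R/E27D",
}


def _raw() -> dict:
    global _CACHE
    if _CACHE is None:
        text = (
            resources.files("sapn").joinpath("data/constructs_synthetic.yaml").read_text()
        )
        _CACHE = yaml.safe_load(text)
    return _CACHE


def _to_construct(rec: dict) -> Construct:
    return Construct(
        name=rec["name"],
        sequence=rec["sequence"],
        pentamer_range=tuple(rec["pentamer"]),
        linker_range=tuple(rec["linker"]),
        trimer_range=tuple(rec["trimer"]),
    )


def mini_peptide(number: int) -> Construct:
    """Mini construct ``peptide-<number>`` (1..11).

    Peptide 1 is the parent; 2..11 are derived by applying their defining
    mutation lists, so e.g. peptide 3 carries the T15C/S23C disulfide pair.
    """
    if not (1 <= number <= 11):
        raise ValueError(f"peptide number must be 1..11, got {number}")
    parent = _to_construct(_raw()["mini"][0])
    if number == 1:
        return parent
    from dataclasses import replace

    muts = parse_mutations(_raw()["mini_mutants"][f"peptide-{number}"])
    return replace(apply_mutations(parent, muts), name=f"peptide-{number}")


def full_length_construct(name: str) -> Construct:
    """Full-length expression construct: ``"2HR"``, ``"2.5HR"`` or ``"3HR"``."""
    for rec in _raw()["full_length"]:
        if rec["name"] == name:
            return _to_construct(rec)
    raise ValueError(f"unknown full-length construct {name!r}")


def load_designs() -> dict[str, Construct]:
    """All packaged designs by name (peptide-1..11, 2HR, 2.5HR, 3HR)."""
    out = {f"peptide-{i}": mini_peptide(i) for i in range(1, 12)}
    for rec in _raw()["full_length"]:
        out[rec["name"]] = _to_construct(rec)
    return out
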