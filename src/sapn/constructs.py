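"""Sequence-level bookkeeping for SAPN peptide constructs.

A self-assembling peptide nanoparticle (SAPN) chain is a fusion peptide:
an N-terminal pentamer-forming coiled-coil domain, a short helix-turn-helix
linker (with a central glycine hinge), and a C-terminal trimer-forming
coiled-coil domain.  This module handles the sequence-level side of the
design loop: domain ranges, point mutations written in the usual ``S23T``
notation, heptad-register assignment, formal charge and average-mass
bookkeeping, and the pentamer/trimer charge-complementarity rule used to
rank designs (opposite overall domain charges attract and favour assembly;
same-sign charges repel).

Conventions
-----------
* Residue numbering is 1-based on the construct chain, matching mutation
  names such as ``G19`` or ``E7R/E27D``.
* Charges are formal side-chain charges at neutral pH: Asp/Glu = -1,
  Lys/Arg = +1, His and the termini contribute 0.
* Masses use the ProtParam average isotopic residue-mass table plus one
  water (18.015 Da).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

__all__ = [
    "CANONICAL_AA",
    "HYDROPHOBIC",
    "RESIDUE_MASS",
    "WATER_MASS",
    "Construct",
    "Mutation",
    "HeptadRegister",
    "ChargeReport",
    "parse_mutation",
    "parse_mutations",
    "apply_mutations",
    "net_charge",
    "average_mass",
    "assign_heptad_register",
    "charge_report",
]

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Hydrophobic residues counted at heptad core (a/d) positions.
HYDROPHOBIC = set("AILMFVWY")

#: ExPASy/ProtParam average isotopic residue masses (Da), i.e. the amino
#: acid minus one water.  Summing these plus one water reproduces ProtParam
#: molecular weights.
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

WATER_MASS = 18.01524

_CHARGE = {"D": -1, "E": -1, "K": +1, "R": +1}

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


def _check_sequence(seq: str, *, context: str = "sequence") -> None:
    if not seq:
        raise ValueError(f"empty {context}")
    bad = sorted(set(seq) - CANONICAL_AA)
    if bad:
        raise ValueError(
            f"non-canonical residue letter(s) {bad} in {context!r}"
        )


@dataclass(frozen=True)
class Mutation:
    """A point mutation, e.g. ``Mutation('S', 23, 'T')`` for S23T."""

    wild_type: str
    position: int  # 1-based
    mutant: str

    def __post_init__(self) -> None:
        for letter, what in ((self.wild_type, "wild-type"), (self.mutant, "mutant")):
            if letter not in CANONICAL_AA:
                raise ValueError(f"{what} letter {letter!r} is not a canonical amino acid")
        if self.position < 1:
            raise ValueError(f"position must be 1-based positive, got {self.position}")

    def __str__(self) -> str:
        return f"{self.wild_type}{self.position}{self.mutant}"

    @property
    def reverse(self) -> "Mutation":
        return Mutation(self.mutant, self.position, self.wild_type)


def parse_mutation(text: str) -> Mutation:
    """Parse a single ``X9Y``-style mutation string."""
    m = _MUTATION_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse mutation string {text!r} (expected e.g. 'S23T')")
    return Mutation(m.group(1), int(m.group(2)), m.group(3))


def parse_mutations(text: str) -> list[Mutation]:
    """Parse a slash-joined mutation list such as ``"E7R/E27D"``."""
    if not text.strip():
        return []
    return [parse_mutation(part) for part in text.split("/")]


@dataclass(frozen=True)
class Construct:
    """An annotated SAPN peptide sequence.

    Ranges are 1-based inclusive ``(start, end)`` tuples, ordered
    pentamer < linker < trimer and mutually contiguous.  Residues before
    ``pentamer_range`` (an N-terminal purification tag) or after
    ``trimer_range`` are allowed but belong to no oligomerization domain.
    """

    name: str
    sequence: str
    pentamer_range: tuple[int, int]
    linker_range: tuple[int, int]
    trimer_range: tuple[int, int]
    mutations_applied: tuple[Mutation, ...] = ()
    disulfide_pairs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        _check_sequence(self.sequence, context=f"construct {self.name!r}")
        n = len(self.sequence)
        ranges = [self.pentamer_range, self.linker_range, self.trimer_range]
        for (lo, hi), label in zip(ranges, ("pentamer", "linker", "trimer")):
            if not (1 <= lo <= hi <= n):
                raise ValueError(
                    f"{label} range {lo}-{hi} outside sequence of length {n}"
                )
        p, l, t = ranges
        if not (p[1] + 1 == l[0] and l[1] + 1 == t[0]):
            raise ValueError(
                "domain ranges must be contiguous and ordered pentamer < linker < trimer"
            )
        for i, j in self.disulfide_pairs:
            for k in (i, j):
                if not (1 <= k <= n):
                    raise ValueError(f"disulfide residue {k} outside sequence")
                if self.sequence[k - 1] != "C":
                    raise ValueError(
                        f"disulfide pair ({i},{j}): residue {k} is "
                        f"{self.sequence[k - 1]}, not cysteine"
                    )

    # -- domain slices ------------------------------------------------
    def domain_sequence(self, which: str) -> str:
        lo, hi = {
            "pentamer": self.pentamer_range,
            "linker": self.linker_range,
            "trimer": self.trimer_range,
        }[which]
        return self.sequence[lo - 1 : hi]

    @property
    def pentamer_sequence(self) -> str:
        return self.domain_sequence("pentamer")

    @property
    def linker_sequence(self) -> str:
        return self.domain_sequence("linker")

    @property
    def trimer_sequence(self) -> str:
        return self.domain_sequence("trimer")

    @property
    def tag_sequence(self) -> str:
        """Residues preceding the pentamer domain (e.g. a His-tag)."""
        return self.sequence[: self.pentamer_range[0] - 1]

    def __len__(self) -> int:
        return len(self.sequence)


def apply_mutations(parent: Construct, mutations: list[Mutation]) -> Construct:
    """Apply point mutations to a parent construct.

    Each mutation's ``wild_type`` letter must match the parent sequence at
    its (1-based) position.  When a batch introduces two or more new
    cysteines, consecutive pairs of the new cysteine positions (sorted) are
    registered as disulfide pairs — this is how T15C/S23C double mutants
    acquire their engineered disulfide bond across the linker hinge.
    """
    seq = list(parent.sequence)
    n = len(seq)
    new_cys: list[int] = []
    for mut in mutations:
        if not (1 <= mut.position <= n):
            raise ValueError(
                f"mutation {mut}: position {mut.position} outside sequence of length {n}"
            )
        found = seq[mut.position - 1]
        if found != mut.wild_type:
            raise ValueError(
                f"mutation {mut}: expected {mut.wild_type} at position "
                f"{mut.position}, found {found}"
            )
        seq[mut.position - 1] = mut.mutant
        if mut.mutant == "C" and mut.wild_type != "C":
            new_cys.append(mut.position)

    # drop disulfides whose cysteines were mutated away, then register new
    # pairs from cysteines introduced in this batch (consecutive by position)
    pairs = [
        (i, j) for i, j in parent.disulfide_pairs
        if seq[i - 1] == "C" and seq[j - 1] == "C"
    ]
    new_cys.sort()
    for i in range(0, len(new_cys) - 1, 2):
        pairs.append((new_cys[i], new_cys[i + 1]))

    if mutations:
        name = f"{parent.name}+{'/'.join(str(m) for m in mutations)}"
    else:
        name = parent.name
    return replace(
        parent,
        name=name,
        sequence="".join(seq),
        mutations_applied=parent.mutations_applied + tuple(mutations),
        disulfide_pairs=tuple(pairs),
    )


def net_charge(sequence: str) -> int:
    """Formal net side-chain charge at neutral pH.

    ``(#Lys + #Arg) - (#Asp + #Glu)``; His and the chain termini count 0.
    """
    if sequence == "":
        return 0
    _check_sequence(sequence)
    return sum(_CHARGE.get(aa, 0) for aa in sequence)


def average_mass(sequence: str) -> float:
    """Average molecular mass in Da, ProtParam convention.

    Sum of average residue masses plus one water (18.015 Da).
    """
    _check_sequence(sequence)
    return sum(RESIDUE_MASS[aa] for aa in sequence) + WATER_MASS


_REGISTER = "abcdefg"


@dataclass(frozen=True)
class HeptadRegister:
    """Per-residue heptad register assignment for one helical domain.

    ``assignments[i]`` is the register letter a..g of residue ``i`` (0-based
    within the domain).  ``ad_hydrophobic_fraction`` is the fraction of a/d
    core positions occupied by hydrophobic residues (A,I,L,M,F,V,W,Y) — a
    crude indicator of coiled-coil plausibility.
    """

    assignments: tuple[str, ...]
    ad_hydrophobic_fraction: float

    def __len__(self) -> int:
        return len(self.assignments)


def assign_heptad_register(domain_sequence: str, start_position: str = "a") -> HeptadRegister:
    """Assign a cyclic a-g heptad register to a helical domain.

    The register advances cyclically a->b->...->g->a starting from
    ``start_position``, so residues i and i+7 always receive the same
    letter.  Domains shorter than one heptad (7 residues) are rejected.
    """
    _check_sequence(domain_sequence, context="domain")
    if len(domain_sequence) < 7:
        raise ValueError(
            f"domain of length {len(domain_sequence)} is shorter than one heptad (7)"
        )
    if start_position not in _REGISTER:
        raise ValueError(f"start register must be one of a..g, got {start_position!r}")
    k0 = _REGISTER.index(start_position)
    letters = tuple(_REGISTER[(k0 + i) % 7] for i in range(len(domain_sequence)))
    core = [aa for aa, reg in zip(domain_sequence, letters) if reg in "ad"]
    frac = sum(aa in HYDROPHOBIC for aa in core) / len(core) if core else 0.0
    return HeptadRegister(letters, frac)


@dataclass(frozen=True)
class ChargeReport:
    """Per-domain formal charges and the complementarity flag.

    The flag encodes the electrostatic design rule for SAPN assembly:
    pentamer and trimer domains with opposite overall charges attract each
    other across the linker region (favourable), equal nonzero signs repel,
    anything else is neutral.  Charges are formal, neutral-pH convention.
    """

    pentamer_charge: int
    trimer_charge: int
    linker_charge: int
    tag_charge: int
    total_charge: int
    complementarity: str  # "attract" | "repel" | "neutral"

    convention: str = "formal charge, neutral-pH convention"


def charge_report(construct: Construct) -> ChargeReport:
    """Formal-charge bookkeeping for one construct, per domain and total."""
    qp = net_charge(construct.pentamer_sequence)
    qt = net_charge(construct.trimer_sequence)
    ql = net_charge(construct.linker_sequence)
    qtag = net_charge(construct.tag_sequence)
    tail = construct.sequence[construct.trimer_range[1]:]
    total = net_charge(construct.sequence)
    assert total == qp + qt + ql + qtag + net_charge(tail)
    if qp * qt < 0:
        flag = "attract"
    elif qp * qt > 0:
        flag = "repel"
    else:
        flag = "neutral"
    return ChargeReport(qp, qt, ql, qtag, total, flag)
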