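"""Lightweight atom-array container shared by all structural modules.

A ``Structure`` is a flat, ordered collection of atom records held in
parallel numpy arrays — the same layout idea as an internal coordinate
selection in a trajectory library, chosen because every metric in this
package (RMSD, radius of gyration, inter-helical angles, wedge
classification) is a vectorized operation over coordinates.  Conversion to
and from gemmi models lives in :mod:`sapn.io`.

Coordinates are Ångström throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Structure"]


@dataclass
class Structure:
    """Ordered atom records: chain, residue, atom identity, coordinates."""

    chain: np.ndarray      # (n,) str  — chain name (may be two characters)
    resseq: np.ndarray     # (n,) int  — residue number, 1-based
    resname: np.ndarray    # (n,) str  — three-letter residue name
    atom_name: np.ndarray  # (n,) str  — e.g. "CA"
    element: np.ndarray    # (n,) str
    coords: np.ndarray     # (n, 3) float, Å

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.coords)
        for name in ("chain", "resseq", "resname", "atom_name", "element"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"field {name!r} has shape {arr.shape}, expected ({n},)")
            setattr(self, name, arr)
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords must be (n, 3), got {self.coords.shape}")

    # -- construction helpers ----------------------------------------
    @classmethod
    def from_ca(
        cls,
        coords: np.ndarray,
        *,
        chain: str = "A",
        resnames=None,
        start_resseq: int = 1,
    ) -> "Structure":
        """Build a CA-only structure from an (n, 3) coordinate array."""
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        n = len(coords)
        if resnames is None:
            resnames = np.full(n, "ALA")
        return cls(
            chain=np.full(n, chain, dtype=object),
            resseq=np.arange(start_resseq, start_resseq + n),
            resname=np.asarray(resnames, dtype=object),
            atom_name=np.full(n, "CA", dtype=object),
            element=np.full(n, "C", dtype=object),
            coords=coords,
        )

    @classmethod
    def concat(cls, parts: list["Structure"]) -> "Structure":
        return cls(
            chain=np.concatenate([p.chain for p in parts]),
            resseq=np.concatenate([p.resseq for p in parts]),
            resname=np.concatenate([p.resname for p in parts]),
            atom_name=np.concatenate([p.atom_name for p in parts]),
            element=np.concatenate([p.element for p in parts]),
            coords=np.concatenate([p.coords for p in parts]),
        )

    def __len__(self) -> int:
        return len(self.coords)

    # -- selections ---------------------------------------------------
    def mask(self, m: np.ndarray) -> "Structure":
        m = np.asarray(m)
        return Structure(
            self.chain[m], self.resseq[m], self.resname[m],
            self.atom_name[m], self.element[m], self.coords[m],
        )

    def select(self, *, chain=None, resseq_range=None, atom_name=None) -> "Structure":
        """Subset by chain name, inclusive residue range, and/or atom name."""
        m = np.ones(len(self), dtype=bool)
        if chain is not None:
            m &= self.chain == chain
        if resseq_range is not None:
            lo, hi = resseq_range
            m &= (self.resseq >= lo) & (self.resseq <= hi)
        if atom_name is not None:
            m &= self.atom_name == atom_name
        return self.mask(m)

    def ca(self) -> "Structure":
        return self.select(atom_name="CA")

    def ca_coords(self) -> np.ndarray:
        return self.select(atom_name="CA").coords

    @property
    def chains(self) -> list[str]:
        """Chain names in order of first appearance."""
        seen: dict = {}
        for c in self.chain:
            seen.setdefault(c, None)
        return list(seen)

    # -- geometry ------------------------------------------------------
    def transformed(self, R: np.ndarray = None, t: np.ndarray = None) -> "Structure":
        """Return a copy with coordinates mapped x -> R x + t."""
        xyz = self.coords
        if R is not None:
            xyz = xyz @ np.asarray(R, dtype=float).T
        if t is not None:
            xyz = xyz + np.asarray(t, dtype=float)
        out = self.copy()
        out.coords = xyz
        return out

    def with_chain(self, name: str) -> "Structure":
        out = self.copy()
        out.chain = np.full(len(self), name, dtype=object)
        return out

    def renumbered(self, start: int = 1) -> "Structure":
        """Renumber residues consecutively from ``start`` (order-preserving)."""
        out = self.copy()
        new = np.empty(len(self), dtype=int)
        cur = start - 1
        prev = None
        for i, (c, r) in enumerate(zip(self.chain, self.resseq)):
            if (c, r) != prev:
                cur += 1
                prev = (c, r)
            new[i] = cur
        out.resseq = new
        return out

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def copy(self) -> "Structure":
        return Structure(
            self.chain.copy(), self.resseq.copy(), self.resname.copy(),
            self.atom_name.copy(), self.element.copy(), self.coords.copy(),
        )
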