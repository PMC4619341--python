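"""File I/O: PDB/mmCIF structures, trajectories, FASTA, construct records.

Structure parsing and writing go through gemmi.  Legacy PDB has
single-character chain IDs only, so the 60 particle chains (named with two
characters internally, e.g. ``A0``) are mapped onto the 62 IDs
``A–Z a–z 0–9`` on PDB export, with the internal name preserved in the
segment-ID field; mmCIF keeps the two-character names as-is.  More than 62
chains cannot be written as legacy PDB (use mmCIF).

Coordinates are Å everywhere; PDB precision is 1e-3 Å.
"""

from __future__ import annotations

import json
import string
from pathlib import Path

import gemmi
import numpy as np
import yaml

from .constructs import Construct, parse_mutations
from .structure import Structure

__all__ = [
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "biomt_remarks",
    "frame_to_json",
    "frame_to_biomt",
    "write_fasta",
    "read_construct_file",
    "write_construct_file",
    "write_metrics_tsv",
]

_PDB_CHAIN_IDS = string.ascii_uppercase + string.ascii_lowercase + string.digits


# ---------------------------------------------------------------------------
# gemmi conversion

def _to_gemmi(frames: list[Structure], *, legacy_pdb: bool = False) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "sapn"
    for mi, frame in enumerate(frames, start=1):
        model = gemmi.Model(mi)
        chain_names = frame.chains
        if legacy_pdb and len(chain_names) > len(_PDB_CHAIN_IDS):
            raise ValueError(
                f"{len(chain_names)} chains exceed the {len(_PDB_CHAIN_IDS)} "
                "single-character IDs of legacy PDB; write mmCIF instead"
            )
        name_map = {}
        for i, cn in enumerate(chain_names):
            if legacy_pdb and len(str(cn)) > 1:
                name_map[cn] = _PDB_CHAIN_IDS[i]
            else:
                name_map[cn] = str(cn)
        for cn in chain_names:
            chain = gemmi.Chain(name_map[cn])
            m = frame.chain == cn
            resseq = frame.resseq[m]
            resname = frame.resname[m]
            atname = frame.atom_name[m]
            elem = frame.element[m]
            xyz = frame.coords[m]

            def _flush(res):
                if res is not None:
                    chain.add_residue(res)  # gemmi copies, so add when complete

            res = None
            prev = None
            for j in range(len(xyz)):
                key = int(resseq[j])
                if key != prev:
                    _flush(res)
                    res = gemmi.Residue()
                    res.name = str(resname[j])
                    res.seqid = gemmi.SeqId(key, " ")
                    if legacy_pdb:
                        res.segment = str(cn)[:4]
                    prev = key
                atom = gemmi.Atom()
                atom.name = str(atname[j])
                atom.element = gemmi.Element(str(elem[j]))
                atom.pos = gemmi.Position(*xyz[j])
                res.add_atom(atom)
            _flush(res)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    return st


def _from_gemmi_model(model: gemmi.Model) -> Structure:
    chains, resseqs, resnames, atnames, elems, coords = [], [], [], [], [], []
    for chain in model:
        for res in chain:
            # resolve altlocs deterministically: highest occupancy, then
            # lowest altloc label; atoms without altloc win outright
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                k = atom.name
                if k not in best:
                    best[k] = atom
                else:
                    a, b = best[k], atom
                    key_a = (0 if not a.altloc else 1, -a.occ, a.altloc)
                    key_b = (0 if not b.altloc else 1, -b.occ, b.altloc)
                    if key_b < key_a:
                        best[k] = b
            name = res.segment if res.segment else chain.name
            for atom in best.values():
                chains.append(name)
                resseqs.append(res.seqid.num)
                resnames.append(res.name)
                atnames.append(atom.name)
                elems.append(atom.element.name)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not coords:
        raise ValueError("model contains no atoms")
    return Structure(
        chain=np.asarray(chains, dtype=object),
        resseq=np.asarray(resseqs, dtype=int),
        resname=np.asarray(resnames, dtype=object),
        atom_name=np.asarray(atnames, dtype=object),
        element=np.asarray(elems, dtype=object),
        coords=np.asarray(coords, dtype=float),
    )


def _read_gemmi(path) -> gemmi.Structure:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"{path}: cannot parse structure file: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    return st


def read_structure(path) -> Structure:
    """Read a PDB or mmCIF file (first model)."""
    return _from_gemmi_model(_read_gemmi(path)[0])


def read_trajectory(path) -> list[Structure]:
    """Read a multi-model PDB (or mmCIF) file as a list of frames."""
    st = _read_gemmi(path)
    return [_from_gemmi_model(model) for model in st]


def _format_of(path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".pdb", ".ent"):
        return "pdb"
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    raise ValueError(f"cannot infer format from {path!r}; pass format='pdb'|'mmcif'")


def write_structure(
    path, structure: Structure, *, format: str | None = None,
    biomt: np.ndarray | None = None,
) -> None:
    """Write a structure as PDB or mmCIF (inferred from the suffix).

    ``biomt`` optionally embeds rotation operators as REMARK 350 BIOMT
    records (PDB only), letting any viewer regenerate the 60-mer from the
    asymmetric unit.
    """
    fmt = _format_of(path, format)
    if fmt == "pdb":
        st = _to_gemmi([structure], legacy_pdb=True)
        text = st.make_pdb_string()
        if biomt is not None:
            text = "\n".join(biomt_remarks(biomt)) + "\n" + text
        Path(path).write_text(text)
    elif fmt == "mmcif":
        st = _to_gemmi([structure])
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_trajectory(path, frames: list[Structure], *, format: str | None = None) -> None:
    """Write frames as a multi-model PDB (MODEL/ENDMDL) or mmCIF file."""
    fmt = _format_of(path, format)
    st = _to_gemmi(frames, legacy_pdb=(fmt == "pdb"))
    if fmt == "pdb":
        Path(path).write_text(st.make_pdb_string())
    else:
        st.make_mmcif_document().write_file(str(path))


# ---------------------------------------------------------------------------
# symmetry export

def biomt_remarks(rotations: np.ndarray) -> list[str]:
    """REMARK 350 BIOMT lines for a set of rotation operators (zero shift)."""
    lines = [
        "REMARK 350 BIOMOLECULE: 1",
        "REMARK 350 APPLY THE FOLLOWING TO CHAINS: A",
    ]
    for n, R in enumerate(np.asarray(rotations), start=1):
        for row in range(3):
            lines.append(
                f"REMARK 350   BIOMT{row + 1} {n:3d}"
                f"{R[row, 0]:10.6f}{R[row, 1]:10.6f}{R[row, 2]:10.6f}"
                f"{0.0:15.5f}"
            )
    return lines


def frame_to_json(frame) -> str:
    """Serialize an icosahedral frame (axes + 60 operators) to JSON."""
    payload = {
        "fivefold_axes": frame.fivefold_axes.tolist(),
        "threefold_axes": frame.threefold_axes.tolist(),
        "twofold_axes": frame.twofold_axes.tolist(),
        "rotations": frame.rotations.tolist(),
        "reference_pair": [frame.reference_pair[0].tolist(),
                           frame.reference_pair[1].tolist()],
    }
    return json.dumps(payload, indent=1)


def frame_to_biomt(frame) -> str:
    """The 60 operators as a REMARK 350 block (standard BIOMT syntax)."""
    return "\n".join(biomt_remarks(frame.rotations))


# ---------------------------------------------------------------------------
# sequence / construct records

def write_fasta(path, records: dict[str, str], width: int = 60) -> None:
    """Write named sequences as FASTA."""
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _construct_to_dict(c: Construct) -> dict:
    return {
        "name": c.name,
        "sequence": c.sequence,
        "pentamer": list(c.pentamer_range),
        "linker": list(c.linker_range),
        "trimer": list(c.trimer_range),
        "mutations": "/".join(str(m) for m in c.mutations_applied),
        "disulfides": [list(p) for p in c.disulfide_pairs],
    }


def _construct_from_dict(d: dict) -> Construct:
    from .constructs import apply_mutations

    c = Construct(
        name=d["name"],
        sequence=d["sequence"],
        pentamer_range=tuple(d["pentamer"]),
        linker_range=tuple(d["linker"]),
        trimer_range=tuple(d["trimer"]),
    )
    muts = d.get("mutations", "")
    if muts and not d.get("mutations_preapplied", True):
        c = apply_mutations(c, parse_mutations(muts))
    return c


def read_construct_file(path) -> list[Construct]:
    """Read construct records from a YAML (or JSON) file.

    The schema is a list (or single mapping) of records with ``name``,
    ``sequence``, ``pentamer``/``linker``/``trimer`` ranges, and optional
    ``mutations`` (slash-joined, applied unless ``mutations_preapplied``).
    """
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        raise ValueError(f"{path}: empty construct file")
    if isinstance(data, dict):
        data = [data]
    return [_construct_from_dict(d) for d in data]


def write_construct_file(path, constructs: list[Construct]) -> None:
    Path(path).write_text(
        yaml.safe_dump([_construct_to_dict(c) for c in constructs], sort_keys=False)
    )


def write_metrics_tsv(path, metrics) -> None:
    """Per-frame TSV: time_ns, rmsd_A, rgyr_A."""
    with open(path, "w") as fh:
        fh.write("time_ns\trmsd_A\trgyr_A\n")
        for t, r, g in zip(metrics.frame_times, metrics.rmsd_series, metrics.rgyr_series):
            fh.write(f"{t:.4f}\t{r:.4f}\t{g:.4f}\n")
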