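"""PDB reading and writing (v3.3 ATOM records), backed by gemmi.

Reading keeps every atom of every polymer residue, so a read-then-write of
an unmodified file preserves side-chain atoms; only residues missing part
of their N/CA/C backbone are dropped (counted and reported).  Coordinates
round-trip at PDB precision (3 decimals).
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

import gemmi
import numpy as np
import pandas as pd

from .model import BACKBONE_ATOMS, BackboneChain, Residue, extract_torsions, ramachandran_class

__all__ = ["read_pdb", "write_pdb", "PdbReadResult", "torsion_table"]


class PdbReadResult(NamedTuple):
    chains: list[BackboneChain]
    skipped: int  # residues dropped for an incomplete N/CA/C backbone


def _validate_atom_records(path: str) -> None:
    """Column-level sanity scan; gemmi is forgiving, so malformed ATOM
    records are caught here and reported with their line numbers."""
    bad = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                bad.append(lineno)
                continue
            try:
                int(line[6:11])
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError:
                bad.append(lineno)
    if bad:
        raise ValueError(f"malformed ATOM/HETATM records at lines: {bad}")


def read_pdb(path: str) -> PdbReadResult:
    """Read backbone chains from a PDB file.

    Returns the chains plus the number of residues skipped because their
    N/CA/C backbone was incomplete.  Residues with insertion codes raise
    (unsupported).  Malformed ATOM records raise with line numbers.
    """
    _validate_atom_records(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    st.setup_entities()
    chains: list[BackboneChain] = []
    skipped = 0
    model = st[0]
    for ch in model:
        residues = []
        for res in ch:
            if res.het_flag == "H" and res.name == "HOH":
                continue
            seqid = res.seqid
            if seqid.icode not in (" ", "", "\x00"):
                raise ValueError(
                    f"insertion codes are unsupported (residue {ch.name}/{seqid.num}{seqid.icode})"
                )
            atoms = {a.name: np.array([a.pos.x, a.pos.y, a.pos.z]) for a in res}
            if not all(n in atoms for n in BACKBONE_ATOMS):
                skipped += 1
                continue
            elements = {a.name: a.element.name for a in res}
            residues.append(Residue(seqid.num, ch.name, res.name, atoms, elements))
        if residues:
            chains.append(BackboneChain(residues, ch.name))
    return PdbReadResult(chains, skipped)


def write_pdb(chains: Iterable[BackboneChain], path: str) -> None:
    """Write chains as a PDB file (ATOM/TER/END, v3.3 columns).

    An empty chain list yields a valid file containing only the END record.
    """
    st = gemmi.Structure()
    st.name = "backpaint"
    model = gemmi.Model("1")
    # stable atom order inside a residue
    order = {n: i for i, n in enumerate(("N", "CA", "C", "O", "CB"))}
    for chain in chains:
        gch = gemmi.Chain(chain.chain_id)
        for res in chain:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_id, " ")
            gres.het_flag = "A"
            names = sorted(res.atoms, key=lambda n: (order.get(n, 99), n))
            for name in names:
                atom = gemmi.Atom()
                atom.name = name
                p = res.atoms[name]
                atom.pos = gemmi.Position(*p)
                elem = res.elements.get(name) or ("C" in name and "C") or name[0]
                atom.element = gemmi.Element(elem)
                atom.occ = 1.0
                atom.b_iso = 20.0
                gres.add_atom(atom)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    opts = gemmi.PdbWriteOptions()
    opts.minimal_file = True
    opts.ter_records = True
    opts.end_record = True
    opts.numbered_ter = False
    with open(path, "w") as fh:
        fh.write(st.make_pdb_string(opts))


def torsion_table(chain: BackboneChain) -> pd.DataFrame:
    """Tabulate per-residue torsions and Ramachandran region:
    columns seq_id, phi, psi, omega, region."""
    rows = []
    for res, t in zip(chain, extract_torsions(chain)):
        rows.append(
            {
                "seq_id": res.seq_id,
                "phi": t.phi,
                "psi": t.psi,
                "omega": t.omega,
                "region": ramachandran_class(t.phi, t.psi),
            }
        )
    return pd.DataFrame(rows, columns=["seq_id", "phi", "psi", "omega", "region"])
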