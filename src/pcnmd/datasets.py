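"""Access to worked-example structures from the public PDB archive.

The package itself never needs an accession — every analysis is testable
on generated fixtures — but the canonical demonstration input is the
ranibizumab/VEGFA crystal structure (PDB 1CZ8), whose VEGFA dimer (chains
V and W) yields a 200-node contact network.
"""

from __future__ import annotations

import urllib.request
from pathlib import Path

from .errors import EmptyInputError
from .network import build_contact_network
from .pdbio import read_pdb
from .structure import Structure

RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"

#: VEGFA dimer chain identifiers in PDB 1CZ8
VEGFA_CHAINS_1CZ8 = ("V", "W")


def fetch_pdb(
    pdb_id: str, cache_dir: str | Path | None = None, timeout: float = 30.0
) -> str:
    """Download (or read from cache) a PDB entry and return its text."""
    pdb_id = pdb_id.upper()
    if cache_dir is not None:
        cached = Path(cache_dir) / f"{pdb_id}.pdb"
        if cached.exists():
            return cached.read_text()
    url = RCSB_URL.format(pdb_id=pdb_id)
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        text = resp.read().decode("utf-8", errors="replace")
    if cache_dir is not None:
        Path(cache_dir).mkdir(parents=True, exist_ok=True)
        (Path(cache_dir) / f"{pdb_id}.pdb").write_text(text)
    return text


def chain_subset(structure: Structure, chains: tuple[str, ...]) -> Structure:
    """Protein atoms of the given chains, in original atom order."""
    atoms = [
        a for a in structure.atoms if a.chain in chains and not a.hetero
    ]
    if not atoms:
        raise EmptyInputError(f"no protein atoms in chains {chains}")
    return Structure(atoms)


def contact_network_node_count(
    structure: Structure, chains: tuple[str, ...]
) -> int:
    """Number of residue nodes in the contact network of selected chains."""
    net = build_contact_network(chain_subset(structure, chains))
    return net.n_nodes


def vegfa_dimer_node_count(pdb_text: str) -> int:
    """Contact-network node count of the VEGFA dimer in 1CZ8-style content."""
    return contact_network_node_count(read_pdb(pdb_text), VEGFA_CHAINS_1CZ8)
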