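"""Fetch deposited PDB entries for the accession-based worked examples.

The relevant accessions are the nanodisc BAM structures (7RI5–7RI9,
7RJ5, 7RI4) and the reference inward-open/outward-open structures 5D0O
and 5LJO.  Downloads go to a local cache directory and are re-used on
subsequent calls; everything else in the package runs fully offline on
synthetic fixtures.
"""

from __future__ import annotations

import urllib.error
import urllib.request
from pathlib import Path

from .errors import BamdynError
from .structio import StructureModel, read_structure

__all__ = ["AccessionError", "fetch_structure", "DEPOSITED_ACCESSIONS"]

_RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.cif"

DEPOSITED_ACCESSIONS = ("7RI7", "7RI8", "7RI9", "7RI5", "7RI6", "7RJ5", "7RI4",
                        "5D0O", "5LJO")


class AccessionError(BamdynError):
    """A deposited entry could not be retrieved."""


def fetch_structure(pdb_id: str, cache_dir: str | Path = "~/.cache/bamdyn",
                    timeout: float = 30.0) -> StructureModel:
    """Download (or reuse a cached copy of) a PDB entry as mmCIF."""
    pdb_id = pdb_id.upper()
    if len(pdb_id) != 4 or not pdb_id.isalnum():
        raise AccessionError(f"not a PDB id: {pdb_id!r}")
    cache = Path(cache_dir).expanduser()
    cache.mkdir(parents=True, exist_ok=True)
    path = cache / f"{pdb_id}.cif"
    if not path.exists():
        url = _RCSB_URL.format(pdb_id=pdb_id)
        try:
            with urllib.request.urlopen(url, timeout=timeout) as resp:
                data = resp.read()
        except (urllib.error.URLError, OSError) as exc:
            raise AccessionError(
                f"cannot download {pdb_id} from {url}: {exc}") from exc
        path.write_bytes(data)
    model = read_structure(path, format="mmcif")
    model.identifier = pdb_id
    return model
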