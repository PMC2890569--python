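"""The nine Ichneumonoidea study accessions and their one-time retrieval.

The comparative analyses are defined against nine deposited mitochondrial
genomes (two ichneumonid references and seven braconids).  GenBank records
are looked up locally (``data/accessions/<ACC>.gb`` under the working
directory or an explicit directory) and, failing that, fetched once from
NCBI Entrez — an operation that requires network access and should be
followed by saving the records locally (see ``scripts/fetch_accessions.py``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .genome_io import AnnotatedGenome, read_genbank


class AccessionUnavailableError(FileNotFoundError):
    """The record is not cached locally and could not be fetched."""


@dataclass(frozen=True)
class StudyAccession:
    accession: str
    species: str
    family: str
    group: str          # outgroup | cyclostome | noncyclostome
    complete: bool


STUDY_ACCESSIONS: dict[str, StudyAccession] = {a.accession: a for a in (
    StudyAccession("EU871947", "Diadegma semiclausum", "Ichneumonidae",
                   "outgroup", True),
    StudyAccession("FJ478177", "Enicospilus sp.", "Ichneumonidae",
                   "outgroup", False),
    StudyAccession("FJ154897", "Cotesia vestalis", "Braconidae",
                   "noncyclostome", True),
    StudyAccession("FJ387020", "Spathius agrili", "Braconidae",
                   "cyclostome", True),
    StudyAccession("GU097654", "Phanerotoma flava", "Braconidae",
                   "noncyclostome", False),
    StudyAccession("GU097655", "Diachasmimorpha longicaudata", "Braconidae",
                   "cyclostome", False),
    StudyAccession("GU097656", "Macrocentrus camphoraphilus", "Braconidae",
                   "noncyclostome", False),
    StudyAccession("GU097657", "Meteorus pulchricornis", "Braconidae",
                   "noncyclostome", False),
    StudyAccession("GU097658", "Aphidius gifuensis", "Braconidae",
                   "noncyclostome", False),
)}

#: Braconid accessions named in the evolutionary-rate contrast.
NONCYCLOSTOME_FOCAL = ("FJ154897", "GU097654", "GU097656")


def _search_dirs(data_dir=None) -> list[Path]:
    dirs = []
    if data_dir is not None:
        dirs.append(Path(data_dir))
    dirs.append(Path.cwd() / "data" / "accessions")
    dirs.append(Path(__file__).resolve().parent.parent.parent / "data" / "accessions")
    return dirs


#: Set after a failed fetch so an offline session fails fast instead of
#: re-attempting the network for every accession.
_FETCH_FAILED = False


def fetch_genbank(accession: str, dest: Path, timeout: float = 10.0) -> Path:
    """Fetch one record from NCBI Entrez and write it to ``dest``."""
    import socket
    from Bio import Entrez
    Entrez.email = "mitocomp@example.org"
    Entrez.max_tries = 1
    Entrez.sleep_between_tries = 0
    old_timeout = socket.getdefaulttimeout()
    socket.setdefaulttimeout(timeout)
    try:
        handle = Entrez.efetch(db="nuccore", id=accession, rettype="gb",
                               retmode="text")
        text = handle.read()
    finally:
        socket.setdefaulttimeout(old_timeout)
    dest.parent.mkdir(parents=True, exist_ok=True)
    dest.write_text(text)
    return dest


def load_accession(accession: str, data_dir=None,
                   allow_fetch: bool = True) -> AnnotatedGenome:
    """Load one study accession as an :class:`AnnotatedGenome`."""
    if accession not in STUDY_ACCESSIONS:
        raise KeyError(f"{accession} is not one of the study accessions")
    for d in _search_dirs(data_dir):
        path = d / f"{accession}.gb"
        if path.exists():
            genome = read_genbank(path)
            meta = STUDY_ACCESSIONS[accession]
            genome.completeness = "complete" if meta.complete else "partial"
            return genome
    global _FETCH_FAILED
    if allow_fetch and not _FETCH_FAILED:
        target = _search_dirs(data_dir)[0] / f"{accession}.gb"
        try:
            fetch_genbank(accession, target)
        except Exception as exc:  # noqa: BLE001 - any network failure
            _FETCH_FAILED = True
            raise AccessionUnavailableError(
                f"{accession}: no local copy under data/accessions/ and the "
                f"Entrez fetch failed ({exc}). Run scripts/fetch_accessions.py "
                f"once with network access.") from exc
        return load_accession(accession, data_dir, allow_fetch=False)
    raise AccessionUnavailableError(
        f"{accession}: no local copy under data/accessions/ and no network "
        f"fetch is possible in this session.")


def load_all(data_dir=None) -> dict[str, AnnotatedGenome]:
    return {acc: load_accession(acc, data_dir) for acc in STUDY_ACCESSIONS}
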