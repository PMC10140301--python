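"""Reading, labelling, filtering and writing of protein sequence sets.

Sequences enter the pipeline as predicted proteins in FASTA, each carrying a
*source* label (``metagenome`` or ``reference``) that drives all downstream
cluster-composition analysis.  The label is taken from a ``src=`` header
token, from the caller, or from a sidecar TSV which overrides both.

Partiality flags (``has_start`` / ``has_stop``) encode whether a probable
start/stop codon was present in the underlying gene call.  ``has_start``
defaults to "begins with Met"; ``has_stop`` defaults to ``False`` because
FASTA files of translated ORFs normally carry no stop-codon information.
Both can be asserted explicitly with ``start=0|1`` / ``stop=0|1`` header
tokens.
"""

from __future__ import annotations

import csv
import logging
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

#: The 20 standard amino acids in alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residue alphabet accepted in input sequences (standard plus ambiguity X).
ALPHABET = frozenset(AMINO_ACIDS + "X")

SOURCES = ("metagenome", "reference")


@dataclass(slots=True)
class SequenceRecord:
    """A labelled protein sequence; the node payload of the similarity network.

    Parameters
    ----------
    id : str
        Unique token within a dataset.
    source : str
        ``"metagenome"`` or ``"reference"``.
    residues : str
        Amino-acid sequence over the 20-letter alphabet plus ``X``.
    description : str
        Free text carried through from the FASTA header.
    contig_id, contig_length :
        Optional provenance used for candidate ranking (large contigs allow
        genomic-context follow-up).
    has_start, has_stop : bool
        Partiality flags; see module docstring.
    """

    id: str
    source: str
    residues: str
    description: str = ""
    contig_id: str | None = None
    contig_length: int | None = None
    has_start: bool = field(default=False)
    has_stop: bool = field(default=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r} for {self.id!r}")
        if not self.residues:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        for pos, ch in enumerate(self.residues):
            if ch not in ALPHABET:
                raise ValueError(
                    f"record {self.id!r}: residue {ch!r} at position {pos} "
                    "is outside the amino-acid alphabet"
                )
        if self.contig_length is not None and self.contig_length <= 0:
            raise ValueError(f"record {self.id!r}: contig_length must be positive")

    def __len__(self) -> int:
        return len(self.residues)


_TRUTHY = {"1", "true", "yes"}


def _parse_header_tokens(description: str) -> dict[str, str]:
    tokens: dict[str, str] = {}
    for part in description.split():
        if "=" in part:
            key, _, value = part.partition("=")
            tokens[key.lower()] = value
    return tokens


def read_fasta(
    path: str | Path,
    source: str | None = None,
    sidecar: str | Path | None = None,
) -> list[SequenceRecord]:
    """Read a protein FASTA file into labelled records.

    ``source`` supplies the default origin label; a ``src=`` header token
    overrides it per record, and a sidecar TSV (``id  source  contig_id
    contig_length``) overrides both.  ``has_start`` is true iff the first
    residue is Met unless a ``start=`` token says otherwise; ``has_stop``
    comes from a ``stop=`` token and defaults to false.

    Raises
    ------
    ValueError
        On duplicate ids or residues outside the alphabet.
    """
    path = Path(path)
    side = _read_sidecar(sidecar) if sidecar is not None else {}
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate sequence id {entry.id!r} in {path}")
        seen.add(entry.id)
        tokens = _parse_header_tokens(entry.description)
        residues = str(entry.seq).upper()
        rec_source = tokens.get("src", source)
        contig_id = tokens.get("contig")
        contig_length = tokens.get("contig_len")
        if entry.id in side:
            rec_source, contig_id, contig_length = side[entry.id]
        if rec_source is None:
            raise ValueError(
                f"record {entry.id!r}: no source label given and no 'src=' "
                "header token present"
            )
        if "start" in tokens:
            has_start = tokens["start"].lower() in _TRUTHY
        else:
            has_start = residues.startswith("M")
        has_stop = tokens.get("stop", "0").lower() in _TRUTHY
        records.append(
            SequenceRecord(
                id=entry.id,
                source=rec_source,
                residues=residues,
                description=entry.description,
                contig_id=contig_id,
                contig_length=int(contig_length) if contig_length else None,
                has_start=has_start,
                has_stop=has_stop,
            )
        )
    if not records:
        logger.warning("FASTA file %s contained no sequences", path)
    return records


def _read_sidecar(path: str | Path) -> dict[str, tuple[str, str | None, str | None]]:
    table: dict[str, tuple[str, str | None, str | None]] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            rec_id = row[0]
            src = row[1] if len(row) > 1 and row[1] else None
            contig = row[2] if len(row) > 2 and row[2] else None
            clen = row[3] if len(row) > 3 and row[3] else None
            if src is None:
                raise ValueError(f"sidecar row for {rec_id!r} lacks a source")
            table[rec_id] = (src, contig, clen)
    return table


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records with their labels encoded as header tokens.

    The output round-trips through :func:`read_fasta`: id, residues, source,
    partiality flags and contig metadata are all preserved.
    """
    out = []
    for rec in records:
        parts = [f"src={rec.source}", f"start={int(rec.has_start)}", f"stop={int(rec.has_stop)}"]
        if rec.contig_id is not None:
            parts.append(f"contig={rec.contig_id}")
        if rec.contig_length is not None:
            parts.append(f"contig_len={rec.contig_length}")
        out.append(
            _BioSeqRecord(Seq(rec.residues), id=rec.id, description=" ".join(parts))
        )
    SeqIO.write(out, str(path), "fasta")


def length_filter(
    records: Sequence[SequenceRecord], min_len: int
) -> list[SequenceRecord]:
    """Retain records of at least ``min_len`` residues.

    Mirrors the minimum-length cut applied before network construction
    (thresholds are set from the profile model length; no maximum is
    applied).  Order-preserving and idempotent.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [rec for rec in records if len(rec) >= min_len]


def sample_reference_fraction(
    metagenome: Sequence[SequenceRecord],
    reference_pool: Sequence[SequenceRecord],
    target_low: float = 0.25,
    target_high: float = 0.35,
    seed: int = 0,
) -> list[SequenceRecord]:
    """Mix a sampled reference outgroup into the metagenome set.

    Samples uniformly without replacement from ``reference_pool`` so that
    the reference share of the combined set falls within
    ``[target_low, target_high]`` (default 25-35%, the outgroup proportion
    used for network construction).  When the pool is too small to reach
    ``target_low`` the whole pool is used and a warning logged.
    Deterministic for a fixed seed.
    """
    if not 0 < target_low <= target_high < 1:
        raise ValueError("require 0 < target_low <= target_high < 1")
    if not metagenome:
        raise ValueError("metagenome set is empty")
    m = len(metagenome)
    # r / (r + m) in [lo, hi]  <=>  r in [lo*m/(1-lo), hi*m/(1-hi)]
    import math

    r_min = math.ceil(target_low * m / (1.0 - target_low))
    r_max = math.floor(target_high * m / (1.0 - target_high))
    mid = 0.5 * (target_low + target_high)
    r_target = round(mid * m / (1.0 - mid))
    r_target = max(r_min, min(r_target, max(r_min, r_max)))
    if len(reference_pool) < r_min:
        if reference_pool:
            logger.warning(
                "reference pool (%d) too small to reach the %.0f%% floor; "
                "using the whole pool",
                len(reference_pool),
                100 * target_low,
            )
        else:
            logger.warning("reference pool is empty; no outgroup added")
        chosen = list(reference_pool)
    else:
        n = min(r_target, len(reference_pool))
        rng = random.Random(seed)
        idx = sorted(rng.sample(range(len(reference_pool)), n))
        chosen = [reference_pool[i] for i in idx]
    return list(metagenome) + chosen


def achieved_reference_fraction(records: Sequence[SequenceRecord]) -> float:
    """Fraction of records labelled ``reference``."""
    if not records:
        raise ValueError("empty record set")
    n_ref = sum(1 for r in records if r.source == "reference")
    return n_ref / len(records)
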