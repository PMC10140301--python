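"""Post-cluster candidate triage.

Once a metagenome-only cluster has been confirmed, its members are
filtered down to credible full-length candidates: sequences lacking a
probable start (or, optionally, stop) codon or aligning poorly to the
family profile are discarded.  Surviving candidates are compared with
characterized reference sequences to measure terminal extensions — runs
of residues at the N- or C-terminus with no aligned counterpart in any
reference — and finally ranked, giving priority to sequences from large
contigs so that neighbouring genes can be investigated later.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from ssnmine.profile_search import DomainProfile, search_profile
from ssnmine.sequence_io import SequenceRecord
from ssnmine.ssn_builder import DEFAULT_SCORING, ScoringConfig, _aligner

DISCARD_REASONS = ("no_start", "no_stop", "poor_alignment")


@dataclass(slots=True)
class CandidateReport:
    """One triaged candidate, ready for the report table."""

    id: str
    cluster: int
    contig_id: str | None
    contig_length: int | None
    coverage: float
    n_extension: int
    c_extension: int
    rank: int = 0


def full_length_filter(
    cluster_records: Sequence[SequenceRecord],
    family_profile: DomainProfile,
    min_coverage: float = 0.8,
    require_stop: bool = False,
) -> tuple[list[SequenceRecord], list[tuple[SequenceRecord, str]]]:
    """Discard partial or poorly-aligned cluster members.

    A record is kept iff it has a probable start codon, a stop codon when
    ``require_stop`` is on (off by default: translated-ORF FASTA rarely
    encodes stop information), and its best family-profile hit covers at
    least ``min_coverage`` of the match columns ("aligned poorly"
    operationalized as coverage < 0.8).  Discards carry a reason code.
    Idempotent: filtering the kept set again changes nothing.
    """
    if not 0.0 < min_coverage <= 1.0:
        raise ValueError("min_coverage must be in (0, 1]")
    kept: list[SequenceRecord] = []
    discarded: list[tuple[SequenceRecord, str]] = []
    for rec in cluster_records:
        if not rec.has_start:
            discarded.append((rec, "no_start"))
            continue
        if require_stop and not rec.has_stop:
            discarded.append((rec, "no_stop"))
            continue
        hits = search_profile(family_profile, rec)
        coverage = hits[0].profile_coverage if hits else 0.0
        if coverage < min_coverage:
            discarded.append((rec, "poor_alignment"))
            continue
        kept.append(rec)
    return kept, discarded


def detect_terminal_extension(
    candidate: SequenceRecord,
    references: Sequence[SequenceRecord],
    scoring: ScoringConfig = DEFAULT_SCORING,
    max_references: int = 25,
) -> tuple[int, int]:
    """Measure N- and C-terminal extensions relative to references.

    The candidate is globally aligned (end-gap-free) to each reference;
    per reference, the extension is the number of candidate residues
    before the first / after the last aligned reference residue.  The
    median over references is returned — robust to a single atypical
    reference.  A candidate identical to a reference gives (0, 0).
    """
    if not references:
        raise ValueError("at least one reference sequence is required")
    aligner = _aligner(scoring)
    n_vals: list[int] = []
    c_vals: list[int] = []
    for ref in references[:max_references]:
        alignment = aligner.align(candidate.residues, ref.residues)[0]
        blocks = alignment.aligned[0]  # candidate (target) coordinate blocks
        if len(blocks) == 0:
            n_vals.append(0)
            c_vals.append(0)
            continue
        n_vals.append(int(blocks[0][0]))
        c_vals.append(len(candidate.residues) - int(blocks[-1][1]))
    return (
        int(round(statistics.median(n_vals))),
        int(round(statistics.median(c_vals))),
    )


def rank_candidates(kept: Sequence[SequenceRecord]) -> list[SequenceRecord]:
    """Order candidates for follow-up, largest contig first.

    Priority goes to sequences from large contigs (they allow adjacent
    genes to be investigated later); records without contig metadata fall
    back to their own sequence length.  Ties break by id, so the order is
    deterministic under any input permutation.
    """
    return sorted(kept, key=lambda r: (-(r.contig_length or len(r)), r.id))


def triage_cluster(
    cluster_index: int,
    cluster_records: Sequence[SequenceRecord],
    family_profile: DomainProfile,
    references: Sequence[SequenceRecord],
    min_coverage: float = 0.8,
    require_stop: bool = False,
    scoring: ScoringConfig = DEFAULT_SCORING,
) -> tuple[list[CandidateReport], list[tuple[SequenceRecord, str]]]:
    """Full triage of one metagenome-only cluster.

    Applies the full-length filter, measures terminal extensions against
    the supplied references, and ranks the survivors (contig length,
    falling back to sequence length when contig metadata is missing).
    """
    kept, discarded = full_length_filter(
        cluster_records, family_profile, min_coverage, require_stop
    )
    reports: list[CandidateReport] = []
    for rank, rec in enumerate(rank_candidates(kept), start=1):
        if references:
            n_ext, c_ext = detect_terminal_extension(rec, references, scoring)
        else:
            n_ext = c_ext = 0
        hits = search_profile(family_profile, rec)
        reports.append(
            CandidateReport(
                id=rec.id,
                cluster=cluster_index,
                contig_id=rec.contig_id,
                contig_length=rec.contig_length or len(rec),
                coverage=hits[0].profile_coverage if hits else 0.0,
                n_extension=n_ext,
                c_extension=c_ext,
                rank=rank,
            )
        )
    return reports, discarded


def write_candidate_tsv(candidates: Sequence[CandidateReport], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "# id\tcluster\tcontig_id\tcontig_length\tcoverage\t"
            "n_extension\tc_extension\trank\n"
        )
        for c in candidates:
            fh.write(
                f"{c.id}\t{c.cluster}\t{c.contig_id or '.'}\t"
                f"{c.contig_length or 0}\t{c.coverage:.3f}\t"
                f"{c.n_extension}\t{c.c_extension}\t{c.rank}\n"
            )
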