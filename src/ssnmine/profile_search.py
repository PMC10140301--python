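"""Profile-based family retrieval and domain-architecture classification.

Family members are retrieved by scoring each protein against a
position-specific scoring model (PSSM) built from a seed alignment, using
local (Smith-Waterman-style) dynamic programming with affine gap costs.
Statistical significance follows the Karlin-Altschul convention: maximal
local scores against random sequences follow a Gumbel distribution, whose
parameters are estimated once per profile from seeded decoy searches.  The
E-value of a hit of score ``s`` against a database of ``L`` total residues
is

    E(s, L) = K * L * model_length * exp(-lambda * s)

so that, by construction, a database of random sequences yields on average
about one hit with E <= 1.  Retrieval uses the permissive inclusion
threshold E < 1; spurious inclusions are removed later by competitive
confirmation against a library of profiles (the hmmscan-style step) and by
the network refinement itself.

Scores are log-odds in half-bits: ``2 * log2(p_column(a) / background(a))``.
DP tie-breaks prefer diagonal moves, then profile gaps, then target gaps.
All coordinates are 0-based half-open internally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import AlignIO

from ssnmine.sequence_io import AMINO_ACIDS, SequenceRecord

logger = logging.getLogger(__name__)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_GAP_CHARS = set("-.")


@lru_cache(maxsize=1)
def _blosum_conditional() -> "np.ndarray":
    """P(a | b) implied by BLOSUM62: column b sums to 1.

    BLOSUM62 entries are half-bit log-odds, so the implied target
    frequency is p(a, b) ~ bg_a * bg_b * 2**(S_ab / 2); conditioning on b
    and normalizing gives the substitution profile used for pseudocounts.
    """
    from Bio.Align import substitution_matrices

    matrix = substitution_matrices.load("BLOSUM62")
    cond = np.empty((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            cond[i, j] = 2.0 ** (matrix[a, b] / 2.0)
    cond /= cond.sum(axis=0, keepdims=True)
    return cond

#: Records shorter than this produce no hits (too short to score reliably).
MIN_TARGET_LENGTH = 8


@dataclass(slots=True)
class DomainProfile:
    """Position-specific scoring model for one protein domain family.

    ``match_scores`` is a ``model_length x 20`` table of half-bit log-odds
    scores over the standard amino-acid order; ``model_length`` is the
    number of match columns and is the basis of the per-family minimum
    length thresholds.  ``lam``/``log_k`` are the Gumbel calibration
    parameters set by :func:`calibrate_evalue` (in units of bits).
    """

    name: str
    match_scores: np.ndarray
    gap_open: float = -11.0
    gap_extend: float = -1.0
    background: np.ndarray = field(
        default_factory=lambda: np.full(20, 1.0 / 20.0)
    )
    lam: float | None = None
    log_k: float | None = None

    def __post_init__(self) -> None:
        self.match_scores = np.asarray(self.match_scores, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.match_scores.ndim != 2 or self.match_scores.shape[1] != 20:
            raise ValueError("match_scores must be model_length x 20")
        if self.match_scores.shape[0] < 1:
            raise ValueError("profile needs at least one match column")
        if not (self.match_scores.max(axis=1) > 0).all():
            raise ValueError("every match column needs a positive consensus score")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be non-positive")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")

    @property
    def model_length(self) -> int:
        return self.match_scores.shape[0]

    @property
    def calibrated(self) -> bool:
        return self.lam is not None and self.log_k is not None

    def consensus(self) -> str:
        """Highest-scoring residue per match column."""
        return "".join(AMINO_ACIDS[i] for i in self.match_scores.argmax(axis=1))

    def column_scores(self, residue: str) -> np.ndarray:
        """Per-column scores for one target residue (X scores as the
        background-weighted column average)."""
        if residue == "X":
            return self.match_scores @ self.background
        return self.match_scores[:, _AA_INDEX[residue]]

    def e_value(self, bit_score: float, db_residues: int) -> float:
        """Expected number of chance hits of at least ``bit_score`` against
        ``db_residues`` total residues of random sequence."""
        if not self.calibrated:
            raise ValueError(f"profile {self.name!r} is not calibrated")
        log_e = (
            self.log_k
            + math.log(db_residues * self.model_length)
            - self.lam * bit_score
        )
        return math.exp(min(log_e, 700.0))


@dataclass(slots=True)
class DomainHit:
    """A scored match of a profile within a target sequence."""

    target_id: str
    profile_name: str
    bit_score: float
    e_value: float
    target_envelope: tuple[int, int]  # 0-based half-open on the target
    profile_coverage: float  # fraction of match columns aligned

    def __post_init__(self) -> None:
        start, end = self.target_envelope
        if not 0 <= start < end:
            raise ValueError("envelope start must precede end")
        if not math.isfinite(self.e_value):
            raise ValueError("e_value must be finite")


@dataclass(frozen=True)
class ArchitectureRule:
    """Domain-combination rule defining one multi-domain family.

    A record matches when every ``required`` profile hits, no ``forbidden``
    profile hits, and (purely informationally) any of ``optional`` may hit.
    ``max_appending`` caps the number of appended domains considered beyond
    the catalytic one.
    """

    family_name: str
    required: frozenset[str]
    optional: frozenset[str] = frozenset()
    forbidden: frozenset[str] = frozenset()
    max_appending: int = 3

    def __post_init__(self) -> None:
        if not self.required:
            raise ValueError("a rule needs at least one required domain")
        if (self.required & self.optional) or (self.required & self.forbidden) or (
            self.optional & self.forbidden
        ):
            raise ValueError("required/optional/forbidden sets must be disjoint")
        if self.max_appending > 3:
            raise ValueError("at most three appending domains are considered")


def star_align(sequences: Sequence[str], center: int | None = None) -> list[str]:
    """Quick star multiple alignment projected onto a center sequence.

    Each sequence is globally aligned (end-gap-free) to the center (the
    longest sequence by default); residues inserted relative to the center
    are dropped, giving equal-length rows in center coordinates.  Crude
    next to a real MSA, but sufficient to build a cluster-level profile
    for spotting members that align poorly or are truncated.
    """
    if len(sequences) < 2:
        raise ValueError("star alignment needs at least two sequences")
    from ssnmine.ssn_builder import DEFAULT_SCORING, _aligner

    if center is None:
        center = max(range(len(sequences)), key=lambda i: len(sequences[i]))
    ref = sequences[center]
    aligner = _aligner(DEFAULT_SCORING)
    rows = []
    for seq in sequences:
        if seq == ref:
            rows.append(ref)
            continue
        alignment = aligner.align(ref, seq)[0]
        row = ["-"] * len(ref)
        for (t_start, t_end), (q_start, _q_end) in zip(*alignment.aligned):
            for offset in range(t_end - t_start):
                row[t_start + offset] = seq[q_start + offset]
        rows.append("".join(row))
    return rows


def read_alignment(path: str | Path, fmt: str | None = None) -> list[str]:
    """Read a seed alignment (aligned FASTA or Stockholm) as row strings."""
    path = Path(path)
    if fmt is None:
        fmt = "stockholm" if path.suffix in {".sto", ".stk", ".stockholm"} else "fasta"
    alignment = AlignIO.read(str(path), fmt)
    return [str(row.seq).upper() for row in alignment]


def build_profile(
    alignment: Sequence[str] | Sequence[SequenceRecord],
    pseudocount_weight: float = 10.0,
    name: str = "profile",
    background: np.ndarray | None = None,
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
    prior: str = "blosum62",
) -> DomainProfile:
    """Estimate a PSSM from a seed alignment.

    Columns with more than 50% gap characters are excluded from the match
    columns.  Scores are pseudocount-smoothed log-odds in half-bits:

        score[c][a] = 2 * ( log2((n_ca + w*g_ca) / (N_c + w)) - log2(b_a) )

    with ``n_ca`` the count of residue ``a`` in column ``c``, ``N_c`` the
    residue total of the column, ``b`` the background and ``w`` the
    pseudocount weight.  The pseudocount distribution ``g_c`` depends on
    ``prior``:

    * ``"blosum62"`` (default): the column's observed frequencies pushed
      through the BLOSUM62 substitution profile, ``g_c = P(a|b) @ f_c`` (weight 10).
      This rewards conservative substitutions the seed alignment never
      exhibited and is essential for retrieving distant (~25% identity)
      homologs — the same role Dirichlet-mixture priors play in profile
      HMM software.
    * ``"background"``: ``g_c = b`` (plain Laplace smoothing toward the
      background, with the formula reducing to
      ``log2((n + w*b_a)/(N + w)) - log2(b_a)``).
    """
    rows = [
        r.residues if isinstance(r, SequenceRecord) else str(r).upper()
        for r in alignment
    ]
    if len(rows) < 2:
        raise ValueError("a seed alignment needs at least two sequences")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("aligned sequences must have equal length")
    if pseudocount_weight <= 0:
        raise ValueError("pseudocount_weight must be positive")
    if prior not in {"blosum62", "background"}:
        raise ValueError(f"unknown prior {prior!r}")
    bg = np.full(20, 1.0 / 20.0) if background is None else np.asarray(background)
    cond = _blosum_conditional() if prior == "blosum62" else None

    columns = []
    for c in range(width):
        col = [row[c] for row in rows]
        n_gap = sum(ch in _GAP_CHARS for ch in col)
        if n_gap * 2 > len(col):
            continue
        counts = np.zeros(20)
        for ch in col:
            if ch in _AA_INDEX:
                counts[_AA_INDEX[ch]] += 1
        total = counts.sum()
        if total == 0:  # column of gaps and X only
            continue
        pseudo = cond @ (counts / total) if cond is not None else bg
        probs = (counts + pseudocount_weight * pseudo) / (total + pseudocount_weight)
        columns.append(2.0 * (np.log2(probs) - np.log2(bg)))
    if not columns:
        raise ValueError("no usable match columns in the alignment")
    return DomainProfile(
        name=name,
        match_scores=np.asarray(columns),
        gap_open=gap_open,
        gap_extend=gap_extend,
        background=bg,
    )


# ---------------------------------------------------------------------------
# Local profile-target dynamic programming
# ---------------------------------------------------------------------------

_NEG = -1e30


def _dp_matrices(profile: DomainProfile, residues: str):
    """Fill local-alignment DP matrices (half-bit scores).

    State M: column i aligned to residue j.  Ix: gap in the target (profile
    column skipped at fixed j).  Iy: gap in the profile (target residue
    skipped... i.e. insertion in the target) -- here Ix advances i only and
    Iy advances j only.  Local: M is floored at 0.
    """
    length = profile.model_length
    n = len(residues)
    go, ge = profile.gap_open, profile.gap_extend
    m_mat = np.full((n + 1, length + 1), 0.0)
    ix_mat = np.full((n + 1, length + 1), _NEG)
    iy_mat = np.full((n + 1, length + 1), _NEG)
    m_mat[:, 0] = 0.0
    idx = np.arange(1, length + 1)
    for j in range(1, n + 1):
        col = profile.column_scores(residues[j - 1])
        prev_m = m_mat[j - 1]
        prev_ix = ix_mat[j - 1]
        prev_iy = iy_mat[j - 1]
        best_prev = np.maximum(np.maximum(prev_m, prev_ix), prev_iy)
        m_row = np.maximum(best_prev[:-1] + col, 0.0)
        m_mat[j, 1:] = m_row
        # Iy: vertical gap (consume target residue, profile stays) from M/Iy
        iy_mat[j, 1:] = np.maximum(prev_m[1:] + go, prev_iy[1:] + ge)
        # Ix: horizontal gap (consume profile column at fixed j); recurrence
        # Ix[j,i] = max(M[j,i-1]+go, Ix[j,i-1]+ge) unrolled via running max
        # of M[j,k] - k*ge.
        t = m_mat[j, :-1] + go - idx * ge  # k = i-1 contributions
        running = np.maximum.accumulate(t)
        ix_mat[j, 1:] = running + idx * ge
    return m_mat, ix_mat, iy_mat


def _traceback(profile, residues, m_mat, ix_mat, iy_mat, j, i):
    """Walk back from M[j, i] to the local start; returns (j_start, i_start,
    n_match_columns).  Ties prefer diagonal, then profile gap (Ix), then
    target gap (Iy)."""
    go, ge = profile.gap_open, profile.gap_extend
    state = "M"
    n_cols = 0
    while True:
        if state == "M":
            score = m_mat[j, i]
            if score <= 0:
                break
            n_cols += 1
            col = profile.column_scores(residues[j - 1])[i - 1]
            prev = score - col
            j -= 1
            i -= 1
            if abs(prev) < 1e-9 and m_mat[j, i] <= 0:
                break
            if abs(m_mat[j, i] - prev) < 1e-9:
                state = "M"
            elif abs(ix_mat[j, i] - prev) < 1e-9:
                state = "Ix"
            elif abs(iy_mat[j, i] - prev) < 1e-9:
                state = "Iy"
            else:  # started fresh at this cell
                break
        elif state == "Ix":
            score = ix_mat[j, i]
            if abs(m_mat[j, i - 1] + go - score) < 1e-9:
                state = "M"
            else:
                state = "Ix"
            i -= 1
        else:  # Iy
            score = iy_mat[j, i]
            if abs(m_mat[j - 1, i] + go - score) < 1e-9:
                state = "M"
            else:
                state = "Iy"
            j -= 1
    return j, i, n_cols


def best_local_score(profile: DomainProfile, residues: str) -> float:
    """Maximal local alignment score in half-bits (score-only fast path)."""
    m_mat, _, _ = _dp_matrices(profile, residues)
    return float(m_mat.max())


def search_profile(
    profile: DomainProfile,
    record: SequenceRecord,
    db_residues: int | None = None,
    max_hits: int = 4,
) -> list[DomainHit]:
    """Find the best non-overlapping local matches of a profile in a target.

    Hits are extracted greedily: the optimal local alignment is taken,
    its target envelope masked, and the search repeated on the flanking
    segments while positive-scoring alignments remain (up to ``max_hits``).
    Hits are returned sorted by descending bit score.  E-values are
    computed at database scale ``db_residues`` (default: the target's own
    length).

    Records shorter than 8 residues yield an empty list.
    """
    if not profile.calibrated:
        raise ValueError(f"profile {profile.name!r} must be calibrated first")
    residues = record.residues
    if len(residues) < MIN_TARGET_LENGTH:
        logger.debug("record %s shorter than %d residues; skipped", record.id, MIN_TARGET_LENGTH)
        return []
    if db_residues is None:
        db_residues = len(residues)

    hits: list[DomainHit] = []
    segments = [(0, len(residues))]
    while segments and len(hits) < max_hits:
        seg_start, seg_end = segments.pop()
        if seg_end - seg_start < MIN_TARGET_LENGTH:
            continue
        sub = residues[seg_start:seg_end]
        m_mat, ix_mat, iy_mat = _dp_matrices(profile, sub)
        j_end, i_end = np.unravel_index(int(m_mat.argmax()), m_mat.shape)
        raw = float(m_mat[j_end, i_end])
        if raw <= 0:
            continue
        j0, _i0, n_cols = _traceback(profile, sub, m_mat, ix_mat, iy_mat, j_end, i_end)
        bits = raw / 2.0
        env = (seg_start + j0, seg_start + j_end)
        hits.append(
            DomainHit(
                target_id=record.id,
                profile_name=profile.name,
                bit_score=bits,
                e_value=profile.e_value(bits, db_residues),
                target_envelope=env,
                profile_coverage=n_cols / profile.model_length,
            )
        )
        segments.append((seg_start, env[0]))
        segments.append((env[1], seg_end))
    hits.sort(key=lambda h: (-h.bit_score, h.target_envelope))
    return hits


def random_background_sequence(rng: np.random.Generator, length: int,
                               background: np.ndarray | None = None) -> str:
    """An i.i.d. background-distributed amino-acid sequence."""
    bg = np.full(20, 1.0 / 20.0) if background is None else np.asarray(background)
    idx = rng.choice(20, size=length, p=bg / bg.sum())
    return "".join(AMINO_ACIDS[i] for i in idx)


def calibrate_evalue(
    profile: DomainProfile,
    decoy_count: int = 200,
    decoy_length: int = 300,
    seed: int = 0,
) -> DomainProfile:
    """Fit Gumbel E-value parameters from seeded decoy searches.

    Generates ``decoy_count`` i.i.d. background sequences of
    ``decoy_length`` residues, records the maximal local bit score of the
    profile in each, and fits a Gumbel distribution by maximum likelihood
    (the moment estimator is too sensitive to the long right tail of
    local-score maxima).  The location is folded into ``K`` via

        log K = lambda * mu - log(decoy_length * model_length)

    which makes ``E(s, L) = K * L * model_length * exp(-lambda s)`` average
    one chance hit with E <= 1 per random database, regardless of its size.
    Deterministic for a fixed seed.  Returns a calibrated copy.
    """
    if decoy_count < 100:
        raise ValueError("decoy_count must be at least 100 for a stable fit")
    rng = np.random.default_rng(seed)
    scores = np.empty(decoy_count)
    for i in range(decoy_count):
        decoy = random_background_sequence(rng, decoy_length, profile.background)
        scores[i] = best_local_score(profile, decoy) / 2.0  # bits
    std = float(scores.std(ddof=1))
    if std < 1e-12:
        raise ValueError("degenerate decoy score distribution; cannot calibrate")
    from scipy import stats

    mu, beta = stats.gumbel_r.fit(scores)
    lam = 1.0 / beta
    log_k = lam * mu - math.log(decoy_length * profile.model_length)
    return replace(profile, lam=lam, log_k=log_k)


# ---------------------------------------------------------------------------
# Retrieval, architecture assignment and confirmation
# ---------------------------------------------------------------------------


@dataclass(slots=True)
class FamilyRetrieval:
    """Result of profile-based retrieval over a sequence database."""

    profile_name: str
    e_inclusion: float
    entries: list[tuple[SequenceRecord, list[DomainHit]]]
    counts: dict[str, int]

    @property
    def records(self) -> list[SequenceRecord]:
        return [rec for rec, _ in self.entries]

    def hits_by_record(self) -> dict[str, list[DomainHit]]:
        return {rec.id: hits for rec, hits in self.entries}


def retrieve_family(
    primary: DomainProfile,
    records: Sequence[SequenceRecord],
    e_inclusion: float = 1.0,
    extra_profiles: Sequence[DomainProfile] = (),
) -> FamilyRetrieval:
    """Retrieve all records whose best primary-profile hit has E below the
    inclusion threshold (default 1, deliberately permissive), attaching
    any hits to appended-domain profiles for architecture classification.
    """
    profiles = [primary, *extra_profiles]
    if any(not p.calibrated for p in profiles):
        raise ValueError("all profiles must be calibrated before retrieval")
    db_residues = sum(len(r) for r in records)
    entries: list[tuple[SequenceRecord, list[DomainHit]]] = []
    counts = {p.name: 0 for p in profiles}
    for rec in records:
        primary_hits = search_profile(primary, rec, db_residues=db_residues)
        if not primary_hits or primary_hits[0].e_value >= e_inclusion:
            continue
        all_hits = list(primary_hits)
        counts[primary.name] += 1
        for prof in extra_profiles:
            extra = search_profile(prof, rec, db_residues=db_residues)
            extra = [h for h in extra if h.e_value < e_inclusion]
            if extra:
                counts[prof.name] += 1
            all_hits.extend(extra)
        entries.append((rec, all_hits))
    return FamilyRetrieval(
        profile_name=primary.name,
        e_inclusion=e_inclusion,
        entries=entries,
        counts=counts,
    )


def assign_architecture(
    hits_per_record: Mapping[str, Sequence[DomainHit]],
    rules: Sequence[ArchitectureRule],
    e_inclusion: float = 1.0,
) -> dict[str, str]:
    """Assign each record to the first matching domain-combination rule.

    Rules are applied most-specific first (more required domains win), so a
    ligase with the catalytic adenylation domain plus a phosphodiesterase
    domain classifies as LigD-type rather than as a bare catalytic core.
    Records matching no rule map to ``"unassigned"``.
    """
    seen_sets = set()
    for rule in rules:
        key = (rule.required, rule.optional, rule.forbidden)
        if key in seen_sets:
            raise ValueError(f"two rules share the domain sets {key}")
        seen_sets.add(key)
    ordered = sorted(rules, key=lambda r: -len(r.required))
    assignment: dict[str, str] = {}
    for rec_id, hits in hits_per_record.items():
        present = {h.profile_name for h in hits if h.e_value < e_inclusion}
        label = "unassigned"
        for rule in ordered:
            if rule.required <= present and not (rule.forbidden & present):
                label = rule.family_name
                break
        assignment[rec_id] = label
    return assignment


def confirm_cluster_members(
    cluster_records: Sequence[SequenceRecord],
    profile_library: Sequence[DomainProfile],
    family_name: str,
) -> tuple[list[SequenceRecord], list[tuple[SequenceRecord, str]]]:
    """Competitively confirm cluster membership against a profile library.

    Each record is scored against every profile in the library (the
    hmmscan-style check); it is kept iff its best-scoring profile is the
    family's own.  Rejected records are returned with the name of the
    outcompeting profile, so spurious inclusions admitted by the
    permissive retrieval threshold can be reported and discounted.
    """
    by_name = {p.name: p for p in profile_library}
    if family_name not in by_name:
        raise ValueError(f"profile library lacks the family profile {family_name!r}")
    kept: list[SequenceRecord] = []
    rejected: list[tuple[SequenceRecord, str]] = []
    for rec in cluster_records:
        best_name, best_score = None, -math.inf
        for prof in profile_library:
            score = best_local_score(prof, rec.residues)
            if score > best_score:
                best_name, best_score = prof.name, score
        if best_name == family_name:
            kept.append(rec)
        else:
            rejected.append((rec, best_name))
    return kept, rejected


# ---------------------------------------------------------------------------
# HMMER3 --domtblout interoperability
# ---------------------------------------------------------------------------


def parse_domtblout(
    path: str | Path,
    e_value_column: str = "full_sequence",
) -> list[DomainHit]:
    """Parse a HMMER3 ``--domtblout`` table into :class:`DomainHit` rows.

    Columns consumed (whitespace-delimited, 1-based positions in the HMMER
    format): target name (1), query/profile name (4), profile length (6),
    full-sequence E-value (7), full-sequence score (8), domain i-Evalue
    (13), domain score (14), hmm from/to (16, 17), env from/to (20, 21).
    ``e_value_column`` selects whether the hit E-value is the full-sequence
    value (default, the convention used for the E < 1 inclusion threshold)
    or the per-domain independent E-value (``"domain_i"``).
    """
    if e_value_column not in {"full_sequence", "domain_i"}:
        raise ValueError("e_value_column must be 'full_sequence' or 'domain_i'")
    hits: list[DomainHit] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 22:
                raise ValueError(f"malformed domtblout line: {line!r}")
            qlen = int(parts[5])
            e_full = float(parts[6])
            e_dom = float(parts[12])
            score_dom = float(parts[13])
            hmm_from, hmm_to = int(parts[15]), int(parts[16])
            env_from, env_to = int(parts[19]), int(parts[20])
            hits.append(
                DomainHit(
                    target_id=parts[0],
                    profile_name=parts[3],
                    bit_score=score_dom,
                    e_value=e_full if e_value_column == "full_sequence" else e_dom,
                    target_envelope=(env_from - 1, env_to),
                    profile_coverage=(hmm_to - hmm_from + 1) / qlen,
                )
            )
    return hits


def write_hits_tsv(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits as a TSV report (envelope 1-based inclusive for humans)."""
    with open(path, "w") as fh:
        fh.write("# target_id\tprofile\tbit_score\te_value\tenv_from\tenv_to\tcoverage\n")
        for h in hits:
            fh.write(
                f"{h.target_id}\t{h.profile_name}\t{h.bit_score:.2f}\t"
                f"{h.e_value:.3g}\t{h.target_envelope[0] + 1}\t"
                f"{h.target_envelope[1]}\t{h.profile_coverage:.3f}\n"
            )
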