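"""Nearest-neighbor 16S search by pairwise percent identity.

Each query (an ASV or OTU representative sequence) is aligned against the
16S sequences of every genome in a reference pack; the genome holding the
highest-identity sequence is the inferred source genome, provided that
identity reaches a user-chosen cutoff (recommended: 99 for ASV input, 96 for
OTU input).

Identity definition
-------------------
Percent identity is computed from a global (end-to-end) pairwise alignment
in which terminal gaps are excluded from the column count:

    identity = 100 * matching_columns / aligned_columns

where ``aligned_columns`` spans the alignment from the first to the last
aligned pair, so a perfectly matching fragment of a longer reference scores
100. Terminal gap runs (an unaligned prefix of one sequence, an unaligned
suffix of one sequence) carry a small per-residue score penalty: if they
were completely free, the score-optimal alignment of two dissimilar
sequences would collapse to a short perfect overlap and report a spuriously
high identity. Among alignments the optimum is chosen lexicographically:
maximal score, then maximal number of matching columns, then fewest aligned
columns. This three-key objective makes the identity of a sequence pair a
well-defined number, independent of traceback order, so two independent
implementations must agree exactly. Scoring is linear-gap (match, mismatch,
per-gap-column and per-terminal-residue penalties), configurable via
:class:`AlignmentScoring`. Comparison is by exact character after
uppercasing and mapping U->T; degenerate IUPAC codes only match themselves
(N vs A is a mismatch).

The production search uses a shared-k-mer prefilter to shortlist candidate
reference sequences, with an exhaustive fallback; ``brute_force_best_hit``
aligns against every sequence and serves as the independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from numba import njit

from .refpack import ReferencePack, ValidationError, _check_nucleotides

# Lexicographic (score, matches, -columns) packed into one int64:
#   key = score * 2^32 + matches * 2^16 - columns
# Safe while columns < 2^16 and |score| * 2^32 stays within int64, i.e.
# sequence lengths below ~16 kb — ample for 16S genes.
_SCORE_SHIFT = np.int64(1) << 32
_MATCH_SHIFT = np.int64(1) << 16
_MAX_LEN = 16000


@dataclass(frozen=True)
class AlignmentScoring:
    """Linear-gap alignment scoring. Defaults favor substitutions over gaps.

    ``terminal_gap`` is the per-residue cost of unaligned sequence ends;
    it steers the optimum toward spanning alignments but terminal residues
    never enter the identity denominator. Setting it to 0 makes terminal
    gaps fully free, which degenerates for dissimilar sequence pairs.
    """

    match: int = 2
    mismatch: int = -3
    gap: int = -5
    terminal_gap: int = -1

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0 or self.gap >= 0 or self.terminal_gap > 0:
            raise ValidationError(
                "scoring requires match > 0, mismatch < 0, gap < 0, "
                f"terminal_gap <= 0; got {self}"
            )


DEFAULT_SCORING = AlignmentScoring()


@dataclass(frozen=True)
class Assignment:
    """The nearest-genome decision for one query sequence.

    ``genome_ids`` holds every genome achieving the maximal identity
    (a singleton unless tied); ``passed`` records whether that identity
    reached the cutoff in force when the assignment was made.
    """

    query_id: str
    genome_ids: tuple[str, ...]
    identity_pct: float
    passed: bool


@njit(cache=True)
def _align_key(a: np.ndarray, b: np.ndarray, match: np.int64, mismatch: np.int64,
               gap: np.int64, terminal: np.int64) -> np.int64:  # pragma: no cover
    n, m = a.shape[0], b.shape[0]
    diag_match = match * _SCORE_SHIFT + _MATCH_SHIFT - 1
    diag_mis = mismatch * _SCORE_SHIFT - 1
    gap_step = gap * _SCORE_SHIFT - 1
    t_step = terminal * _SCORE_SHIFT  # terminal residues: score only, no column
    prev = np.empty(m + 1, dtype=np.int64)
    cur = np.empty(m + 1, dtype=np.int64)
    for j in range(m + 1):  # unaligned prefix of b
        prev[j] = t_step * j
    best = np.int64(-1) << 60
    for i in range(n):
        cur[0] = t_step * (i + 1)  # unaligned prefix of a
        ai = a[i]
        for j in range(m):
            v = prev[j] + (diag_match if ai == b[j] else diag_mis)
            u = prev[j + 1] + gap_step
            if u > v:
                v = u
            l = cur[j] + gap_step
            if l > v:
                v = l
            cur[j + 1] = v
        cand = cur[m] + t_step * (n - 1 - i)  # unaligned suffix of a
        if cand > best:
            best = cand
        prev, cur = cur, prev
    for j in range(m + 1):  # unaligned suffix of b
        cand = prev[j] + t_step * (m - j)
        if cand > best:
            best = cand
    return best


_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGTRYSWKMBDHVN"):
    _ENCODE[_c] = _i
    _ENCODE[_c + 32] = _i  # lowercase
_ENCODE[ord("U")] = _ENCODE[ord("T")]
_ENCODE[ord("u")] = _ENCODE[ord("T")]


def _encode(seq: str, label: str = "sequence") -> np.ndarray:
    _check_nucleotides(seq, label)
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _decode_key(key: int) -> tuple[int, int, int]:
    """Unpack an alignment key into (score, matches, columns)."""
    score = (int(key) + (1 << 31)) >> 32
    x = int(key) - (score << 32)
    matches = (x + (1 << 16) - 1) >> 16
    columns = (matches << 16) - x
    return score, matches, columns


def alignment_stats(
    a: str, b: str, scoring: AlignmentScoring = DEFAULT_SCORING
) -> tuple[int, int, int]:
    """(score, matching columns, aligned columns) of the optimal alignment."""
    if not a or not b:
        raise ValidationError("cannot align an empty sequence")
    if len(a) > _MAX_LEN or len(b) > _MAX_LEN:
        raise ValidationError(f"sequences longer than {_MAX_LEN} bp unsupported")
    key = _align_key(
        _encode(a, "sequence a"), _encode(b, "sequence b"),
        np.int64(scoring.match), np.int64(scoring.mismatch),
        np.int64(scoring.gap), np.int64(scoring.terminal_gap),
    )
    return _decode_key(key)


def percent_identity(
    a: str, b: str, scoring: AlignmentScoring = DEFAULT_SCORING
) -> float:
    """Percent identity of two nucleotide sequences in [0, 100].

    Symmetric; identical sequences (up to case, after U->T) score exactly
    100.0, as does a perfectly matching fragment or overlap of a longer
    sequence, since terminal gaps are excluded from the denominator.
    Sequences are compared as given — no reverse-complement search is
    attempted. If the optimal alignment has no aligned columns (everything
    relegated to terminal gaps), identity is 0.0.
    """
    _, matches, columns = alignment_stats(a, b, scoring)
    if columns == 0:
        return 0.0
    return 100.0 * matches / columns


class PackIndex:
    """Alignment-ready view of a reference pack.

    Deduplicates identical 16S sequences across genomes (intra-genome copies
    are often identical) and builds a k-mer postings table used to shortlist
    candidate sequences before alignment. With ``max_candidates=None`` every
    sequence sharing at least one k-mer with the query is aligned, which in
    practice is lossless for 16S-scale divergence; a finite cap trades
    exactness for speed and is guarded by the oracle-equivalence tests.
    """

    def __init__(
        self,
        pack: ReferencePack,
        scoring: AlignmentScoring = DEFAULT_SCORING,
        k: int = 8,
        max_candidates: int | None = None,
    ) -> None:
        if k < 1:
            raise ValidationError(f"k-mer size must be >= 1, got {k}")
        self.pack = pack
        self.scoring = scoring
        self.k = k
        self.max_candidates = max_candidates
        seq_to_genomes: dict[str, set[str]] = {}
        for gid in pack.genome_ids:
            for seq in pack.genomes[gid].ssu_sequences:
                seq_to_genomes.setdefault(seq.upper().replace("U", "T"), set()).add(gid)
        self._seqs: list[str] = sorted(seq_to_genomes)
        self._seq_genomes: list[tuple[str, ...]] = [
            tuple(sorted(seq_to_genomes[s])) for s in self._seqs
        ]
        self._encoded = [_encode(s) for s in self._seqs]
        self._postings: dict[str, list[int]] = {}
        for idx, seq in enumerate(self._seqs):
            for kmer in {seq[i : i + k] for i in range(len(seq) - k + 1)}:
                self._postings.setdefault(kmer, []).append(idx)
        # identity does not depend on the cutoff, so repeated searches of the
        # same sequence (e.g. cutoff sweeps) are answered from a memo
        self._cache: dict[str, tuple[float, tuple[str, ...]]] = {}

    def _identity_to(self, query_enc: np.ndarray, seq_idx: int) -> float:
        key = _align_key(
            query_enc, self._encoded[seq_idx],
            np.int64(self.scoring.match), np.int64(self.scoring.mismatch),
            np.int64(self.scoring.gap), np.int64(self.scoring.terminal_gap),
        )
        _, matches, columns = _decode_key(key)
        return 100.0 * matches / columns if columns else 0.0

    def _best_over(self, query: str, seq_indices: list[int]) -> tuple[float, tuple[str, ...]]:
        query_enc = _encode(query, "query")
        best = -1.0
        tied: set[str] = set()
        for idx in seq_indices:
            ident = self._identity_to(query_enc, idx)
            if ident > best:
                best = ident
                tied = set(self._seq_genomes[idx])
            elif ident == best:
                tied.update(self._seq_genomes[idx])
        return best, tuple(sorted(tied))

    def best_hit_exhaustive(self, query: str) -> tuple[float, tuple[str, ...]]:
        """Align against every (unique) reference 16S; the search oracle."""
        return self._best_over(query, list(range(len(self._seqs))))

    def best_hit(self, query: str) -> tuple[float, tuple[str, ...]]:
        """Production search: k-mer shortlist with exhaustive fallback."""
        q = query.upper().replace("U", "T")
        hit = self._cache.get(q)
        if hit is not None:
            return hit
        counts = np.zeros(len(self._seqs), dtype=np.int64)
        for kmer in {q[i : i + self.k] for i in range(len(q) - self.k + 1)}:
            for idx in self._postings.get(kmer, ()):
                counts[idx] += 1
        candidates = [i for i in range(len(self._seqs)) if counts[i] > 0]
        if not candidates:
            hit = self.best_hit_exhaustive(query)
        else:
            if self.max_candidates is not None and len(candidates) > self.max_candidates:
                order = sorted(candidates, key=lambda i: (-counts[i], i))
                threshold = counts[order[self.max_candidates - 1]]
                # keep the top-N plus everything tied with the N-th k-mer count
                candidates = [i for i in candidates if counts[i] >= threshold]
            hit = self._best_over(query, candidates)
        self._cache[q] = hit
        return hit


def brute_force_best_hit(
    query: str,
    pack: ReferencePack | PackIndex,
    cutoff_pct: float = 0.0,
    query_id: str = "query",
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> Assignment:
    """Exhaustively align ``query`` against every 16S of every genome.

    Returns the maximal-identity assignment with the full tie set. This is
    the reference implementation the faster prefiltered path is checked
    against.
    """
    index = pack if isinstance(pack, PackIndex) else PackIndex(pack, scoring)
    identity, genome_ids = index.best_hit_exhaustive(query)
    return Assignment(
        query_id=query_id,
        genome_ids=genome_ids,
        identity_pct=identity,
        passed=identity >= cutoff_pct,
    )


TiePolicy = Literal["split", "first"]


def _apply_tie_policy(assignment: Assignment, tie_policy: TiePolicy) -> Assignment:
    if tie_policy not in ("split", "first"):
        raise ValidationError(f"unknown tie policy {tie_policy!r}")
    if tie_policy == "first" and len(assignment.genome_ids) > 1:
        return Assignment(
            query_id=assignment.query_id,
            genome_ids=(min(assignment.genome_ids),),
            identity_pct=assignment.identity_pct,
            passed=assignment.passed,
        )
    return assignment


def assign_nearest_genome(
    query: str,
    pack: ReferencePack | PackIndex,
    cutoff_pct: float,
    tie_policy: TiePolicy = "split",
    query_id: str = "query",
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> Assignment | None:
    """Nearest-genome assignment at an identity cutoff, or None if below it.

    Under ``tie_policy='split'`` ties at the maximal identity are all
    retained (downstream the query's counts are shared equally among them);
    under ``'first'`` the lexicographically smallest genome id wins.
    """
    if not 0.0 <= cutoff_pct <= 100.0:
        raise ValidationError(f"cutoff_pct must be in [0, 100], got {cutoff_pct}")
    index = pack if isinstance(pack, PackIndex) else PackIndex(pack, scoring)
    identity, genome_ids = index.best_hit(query)
    if identity < cutoff_pct:
        return None
    return _apply_tie_policy(
        Assignment(query_id=query_id, genome_ids=genome_ids,
                   identity_pct=identity, passed=True),
        tie_policy,
    )


def write_assignments(assignments: list[Assignment], path) -> None:
    """Write an assignment report TSV: query_id, genome_ids, identity, passed."""
    import pandas as pd

    rows = [
        {
            "query_id": a.query_id,
            "genome_ids": ";".join(a.genome_ids),
            "identity_pct": a.identity_pct,
            "passed": a.passed,
        }
        for a in assignments
    ]
    pd.DataFrame(
        rows, columns=["query_id", "genome_ids", "identity_pct", "passed"]
    ).to_csv(path, sep="\t", index=False)
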