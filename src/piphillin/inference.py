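"""The prediction pipeline: queries -> genomes -> functions.

Given representative amplicon sequences (ASVs or OTU representatives) with a
feature-by-sample abundance table, the pipeline

1. assigns each query to its nearest reference genome at an identity cutoff,
2. accumulates query counts onto genomes (splitting counts equally across
   tied genomes under the ``split`` tie policy) and divides each genome's
   total by its 16S copy number — amplicon counts scale with rRNA operon
   multiplicity, so the division recovers genome abundance,
3. summarizes genome abundance into function abundance through the pack's
   function copy-count matrix, and
4. emits a per-genome contribution table whose marginals over genomes
   reproduce the function table exactly.

Queries failing the cutoff are never silently dropped: they appear in the
assignment report and in :class:`MappingStats`, since the fraction of read
mass passing the cutoff is itself a primary result.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .nnsearch import (
    DEFAULT_SCORING,
    AlignmentScoring,
    Assignment,
    PackIndex,
    TiePolicy,
    _apply_tie_policy,
    write_assignments,
)
from .refpack import PiphillinError, ReferencePack, ValidationError, load_pack

logger = logging.getLogger(__name__)


class PipelineError(PiphillinError):
    """A pipeline stage failed; the message is prefixed with the stage name."""


def validate_abundance_table(table: pd.DataFrame, label: str = "abundance table") -> None:
    """Check the feature-by-sample contract: unique ids, no negative entries."""
    if not table.index.is_unique:
        raise ValidationError(f"{label}: duplicate feature ids")
    if not table.columns.is_unique:
        raise ValidationError(f"{label}: duplicate sample ids")
    values = table.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValidationError(f"{label}: NaN entries")
    if (values < 0).any():
        raise ValidationError(f"{label}: negative entries")


def read_abundance_csv(path: str | Path, transpose: bool = False) -> pd.DataFrame:
    """Read a feature-by-sample CSV (features in rows, header of sample ids).

    Set ``transpose=True`` when the file stores samples in rows instead.
    """
    table = pd.read_csv(path, index_col=0)
    if transpose:
        table = table.T
    table.index = table.index.astype(str)
    table.columns = table.columns.astype(str)
    validate_abundance_table(table, str(path))
    return table


def read_query_fasta(path: str | Path) -> dict[str, str]:
    """Read representative sequences; returns an ordered id -> sequence map."""
    queries: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in queries:
            raise ValidationError(f"duplicate query id {rec.id!r} in {path}")
        queries[rec.id] = str(rec.seq)
    if not queries:
        raise ValidationError(f"no sequences in {path}")
    return queries


@dataclass(frozen=True)
class MappingStats:
    """Pass/fail bookkeeping for one cutoff, weighted by read counts."""

    cutoff_pct: float
    n_queries_total: int
    n_queries_passed: int
    reads_total: float
    reads_passed: float

    @property
    def fraction_reads_passed(self) -> float:
        return self.reads_passed / self.reads_total if self.reads_total else 0.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fraction_reads_passed"] = self.fraction_reads_passed
        return d


def map_queries(
    queries: Mapping[str, str] | str | Path,
    query_table: pd.DataFrame,
    pack: ReferencePack | PackIndex,
    cutoff_pct: float,
    tie_policy: TiePolicy = "split",
    scoring: AlignmentScoring = DEFAULT_SCORING,
    on_missing: str = "warn",
) -> tuple[list[Assignment], MappingStats]:
    """Assign every query to its nearest genome and tally pass statistics.

    Every query receives an :class:`Assignment` carrying its best hit and a
    ``passed`` flag (queries below the cutoff are reported, not dropped).
    Read-weighted statistics use the query's total count across samples;
    queries present in the FASTA but absent from the table are excluded from
    the read-weighted statistics with a warning (``on_missing='error'``
    raises instead).
    """
    if not 0.0 <= cutoff_pct <= 100.0:
        raise ValidationError(f"cutoff_pct must be in [0, 100], got {cutoff_pct}")
    if isinstance(queries, (str, Path)):
        queries = read_query_fasta(queries)
    validate_abundance_table(query_table, "query abundance table")
    index = pack if isinstance(pack, PackIndex) else PackIndex(pack, scoring)

    missing = [qid for qid in queries if qid not in query_table.index]
    if missing:
        msg = (
            f"{len(missing)} query id(s) absent from the abundance table "
            f"(e.g. {missing[:3]}); excluded from read-weighted statistics"
        )
        if on_missing == "error":
            raise ValidationError(msg)
        warnings.warn(msg, stacklevel=2)

    totals = query_table.sum(axis=1)
    assignments: list[Assignment] = []
    n_passed = 0
    reads_total = 0.0
    reads_passed = 0.0
    for qid, seq in queries.items():
        identity, genome_ids = index.best_hit(seq)
        passed = identity >= cutoff_pct
        assignment = _apply_tie_policy(
            Assignment(query_id=qid, genome_ids=genome_ids,
                       identity_pct=identity, passed=passed),
            tie_policy,
        )
        assignments.append(assignment)
        weight = float(totals.get(qid, 0.0))
        reads_total += weight
        if passed:
            n_passed += 1
            reads_passed += weight
    stats = MappingStats(
        cutoff_pct=cutoff_pct,
        n_queries_total=len(queries),
        n_queries_passed=n_passed,
        reads_total=reads_total,
        reads_passed=reads_passed,
    )
    return assignments, stats


def genome_abundance(
    query_table: pd.DataFrame,
    assignments: list[Assignment],
    pack: ReferencePack,
    tie_policy: TiePolicy = "split",
) -> pd.DataFrame:
    """Copy-number-normalized genome abundance (genomes x samples).

    For genome g and sample s:

        value(g, s) = sum_q share(q, g) * counts(q, s) / ssu_copy_number(g)

    where the sum runs over passing queries assigned to g and ``share`` is 1
    for a singleton assignment, 1/|tie set| under ``split``, and winner-take-
    all under ``first``. Unassigned or failing queries contribute nothing.
    """
    validate_abundance_table(query_table, "query abundance table")
    raw = pd.DataFrame(0.0, index=pd.Index([], name="genome_id"),
                       columns=query_table.columns)
    zero_row = pd.Series(0.0, index=query_table.columns)
    acc: dict[str, pd.Series] = {}
    for assignment in assignments:
        if assignment is None or not assignment.passed:
            continue
        for gid in assignment.genome_ids:
            if gid not in pack.genomes:
                raise PipelineError(
                    f"[genome-abundance] assignment for {assignment.query_id!r} "
                    f"references genome {gid!r} not present in the pack"
                )
        assignment = _apply_tie_policy(assignment, tie_policy)
        share = 1.0 / len(assignment.genome_ids)
        if assignment.query_id not in query_table.index:
            continue
        counts = query_table.loc[assignment.query_id].astype(float)
        for gid in assignment.genome_ids:
            acc[gid] = acc.get(gid, zero_row) + share * counts
    if acc:
        raw = pd.DataFrame(acc).T.sort_index()
        raw.index.name = "genome_id"
    copy_numbers = pd.Series(
        {gid: pack.genomes[gid].ssu_copy_number for gid in raw.index}, dtype=float
    )
    table = raw.div(copy_numbers, axis=0) if len(raw) else raw
    table.columns.name = "sample_id"
    return table


def function_abundance(
    genome_table: pd.DataFrame,
    pack: ReferencePack,
    drop_zero_rows: bool = False,
) -> pd.DataFrame:
    """Summarize genome abundance into function abundance (functions x samples).

    value(f, s) = sum_g genome_table(g, s) * function_copies(f, g) — a plain
    matrix product with the pack's copy matrix.
    """
    unknown = sorted(set(genome_table.index) - set(pack.genomes))
    if unknown:
        raise ValidationError(f"genomes absent from pack: {unknown}")
    copy_matrix = pack.function_copy_matrix()[list(genome_table.index)] if len(
        genome_table
    ) else pack.function_copy_matrix().iloc[:, :0]
    table = copy_matrix.to_numpy() @ genome_table.to_numpy(dtype=float)
    out = pd.DataFrame(table, index=copy_matrix.index, columns=genome_table.columns)
    if drop_zero_rows:
        out = out.loc[(out != 0).any(axis=1)]
    out.index.name = "function_id"
    out.columns.name = "sample_id"
    return out


def contribution_table(
    genome_table: pd.DataFrame,
    pack: ReferencePack,
    include_zeros: bool = False,
) -> pd.DataFrame:
    """Per-genome breakdown of predicted function abundance.

    Long-form records (function_id, genome_id, sample_id, contribution) with
    contribution(f, g, s) = genome_table(g, s) * function_copies(f, g);
    summing over genome_id recovers :func:`function_abundance` exactly. Zero
    contributions are omitted unless ``include_zeros``.
    """
    unknown = sorted(set(genome_table.index) - set(pack.genomes))
    if unknown:
        raise ValidationError(f"genomes absent from pack: {unknown}")
    copies_long = []
    for gid in genome_table.index:
        for fid, copies in sorted(pack.genomes[gid].function_copies.items()):
            copies_long.append((fid, gid, float(copies)))
    copies_df = pd.DataFrame(copies_long, columns=["function_id", "genome_id", "copies"])
    genome_long = (
        genome_table.rename_axis(index="genome_id", columns="sample_id")
        .stack()
        .rename("abundance")
        .reset_index()
    )
    merged = copies_df.merge(genome_long, on="genome_id")
    merged["contribution"] = merged["copies"] * merged["abundance"]
    out = merged[["function_id", "genome_id", "sample_id", "contribution"]]
    if not include_zeros:
        out = out[out["contribution"] != 0.0]
    return out.sort_values(
        ["function_id", "genome_id", "sample_id"], kind="mergesort"
    ).reset_index(drop=True)


def run_piphillin(
    query_fasta: str | Path,
    query_table_csv: str | Path,
    pack: ReferencePack | str | Path,
    cutoff_pct: float,
    tie_policy: TiePolicy = "split",
    outputs_dir: str | Path = "piphillin_out",
    transpose_table: bool = False,
    scoring: AlignmentScoring = DEFAULT_SCORING,
    drop_zero_functions: bool = False,
    max_candidates: int | None = None,
) -> dict[str, Path]:
    """End-to-end run; writes all output tables and returns their paths.

    Outputs (CSV/TSV/JSON, deterministic given inputs and config):
    ``assignments.tsv``, ``mapping_stats.json``, ``genome_abundance.csv``,
    ``function_abundance.csv``, ``contributions.csv``. Any stage failure
    aborts with a stage-labeled :class:`PipelineError` and removes partial
    outputs.
    """
    outputs_dir = Path(outputs_dir)
    outputs_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(name: str, writer) -> Path:
        path = outputs_dir / name
        writer(path)
        written.append(path)
        return path

    stage = "load-inputs"
    try:
        if not isinstance(pack, ReferencePack):
            pack = load_pack(pack)
        queries = read_query_fasta(query_fasta)
        query_table = read_abundance_csv(query_table_csv, transpose=transpose_table)

        stage = "map-queries"
        index = PackIndex(pack, scoring=scoring, max_candidates=max_candidates)
        assignments, stats = map_queries(
            queries, query_table, index, cutoff_pct, tie_policy, scoring
        )

        stage = "genome-abundance"
        genome_table = genome_abundance(query_table, assignments, pack, tie_policy)

        stage = "function-abundance"
        function_table = function_abundance(genome_table, pack, drop_zero_functions)

        stage = "contributions"
        contributions = contribution_table(genome_table, pack)

        stage = "write-outputs"
        paths = {
            "assignments": _write(
                "assignments.tsv", lambda p: write_assignments(assignments, p)
            ),
            "mapping_stats": _write(
                "mapping_stats.json",
                lambda p: p.write_text(
                    json.dumps(stats.to_dict(), indent=2, sort_keys=True) + "\n"
                ),
            ),
            "genome_abundance": _write(
                "genome_abundance.csv", lambda p: genome_table.to_csv(p)
            ),
            "function_abundance": _write(
                "function_abundance.csv", lambda p: function_table.to_csv(p)
            ),
            "contributions": _write(
                "contributions.csv", lambda p: contributions.to_csv(p, index=False)
            ),
        }
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(exc, PiphillinError) and str(exc).startswith("["):
            raise
        raise PipelineError(f"[{stage}] {exc}") from exc
    logger.info(
        "run complete: %d/%d queries passed cutoff %.4g (%.1f%% of reads)",
        stats.n_queries_passed, stats.n_queries_total, cutoff_pct,
        100.0 * stats.fraction_reads_passed,
    )
    return paths
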