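"""Reference packs: annotated genome collections searched by the pipeline.

A reference pack is the tool's database analogue: for every genome it holds
the 16S rRNA gene sequences that passed a length filter, the resulting 16S
copy number (used later to normalize amplicon counts), and a per-function
gene copy-count vector in a single function namespace (KO-like or RXN-like).

Packs are built from per-genome 16S FASTA files plus a long-form function
copy table, and serialize to a plain-text directory (JSON manifest + FASTA +
TSV) so they can be versioned and diffed.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Inclusive default length bounds for a plausibly full-length 16S rRNA gene.
DEFAULT_LENGTH_BOUNDS: tuple[int, int] = (1400, 1600)

PACK_FORMAT = "piphillin-pack"
PACK_VERSION = 1

_IUPAC_NT = set("ACGTURYSWKMBDHVN")
_VALID_SEQ_RE = re.compile(r"^[ACGTURYSWKMBDHVNacgturyswkmbdhvn]+$")


class PiphillinError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(PiphillinError):
    """Invalid input data (sequences, tables, parameters)."""


class PackFormatError(PiphillinError):
    """A serialized reference pack is missing, corrupt, or incompatible."""


def _check_nucleotides(seq: str, label: str) -> None:
    if not seq:
        raise ValidationError(f"{label}: empty sequence")
    if not _VALID_SEQ_RE.match(seq):
        bad = sorted(set(seq.upper()) - _IUPAC_NT)
        raise ValidationError(
            f"{label}: non-IUPAC nucleotide characters {bad!r}"
        )


def filter_ssu_by_length(
    sequences: list[str],
    min_bp: int = DEFAULT_LENGTH_BOUNDS[0],
    max_bp: int | float = DEFAULT_LENGTH_BOUNDS[1],
) -> list[str]:
    """Keep sequences whose length lies in the inclusive window [min_bp, max_bp].

    Near-full-length 16S rRNA genes are roughly 1.5 kb; the default window of
    1400-1600 bp discards fragments and mis-annotated genes before copy
    counting. Input order is preserved. Pass ``max_bp=math.inf`` to disable
    the upper bound.

    Raises
    ------
    ValidationError
        If ``min_bp > max_bp`` or any sequence contains non-IUPAC characters.
    """
    if min_bp > max_bp:
        raise ValidationError(f"min_bp {min_bp} > max_bp {max_bp}")
    for i, seq in enumerate(sequences):
        _check_nucleotides(seq, f"sequence #{i}")
    return [s for s in sequences if min_bp <= len(s) <= max_bp]


@dataclass(frozen=True)
class ReferenceGenome:
    """One annotated genome: filtered 16S sequences plus function copy counts.

    ``ssu_copy_number`` is defined as the number of 16S sequences that passed
    the length filter; it is the denominator used to correct amplicon counts
    for rRNA operon multiplicity.
    """

    genome_id: str
    ssu_sequences: tuple[str, ...]
    function_copies: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genome_id or "|" in self.genome_id or any(
            c.isspace() for c in self.genome_id
        ):
            raise ValidationError(
                f"invalid genome id {self.genome_id!r}: must be nonempty, "
                "with no whitespace or '|'"
            )
        object.__setattr__(self, "ssu_sequences", tuple(self.ssu_sequences))
        if not self.ssu_sequences:
            raise ValidationError(
                f"genome {self.genome_id!r} has no 16S sequences; genomes "
                "with zero filtered 16S are excluded from packs"
            )
        for i, seq in enumerate(self.ssu_sequences):
            _check_nucleotides(seq, f"genome {self.genome_id!r} 16S #{i}")
        object.__setattr__(
            self, "function_copies", dict(self.function_copies)
        )
        for fid, copies in self.function_copies.items():
            if not isinstance(copies, int) or isinstance(copies, bool) or copies < 0:
                raise ValidationError(
                    f"genome {self.genome_id!r}, function {fid!r}: copy count "
                    f"{copies!r} is not a nonnegative integer"
                )

    @property
    def ssu_copy_number(self) -> int:
        return len(self.ssu_sequences)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferenceGenome):
            return NotImplemented
        return (
            self.genome_id == other.genome_id
            and self.ssu_sequences == other.ssu_sequences
            and dict(self.function_copies) == dict(other.function_copies)
        )

    def __hash__(self) -> int:
        return hash((self.genome_id, self.ssu_sequences))


@dataclass
class ReferencePack:
    """An indexed collection of reference genomes in one function namespace."""

    genomes: dict[str, ReferenceGenome]
    function_namespace: str = "KO-like"
    length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genomes = dict(self.genomes)
        self.length_bounds = (self.length_bounds[0], self.length_bounds[1])
        if not self.genomes:
            raise ValidationError("reference pack contains no genomes")
        lo, hi = self.length_bounds
        for gid, genome in self.genomes.items():
            if gid != genome.genome_id:
                raise ValidationError(
                    f"pack key {gid!r} != genome id {genome.genome_id!r}"
                )
            for seq in genome.ssu_sequences:
                if not (lo <= len(seq) <= hi):
                    raise ValidationError(
                        f"genome {gid!r}: 16S of length {len(seq)} outside "
                        f"pack length bounds [{lo}, {hi}]"
                    )

    @property
    def genome_ids(self) -> list[str]:
        return sorted(self.genomes)

    @property
    def function_ids(self) -> list[str]:
        ids: set[str] = set()
        for genome in self.genomes.values():
            ids.update(genome.function_copies)
        return sorted(ids)

    def ssu_copy_numbers(self) -> pd.Series:
        """16S copy number per genome, indexed by genome id (sorted)."""
        return pd.Series(
            {gid: g.ssu_copy_number for gid, g in self.genomes.items()},
            name="ssu_copy_number",
        ).sort_index()

    def function_copy_matrix(self) -> pd.DataFrame:
        """Dense function x genome copy-count matrix (sorted ids, zeros filled)."""
        mat = pd.DataFrame(
            0.0, index=self.function_ids, columns=self.genome_ids
        )
        for gid, genome in self.genomes.items():
            for fid, copies in genome.function_copies.items():
                mat.at[fid, gid] = float(copies)
        mat.index.name = "function_id"
        mat.columns.name = "genome_id"
        return mat

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferencePack):
            return NotImplemented
        return (
            self.genomes == other.genomes
            and self.function_namespace == other.function_namespace
            and tuple(self.length_bounds) == tuple(other.length_bounds)
        )


def _read_ssu_fasta(
    ssu_fasta: Mapping[str, str | Path] | str | Path,
) -> dict[str, list[str]]:
    """Read raw (unfiltered) 16S sequences per genome.

    Two dialects are accepted: a mapping genome_id -> FASTA path (one file
    per genome), or a single FASTA whose record ids are ``genomeID|seqN``.
    """
    raw: dict[str, list[str]] = {}
    if isinstance(ssu_fasta, (str, Path)):
        for rec in SeqIO.parse(str(ssu_fasta), "fasta"):
            if "|" not in rec.id:
                raise ValidationError(
                    f"combined FASTA record {rec.id!r} lacks the "
                    "'genomeID|seqN' header prefix"
                )
            gid = rec.id.rsplit("|", 1)[0]
            raw.setdefault(gid, []).append(str(rec.seq))
    else:
        for gid in sorted(ssu_fasta):
            raw[gid] = [
                str(rec.seq) for rec in SeqIO.parse(str(ssu_fasta[gid]), "fasta")
            ]
    return raw


def _read_function_table(function_table: str | Path | pd.DataFrame) -> pd.DataFrame:
    if isinstance(function_table, pd.DataFrame):
        df = function_table.copy()
    else:
        sep = "\t" if str(function_table).endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(function_table, sep=sep, dtype={0: str, 1: str})
    required = {"genome_id", "function_id", "copies"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"function table must have columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    dup = df.duplicated(subset=["genome_id", "function_id"])
    if dup.any():
        rows = df.loc[dup, ["genome_id", "function_id"]].head(5)
        raise ValidationError(
            "duplicate (genome_id, function_id) rows in function table, "
            f"e.g.\n{rows.to_string(index=False)}"
        )
    return df


def build_reference_pack(
    ssu_fasta: Mapping[str, str | Path] | str | Path,
    function_table: str | Path | pd.DataFrame,
    length_bounds: tuple[int, int | float] = DEFAULT_LENGTH_BOUNDS,
    function_namespace: str = "KO-like",
    provenance: Mapping[str, str] | None = None,
) -> ReferencePack:
    """Build a reference pack from 16S FASTA input and a function copy table.

    For each genome the 16S sequences are length-filtered and counted; the
    count becomes the genome's 16S copy number. Genomes whose every 16S fails
    the filter can never be matched by a query and would corrupt copy-number
    normalization, so they are logged and excluded. A genome with filtered
    16S but no rows in the function table is an error (orphan), because its
    functional content is unknown.
    """
    raw = _read_ssu_fasta(ssu_fasta)
    func_df = _read_function_table(function_table)

    genomes: dict[str, ReferenceGenome] = {}
    excluded: list[str] = []
    func_by_genome = {
        str(gid): dict(zip(sub["function_id"].astype(str), sub["copies"].astype(int)))
        for gid, sub in func_df.groupby("genome_id")
    }
    for gid in sorted(raw):
        kept = filter_ssu_by_length(raw[gid], length_bounds[0], length_bounds[1])
        if not kept:
            excluded.append(gid)
            continue
        genomes[gid] = ReferenceGenome(
            genome_id=gid,
            ssu_sequences=tuple(kept),
            function_copies=func_by_genome.get(gid, {}),
        )
    if excluded:
        logger.info(
            "excluded %d genome(s) with no 16S passing the [%s, %s] length "
            "filter: %s",
            len(excluded), length_bounds[0], length_bounds[1], ", ".join(excluded),
        )
    orphans = sorted(set(genomes) - set(func_by_genome))
    if orphans:
        raise ValidationError(
            "genomes with filtered 16S but absent from the function table: "
            + ", ".join(orphans)
        )
    unused = sorted(set(func_by_genome) - set(raw))
    if unused:
        logger.info(
            "function table lists %d genome(s) without 16S input (ignored): %s",
            len(unused), ", ".join(unused),
        )
    hi = length_bounds[1]
    hi_int = int(hi) if math.isfinite(hi) else 10**9
    return ReferencePack(
        genomes=genomes,
        function_namespace=function_namespace,
        length_bounds=(int(length_bounds[0]), hi_int),
        provenance=dict(provenance or {}),
    )


def save_pack(pack: ReferencePack, path: str | Path) -> None:
    """Serialize a pack to a directory: manifest.json + ssu.fasta + functions.tsv.

    Output is deterministic (genomes and functions sorted), so identical
    packs serialize byte-identically.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format": PACK_FORMAT,
        "version": PACK_VERSION,
        "function_namespace": pack.function_namespace,
        "length_bounds": list(pack.length_bounds),
        "provenance": pack.provenance,
        "genome_ids": pack.genome_ids,
        "ssu_copy_numbers": {
            gid: pack.genomes[gid].ssu_copy_number for gid in pack.genome_ids
        },
    }
    (path / "manifest.json").write_text(
        json.dumps(manifest, indent=2, ensure_ascii=False, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    records = [
        SeqRecord(Seq(seq), id=f"{gid}|{i}", description="")
        for gid in pack.genome_ids
        for i, seq in enumerate(pack.genomes[gid].ssu_sequences)
    ]
    SeqIO.write(records, str(path / "ssu.fasta"), "fasta")
    rows = [
        (gid, fid, copies)
        for gid in pack.genome_ids
        for fid, copies in sorted(pack.genomes[gid].function_copies.items())
    ]
    pd.DataFrame(rows, columns=["genome_id", "function_id", "copies"]).to_csv(
        path / "functions.tsv", sep="\t", index=False
    )


def load_pack(path: str | Path) -> ReferencePack:
    """Load a serialized pack, verifying format, version, and completeness.

    A truncated or inconsistent pack (sequence counts disagreeing with the
    manifest, missing function rows) raises :class:`PackFormatError` rather
    than yielding a partial pack.
    """
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.is_file():
        raise PackFormatError(f"no manifest.json under {path}")
    try:
        manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise PackFormatError(f"corrupt manifest.json under {path}: {exc}") from exc
    if manifest.get("format") != PACK_FORMAT:
        raise PackFormatError(f"not a reference pack: {manifest_path}")
    if manifest.get("version") != PACK_VERSION:
        raise PackFormatError(
            f"incompatible pack version {manifest.get('version')!r} "
            f"(this build reads version {PACK_VERSION})"
        )
    try:
        pack = build_reference_pack(
            path / "ssu.fasta",
            path / "functions.tsv",
            length_bounds=tuple(manifest["length_bounds"]),
            function_namespace=manifest["function_namespace"],
            provenance=manifest.get("provenance", {}),
        )
    except (ValidationError, FileNotFoundError, ValueError) as exc:
        raise PackFormatError(f"corrupt or truncated pack under {path}: {exc}") from exc
    expected = manifest.get("ssu_copy_numbers", {})
    actual = {gid: g.ssu_copy_number for gid, g in pack.genomes.items()}
    if actual != {k: int(v) for k, v in expected.items()}:
        raise PackFormatError(
            f"pack under {path} disagrees with its manifest "
            "(truncated ssu.fasta?)"
        )
    return pack


def percent_increase(n_old: int, n_new: int) -> float:
    """Relative growth of a genome collection, in percent.

    Used to report how much a reference database expanded between releases,
    e.g. ``percent_increase(3036, 4132)`` -> ~36.1.
    """
    if n_old <= 0:
        raise ValidationError(f"old count must be positive, got {n_old}")
    return 100.0 * (n_new - n_old) / n_old
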