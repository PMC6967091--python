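"""Synthetic reference packs, communities and amplicon observations.

The generator emulates exactly the structure the prediction method assumes:
annotated genomes carrying one or more (near-)identical 16S gene copies and
a sparse function copy-count vector; per-sample community abundances; and
observed amplicon representatives that are error-bearing copies of the true
16S genes, with read counts proportional to genome abundance times 16S copy
number. Everything is driven by a single integer seed through numpy's
``default_rng`` (integer-state, platform-independent), so any bundle is
exactly reproducible.

Model summary
-------------
* Reference genomes are independent per-site mutations of one random
  ancestor 16S at rate ``divergence_between_genomes`` (a substitution always
  changes the base), so the expected pairwise identity between two genomes
  is (1-d)^2 + d^2/3 per site.
* 16S copy numbers are uniform integers in ``copy_number_range``; copies are
  identical by default (``copy_divergence`` adds intra-genome variation).
* Function copy counts: each genome carries each function with probability
  ``function_prevalence``; present functions get 1 + Poisson(mean-1) copies.
* Per-sample genome abundances are log-normal; the amplicon pool weights
  each genome by abundance x copy number; reads are multinomial at
  ``read_depth`` (or exact expected counts in deterministic mode).
* Observed query sequences are per-site substitution-mutated copies of a
  genome's 16S at ``query_error_rate`` (no indels by default, keeping
  identities hand-derivable; ``query_indel_rate`` stresses the aligner).
* Optional two-group design: the second half of the samples has
  ``n_affected_genomes`` genomes' abundances multiplied by
  ``planted_fold_change``.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .refpack import (
    DEFAULT_LENGTH_BOUNDS,
    ReferenceGenome,
    ReferencePack,
    ValidationError,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic world; defaults give a small noisy benchmark."""

    n_genomes: int = 20
    ssu_length: int = 1500
    divergence_between_genomes: float = 0.04
    copy_number_range: tuple[int, int] = (1, 15)
    copy_divergence: float = 0.0
    n_functions: int = 100
    function_prevalence: float = 0.35
    mean_function_copies: float = 2.0
    n_samples: int = 6
    lognormal_sigma: float = 1.0
    query_error_rate: float = 0.005
    query_indel_rate: float = 0.0
    queries_per_genome: int = 1
    read_depth: int = 50_000
    deterministic_counts: bool = False
    planted_fold_change: float = 1.0
    n_affected_genomes: int = 0
    length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("divergence_between_genomes", "copy_divergence",
                     "query_error_rate", "query_indel_rate",
                     "function_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if not (self.length_bounds[0] <= self.ssu_length <= self.length_bounds[1]):
            raise ValidationError(
                f"ssu_length {self.ssu_length} outside the length filter "
                f"{self.length_bounds}; reference genomes would be empty"
            )
        if self.copy_number_range[0] < 1 or (
            self.copy_number_range[0] > self.copy_number_range[1]
        ):
            raise ValidationError(
                f"invalid copy_number_range {self.copy_number_range}"
            )
        if min(self.n_genomes, self.n_functions, self.n_samples,
               self.queries_per_genome) < 1:
            raise ValidationError("counts must be >= 1")
        if self.n_affected_genomes > self.n_genomes:
            raise ValidationError("n_affected_genomes exceeds n_genomes")
        if self.mean_function_copies < 1.0:
            raise ValidationError("mean_function_copies must be >= 1")


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution at ``rate``; a hit always changes the base."""
    out = seq.copy()
    if rate <= 0.0:
        return out
    hits = np.flatnonzero(rng.random(seq.shape[0]) < rate)
    # pick one of the 3 other bases uniformly
    for i in hits:
        choices = _BASES[_BASES != out[i]]
        out[i] = choices[rng.integers(3)]
    return out


def _indel(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0.0:
        return seq
    out: list[int] = []
    for base in seq:
        r = rng.random()
        if r < rate / 2:
            continue  # deletion
        out.append(base)
        if rate / 2 <= r < rate:
            out.append(_BASES[rng.integers(4)])  # insertion
    if not out:
        out.append(_BASES[rng.integers(4)])
    return np.asarray(out, dtype=np.uint8)


def _to_str(seq: np.ndarray) -> str:
    return seq.tobytes().decode("ascii")


def expected_pairwise_identity(divergence: float) -> float:
    """Expected per-site identity of two genomes mutated from one ancestor."""
    d = divergence
    return (1.0 - d) ** 2 + d**2 / 3.0


def simulate_reference_pack(
    config: SimulationConfig,
) -> tuple[ReferencePack, pd.DataFrame]:
    """Generate a reference pack and its dense function copy matrix.

    Returns ``(pack, copy_matrix)`` where ``copy_matrix`` is the functions x
    genomes table also recoverable via ``pack.function_copy_matrix()``.
    """
    if expected_pairwise_identity(config.divergence_between_genomes) < 0.75:
        warnings.warn(
            "configured divergence implies expected pairwise identity below "
            "75%; queries would fail every customary cutoff",
            stacklevel=2,
        )
    rng = np.random.default_rng([config.random_seed, 0])
    ancestor = rng.choice(_BASES, size=config.ssu_length)
    genome_ids = [f"G{i:03d}" for i in range(config.n_genomes)]
    function_ids = [f"F{j:04d}" for j in range(config.n_functions)]

    present = rng.random((config.n_functions, config.n_genomes)) < config.function_prevalence
    copies = 1 + rng.poisson(config.mean_function_copies - 1.0,
                             size=(config.n_functions, config.n_genomes))
    copy_matrix = pd.DataFrame(
        np.where(present, copies, 0).astype(float),
        index=pd.Index(function_ids, name="function_id"),
        columns=pd.Index(genome_ids, name="genome_id"),
    )

    genomes: dict[str, ReferenceGenome] = {}
    lo, hi = config.copy_number_range
    for g, gid in enumerate(genome_ids):
        base = _mutate(ancestor, config.divergence_between_genomes, rng)
        n_copies = int(rng.integers(lo, hi + 1))
        seqs = tuple(
            _to_str(_mutate(base, config.copy_divergence, rng))
            for _ in range(n_copies)
        )
        genomes[gid] = ReferenceGenome(
            genome_id=gid,
            ssu_sequences=seqs,
            function_copies={
                fid: int(copy_matrix.at[fid, gid])
                for fid in function_ids
                if copy_matrix.at[fid, gid] > 0
            },
        )
    pack = ReferencePack(
        genomes=genomes,
        function_namespace="KO-like",
        length_bounds=config.length_bounds,
        provenance={
            "source": "synthetic",
            "seed": str(config.random_seed),
            "n_genomes": str(config.n_genomes),
        },
    )
    return pack, copy_matrix


@dataclass
class CommunitySim:
    """One simulated study: observed amplicon data plus the ground truth."""

    queries: dict[str, str]
    query_table: pd.DataFrame          # queries x samples (observed counts)
    true_genome_table: pd.DataFrame    # genomes x samples (latent abundance)
    true_function_table: pd.DataFrame  # functions x samples (ground truth)
    query_sources: dict[str, str]      # query id -> source genome id
    group_labels: dict[str, str] = field(default_factory=dict)
    affected_genomes: tuple[str, ...] = ()


def simulate_community(
    pack: ReferencePack,
    config: SimulationConfig,
    copy_matrix: pd.DataFrame | None = None,
) -> CommunitySim:
    """Draw per-sample community abundances and observed amplicon counts.

    The amplicon pool weights genome g in sample s by abundance(g, s) times
    its 16S copy number; each genome emits ``queries_per_genome`` observed
    representative sequences that share its reads equally. In deterministic
    mode counts are exact expected values (read_depth times pool share);
    otherwise they are one multinomial draw per sample.
    """
    if config.read_depth <= 0:
        raise ValidationError(f"read_depth must be positive, got {config.read_depth}")
    if copy_matrix is None:
        copy_matrix = pack.function_copy_matrix()
    rng = np.random.default_rng([config.random_seed, 1])
    genome_ids = pack.genome_ids
    sample_ids = [f"S{j:02d}" for j in range(config.n_samples)]

    abund = rng.lognormal(mean=0.0, sigma=config.lognormal_sigma,
                          size=(len(genome_ids), config.n_samples))
    group_labels: dict[str, str] = {}
    affected: tuple[str, ...] = ()
    if config.n_affected_genomes and config.planted_fold_change != 1.0:
        half = config.n_samples // 2
        group_labels = {
            s: ("control" if j < half else "case")
            for j, s in enumerate(sample_ids)
        }
        affected = tuple(genome_ids[: config.n_affected_genomes])
        abund[: config.n_affected_genomes, half:] *= config.planted_fold_change

    true_genome_table = pd.DataFrame(
        abund, index=pd.Index(genome_ids, name="genome_id"),
        columns=pd.Index(sample_ids, name="sample_id"),
    )
    true_function_table = pd.DataFrame(
        copy_matrix.loc[:, genome_ids].to_numpy() @ abund,
        index=copy_matrix.index.copy(), columns=true_genome_table.columns.copy(),
    )

    queries: dict[str, str] = {}
    query_sources: dict[str, str] = {}
    for gid in genome_ids:
        ssu = pack.genomes[gid].ssu_sequences
        for v in range(config.queries_per_genome):
            template = np.frombuffer(
                ssu[int(rng.integers(len(ssu)))].encode("ascii"), dtype=np.uint8
            )
            observed = _mutate(template, config.query_error_rate, rng)
            observed = _indel(observed, config.query_indel_rate, rng)
            qid = f"ASV_{gid}_{v}"
            queries[qid] = _to_str(observed)
            query_sources[qid] = gid

    copies = np.array([pack.genomes[g].ssu_copy_number for g in genome_ids], float)
    pool = abund * copies[:, None]  # genome read-pool weights per sample
    per_query = np.repeat(pool, config.queries_per_genome, axis=0)
    per_query = per_query / config.queries_per_genome
    shares = per_query / per_query.sum(axis=0, keepdims=True)
    if config.deterministic_counts:
        counts = config.read_depth * shares
    else:
        counts = np.stack(
            [
                rng.multinomial(config.read_depth, shares[:, j]).astype(float)
                for j in range(config.n_samples)
            ],
            axis=1,
        )
    query_table = pd.DataFrame(
        counts, index=pd.Index(list(queries), name="query_id"),
        columns=pd.Index(sample_ids, name="sample_id"),
    )
    return CommunitySim(
        queries=queries,
        query_table=query_table,
        true_genome_table=true_genome_table,
        true_function_table=true_function_table,
        query_sources=query_sources,
        group_labels=group_labels,
        affected_genomes=affected,
    )


@dataclass
class BenchmarkBundle:
    """Everything one run needs: pack, community, ground truth, manifest."""

    config: SimulationConfig
    pack: ReferencePack
    copy_matrix: pd.DataFrame
    community: CommunitySim
    manifest: dict


def simulate_benchmark(
    config: SimulationConfig | None = None,
    out_dir: str | Path | None = None,
) -> BenchmarkBundle:
    """One-call fixture: pack + community + manifest, optionally written out.

    When ``out_dir`` is given, writes the exact file formats the pipeline
    consumes (serialized pack, queries.fasta, query_table.csv, ground-truth
    CSVs) plus ``manifest.json`` recording the full configuration and seed.
    """
    config = config or SimulationConfig()
    pack, copy_matrix = simulate_reference_pack(config)
    community = simulate_community(pack, config, copy_matrix)
    manifest = {
        "generator": "piphillin.synthetic",
        "config": _config_to_json(config),
        "seed": config.random_seed,
        "n_queries": len(community.queries),
    }
    bundle = BenchmarkBundle(
        config=config, pack=pack, copy_matrix=copy_matrix,
        community=community, manifest=manifest,
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def _config_to_json(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["copy_number_range"] = list(d["copy_number_range"])
    d["length_bounds"] = list(d["length_bounds"])
    return d


def config_from_mapping(mapping: Mapping) -> SimulationConfig:
    """Rebuild a :class:`SimulationConfig` from a manifest's config mapping."""
    d = dict(mapping)
    d["copy_number_range"] = tuple(d["copy_number_range"])
    d["length_bounds"] = tuple(d["length_bounds"])
    return SimulationConfig(**d)


def write_bundle(bundle: BenchmarkBundle, out_dir: str | Path) -> dict[str, Path]:
    from .refpack import save_pack  # local import to avoid cycle at module load

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pack": out_dir / "pack",
        "queries": out_dir / "queries.fasta",
        "query_table": out_dir / "query_table.csv",
        "true_genome_table": out_dir / "true_genome_table.csv",
        "true_function_table": out_dir / "true_function_table.csv",
        "manifest": out_dir / "manifest.json",
    }
    save_pack(bundle.pack, paths["pack"])
    records = [
        SeqRecord(Seq(seq), id=qid, description="")
        for qid, seq in bundle.community.queries.items()
    ]
    SeqIO.write(records, str(paths["queries"]), "fasta")
    bundle.community.query_table.to_csv(paths["query_table"])
    bundle.community.true_genome_table.to_csv(paths["true_genome_table"])
    bundle.community.true_function_table.to_csv(paths["true_function_table"])
    manifest = dict(bundle.manifest)
    if bundle.community.group_labels:
        manifest["group_labels"] = bundle.community.group_labels
        manifest["affected_genomes"] = list(bundle.community.affected_genomes)
    paths["manifest"].write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return paths
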