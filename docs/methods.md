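# Methods

## The problem and the model

16S rRNA gene amplicon sequencing reports which taxa are present in a
microbial community but not what their genomes can do. This package predicts
a community's metagenomic functional content from amplicon data alone, under
a deliberately simple model: each representative amplicon sequence (a
DADA2-style ASV or a 97% OTU representative) is assumed to originate from
the sequenced genome whose 16S rRNA gene it most closely resembles. Given a
*reference pack* — a collection of genomes, each with its length-filtered
16S gene sequences, the resulting 16S copy number, and a vector of function
copy counts (KO-like or RXN-like) — the pipeline is, per sample *s*:

1. **Nearest-neighbor assignment.** Each query *q* is aligned against every
   16S sequence of every genome; the genome(s) achieving the maximal percent
   identity are the inferred source, accepted only if that identity reaches
   the cutoff *c*. Queries below the cutoff are reported as failed, never
   silently dropped — the fraction of read mass passing the cutoff is itself
   a monitored result.
2. **Copy-number normalization.** Amplicon counts scale with the number of
   16S gene copies per genome, so genome abundance is

       a_g(s) = [ Σ_q share(q, g) · n_q(s) ] / k_g

   where `n_q(s)` is the query's count, `k_g` the genome's 16S copy number,
   and `share` divides a query's counts equally among genomes tied at the
   maximal identity (tie policy `split`; policy `first` gives everything to
   the lexicographically smallest genome id).
3. **Function summarization.** Function abundance is the matrix product
   `F = C · A` with `C` the functions × genomes copy-count matrix; the
   per-genome contribution table stores every term `C_fg · a_g(s)` so that
   marginalizing over genomes reproduces `F` exactly.

The method carries the usual caveats of nearest-neighbor functional
prediction: it can only see functions present in the reference pack, and a
query whose true source genome is unsequenced is attributed to its closest
sequenced relative.

## Reference packs

Packs are built from per-genome 16S FASTA input (either one file per genome
or a combined file with `genomeID|seqN` headers) and a long-form function
copy table `(genome_id, function_id, copies)`. 16S sequences are filtered to
an inclusive length window, default **[1400, 1600] bp** — roughly
full-length genes, excluding fragments and mis-annotations. The count of
surviving sequences defines the genome's 16S copy number. Genomes with no
surviving 16S are excluded (they could never be matched and would corrupt
normalization); genomes with 16S but no function rows are an error. One pack
carries exactly one function namespace; mixing KO-like and RXN-like
summaries in one pack is rejected. Packs serialize to a plain-text directory
(JSON manifest, FASTA, TSV) with a format version stamp; loading verifies
the manifest against the files so truncation is an error, not a partial
pack.

The extraction recipes for commercial genome databases (16S gene IDs from
per-genome gene tables, reaction-level summaries) are intentionally not
implemented; the pack format is the generic equivalent of their output.

## Percent identity

Identity is computed from a global pairwise DNA alignment:

    identity = 100 · matching columns / aligned columns

* **Alignment space.** End-to-end alignment that may leave an unaligned
  prefix of *one* sequence and an unaligned suffix of *one* sequence
  (semi-global). Those terminal runs are excluded from the column count, so
  a perfect amplicon fragment of a full-length gene scores 100%.
* **Terminal-gap penalty.** Terminal residues cost a small score penalty
  (default −1 each). Making them fully free looks harmless but degenerates:
  for dissimilar pairs the score-optimal alignment collapses to a few
  perfectly matching overlap columns and reports near-100% identity,
  corrupting both ranking and cutoff semantics. The small penalty steers the
  optimum to spanning alignments while leaving fragment behavior intact.
* **Well-defined optimum.** Among all alignments the optimum maximizes
  (score, matching columns, −columns) lexicographically. Because all three
  keys are additive along an alignment, this is solvable by dynamic
  programming, and the identity of a pair is a single well-defined number
  that any correct implementation must reproduce exactly — the test suite
  checks the production kernel against an independent pure-Python
  implementation, and ties across genomes compare exactly (equal rationals
  divide to equal floats).
* **Scoring defaults.** match +2, mismatch −3, gap −5 per column (linear),
  terminal −1 per residue. Substitutions are favored over gaps, matching the
  substitution-dominated error structure of denoised amplicons. A linear gap
  model (rather than affine) keeps the three-key objective implementable in
  a single packed-integer DP.
* **Character semantics.** Case-insensitive, U≡T. Degenerate IUPAC codes are
  accepted but match only themselves (N vs A is a mismatch) — conservative
  and deterministic. No reverse-complement search by default; inputs are
  assumed consistently oriented.
* **Kernel.** The DP packs (score, matches, columns) into one int64 per cell
  (numba-compiled, ~3 × 10⁸ cells/s), so a 1.5 kb × 1.5 kb alignment takes
  ~8 ms. Sequences up to 16 kb are supported by the packing.

## Search strategy

`PackIndex` deduplicates identical 16S sequences across genomes (intra-pack
copies are identical in the default simulation, and near-identical in real
genomes) and shortlists candidates by counting shared 8-mers. By default
(`max_candidates=None`) every sequence sharing at least one 8-mer is
aligned, and a query sharing no 8-mer with any reference falls back to
exhaustive alignment — at 16S-scale divergence this is lossless in practice.
A finite `max_candidates` caps the shortlist (keeping ties at the cut) and
trades exactness for speed. `brute_force_best_hit` aligns against every
sequence unconditionally and serves as the oracle the production path is
tested against.

Cutoff defaults surfaced in the CLI follow the input type: **99%** for ASV
input, **96%** for OTU input; the cutoff is a free parameter over the
customary 75–100% grid. Assignment ranks genomes by the maximum identity
over each genome's 16S sequences.

## Evaluation statistics

* **Per-sample Spearman rho** between a predicted and an observed
  function-by-sample table is computed over the *union* of function ids,
  zero-filling features missing from either table, with average ranks for
  ties. A vector with fewer than two distinct values has no rank correlation
  and yields NaN rather than an error.
* **Differential-abundance concordance** consumes two DE tables
  (`function_id`, `log2_fold_change`, `adjusted_p`); DESeq2-style column
  names (`log2FoldChange`, `padj`) are accepted on import. With significance
  defined as adjusted p < α (default α = 0.2), features are classified over
  the union universe: TP significant in both, FP predicted-only, FN
  reference-only, TN neither. By default a true positive additionally
  requires log2 fold-change sign agreement (sign-discordant shared hits
  count as FP); `require_sign_agreement=False` gives the weaker
  significant-in-both rule. Neither variant is claimed to be the original
  benchmark's exact rule, which is why both are provided. Metrics follow the
  standard definitions FPR = FP/(FP+TN), TPR = TP/(TP+FN),
  BA = TPR/2 + (1−FPR)/2, precision = TP/(TP+FP); empty denominators yield
  NaN.
* **`simple_de_test`** is a transparent stand-in for an external DE engine:
  Mann-Whitney U (or Wilcoxon signed-rank in paired mode) per feature,
  log2 fold change of group means with a 0.5 pseudocount, Benjamini–Hochberg
  correction. Its output is labeled "NOT DESeq2" and it deliberately models
  no dispersion shrinkage; real benchmarking workflows should import DESeq2
  results instead.

## Synthetic data generator

The generator produces exactly the structure the method assumes, so every
pipeline stage is testable without any external database.

| parameter | default | meaning |
|---|---|---|
| `n_genomes` | 20 | genomes in the pack |
| `ssu_length` | 1500 bp | 16S gene length (inside the length filter) |
| `divergence_between_genomes` | 0.04 | per-site substitution probability from a shared ancestor |
| `copy_number_range` | 1–15 | uniform 16S copies per genome (bacterial range) |
| `copy_divergence` | 0 | intra-genome 16S copy variation |
| `n_functions`, `function_prevalence`, `mean_function_copies` | 100, 0.35, 2 | sparse function copy matrix (presence Bernoulli, copies 1 + Poisson) |
| `n_samples` | 6 | samples per community |
| `lognormal_sigma` | 1.0 | spread of per-sample genome abundances |
| `query_error_rate` | 0.005 | per-site substitution on observed amplicons |
| `query_indel_rate` | 0 | optional indels, to stress the aligner |
| `read_depth` | 50 000 | reads per sample (multinomial, or exact expected counts) |
| `planted_fold_change`, `n_affected_genomes` | 1, 0 | optional two-group design |

Genomes are independent mutations of one ancestor, so the expected pairwise
identity is (1−d)² + d²/3 per site (≈ 92.2% at d = 0.04; queries at 0.5%
error sit ≈ 99.5% from their own genome, keeping assignment well-posed at
the 99% cutoff). The amplicon pool weights each genome by abundance × copy
number; each genome emits `queries_per_genome` observed representative
sequences sharing its reads equally. All randomness flows through
`numpy.random.default_rng` seeded from one integer, so bundles are exactly
reproducible; the substitution-only default keeps expected identities
hand-derivable for oracle tests.

What the generator does **not** emulate: chimeras, PCR/primer bias,
platform-specific quality profiles, intra-genome 16S divergence by default,
fragment-length amplicons (queries are full-length genes), and real
phylogenetic correlation between gene content and 16S similarity. Passing
tests therefore demonstrate the correctness of the algorithmic machinery
and its self-consistency, not field accuracy on real communities — the
headline accuracies published for this class of method depend on commercial
reference databases and real shotgun data that are out of scope here.

## Numerical and design choices

* Counts become reals as soon as ties are split or copy numbers divide;
  all output tables are real-valued.
* Tie handling: `split` is the default to avoid systematic bias toward
  alphabetically early genome ids; exact float equality is a safe tie test
  because equal match/column ratios divide to identical doubles.
* Conservation identities hold to ~1e-12 relative: Σ_g a_g(s)·k_g equals
  the passing read mass per sample, and contribution marginals equal the
  function table.
* Degenerate inputs: an empty assignment set yields empty-but-well-formed
  downstream tables; constant vectors yield NaN correlations; zero
  denominators yield NaN metrics; cutoffs outside [0, 100] and negative
  table entries are validation errors.
* Determinism: identical inputs and configuration produce byte-identical
  outputs (sorted genome/function/sample orders everywhere); CLI manifests
  differ only in their timestamp.
* Problem sizes used by the bundled checks (oracle equivalence on 200
  queries × 50 genomes; recovery on the 20-genome default benchmark) were
  chosen so the whole suite runs on a laptop-class single core in a few
  minutes.

## Known limitations

* The identity definition, while standard in spirit (terminal gaps excluded
  from the denominator), is not bit-identical to any particular published
  search tool; cutoffs calibrated against one tool may shift marginally
  against another.
* Very short perfect overlaps between otherwise unrelated sequences can
  still outscore a poor spanning alignment and report high identity; with
  the default terminal penalty this requires pathologically dissimilar
  inputs far below any useful cutoff.
* `simple_de_test` is underpowered relative to negative-binomial DE engines
  at small n; it exists for self-contained testing, not inference.
* Genome assignment uses the per-genome *maximum* over its 16S copies;
  packs whose genomes carry highly divergent intra-genome copies are
  handled but were not the design center.
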