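"""Comparison statistics between predicted and observed function tables.

Two kinds of agreement are measured, mirroring how 16S-based functional
predictions are benchmarked against shotgun metagenomics:

* per-sample Spearman rank correlation between a predicted and an observed
  function-by-sample table, computed over the union of function ids with
  features missing from either table counted as zero abundance;
* concordance of differential-abundance (DE) calls: given two DE result
  tables (log2 fold change + BH-adjusted p per function), features are
  classified into TP/FP/TN/FN and summarized as false positive rate, true
  positive rate, balanced accuracy, and precision:

      FPR = FP / (FP + TN)          TPR = TP / (TP + FN)
      BA  = TPR / 2 + (1 - FPR) / 2 Precision = TP / (TP + FP)

DE results are consumed as tables so that any external caller (e.g. DESeq2
output) can be imported; :func:`simple_de_test` provides a transparent
rank-test stand-in for callers without an external DE engine. It is a
Mann-Whitney/Wilcoxon test with BH correction — explicitly NOT DESeq2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .refpack import ValidationError

DEFAULT_ALPHA = 0.2  # adjusted-p significance cutoff used throughout

DE_COLUMNS = ["function_id", "log2_fold_change", "adjusted_p"]
_DE_ALIASES = {"log2FoldChange": "log2_fold_change", "padj": "adjusted_p"}


def _as_de_frame(de: pd.DataFrame, label: str) -> pd.DataFrame:
    de = de.rename(columns=_DE_ALIASES)
    missing = [c for c in DE_COLUMNS if c not in de.columns]
    if missing:
        raise ValidationError(f"{label}: missing DE columns {missing}")
    de = de[DE_COLUMNS].copy()
    de["function_id"] = de["function_id"].astype(str)
    if de["function_id"].duplicated().any():
        raise ValidationError(f"{label}: duplicate function ids")
    p = de["adjusted_p"].to_numpy(dtype=float)
    if np.nanmin(p, initial=0.0) < 0 or np.nanmax(p, initial=0.0) > 1:
        raise ValidationError(f"{label}: adjusted p-values outside [0, 1]")
    return de.set_index("function_id")


def per_sample_spearman(
    predicted: pd.DataFrame,
    observed: pd.DataFrame,
    sample_pairs: Mapping[str, str] | None = None,
) -> pd.Series:
    """Spearman rho per sample between two function-by-sample tables.

    The correlation for each sample is computed over the union of function
    ids of the two tables, with features absent from either table zero-filled
    before ranking; ties receive average ranks (scipy default). Samples must
    match by id unless an explicit ``sample_pairs`` map (predicted sample ->
    observed sample) is supplied. A sample in which either vector has fewer
    than two distinct values has no defined rank correlation and yields NaN.
    """
    if sample_pairs is None:
        if set(predicted.columns) != set(observed.columns):
            raise ValidationError(
                "sample id sets differ; supply sample_pairs to pair them "
                f"(predicted-only: {sorted(set(predicted.columns) - set(observed.columns))[:3]}, "
                f"observed-only: {sorted(set(observed.columns) - set(predicted.columns))[:3]})"
            )
        sample_pairs = {s: s for s in predicted.columns}
    features = sorted(set(predicted.index) | set(observed.index))
    pred = predicted.reindex(features).fillna(0.0)
    obs = observed.reindex(features).fillna(0.0)
    rhos: dict[str, float] = {}
    for ps, os_ in sample_pairs.items():
        x = pred[ps].to_numpy(dtype=float)
        y = obs[os_].to_numpy(dtype=float)
        if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
            rhos[ps] = math.nan
            continue
        rhos[ps] = float(sps.spearmanr(x, y).statistic)
    return pd.Series(rhos, name="spearman_rho")


@dataclass(frozen=True)
class ConcordanceCounts:
    """Confusion counts between predicted and reference DE calls."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError(f"negative confusion counts: {self}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def classify_concordance(
    pred_de: pd.DataFrame,
    ref_de: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    require_sign_agreement: bool = True,
) -> ConcordanceCounts:
    """Classify every function in the union of the two DE tables.

    A feature is significant in a table when its adjusted p-value is < alpha;
    features absent from a table are non-significant there. TP = significant
    in both (and, when ``require_sign_agreement``, with the same log2
    fold-change sign); FP = significant in the prediction only, or
    significant in both with discordant sign when sign agreement is required;
    FN = significant in the reference only; TN = significant in neither.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValidationError(f"alpha must be in (0, 1], got {alpha}")
    pred = _as_de_frame(pred_de, "predicted DE table")
    ref = _as_de_frame(ref_de, "reference DE table")
    universe = sorted(set(pred.index) | set(ref.index))
    tp = fp = tn = fn = 0
    for fid in universe:
        p_sig = fid in pred.index and pred.at[fid, "adjusted_p"] < alpha
        r_sig = fid in ref.index and ref.at[fid, "adjusted_p"] < alpha
        if p_sig and r_sig:
            if require_sign_agreement and np.sign(
                pred.at[fid, "log2_fold_change"]
            ) != np.sign(ref.at[fid, "log2_fold_change"]):
                fp += 1
            else:
                tp += 1
        elif p_sig:
            fp += 1
        elif r_sig:
            fn += 1
        else:
            tn += 1
    return ConcordanceCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def concordance_metrics(counts: ConcordanceCounts) -> dict[str, float]:
    """FPR, TPR, balanced accuracy and precision from confusion counts.

    Zero-denominator cases (e.g. no positives in the reference) yield NaN
    rather than raising; balanced accuracy is NaN if either component is.
    """
    tpr = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else math.nan
    fpr = counts.fp / (counts.fp + counts.tn) if counts.fp + counts.tn else math.nan
    precision = (
        counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else math.nan
    )
    ba = tpr / 2 + (1 - fpr) / 2
    return {
        "FPR": fpr,
        "TPR": tpr,
        "balanced_accuracy": ba,
        "precision": precision,
    }


DE_METHOD_LABEL = "two-group rank test with BH correction (NOT DESeq2)"


def simple_de_test(
    table: pd.DataFrame,
    group_labels: Mapping[str, str] | pd.Series,
    paired: bool = False,
    pairing: Mapping[str, str] | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Transparent two-group differential-abundance stand-in.

    Per feature: an unpaired Mann-Whitney U test (or Wilcoxon signed-rank in
    paired mode, which requires a ``pairing`` map from group-A samples to
    group-B samples), a log2 fold change of group means computed with a
    pseudocount, and Benjamini-Hochberg adjusted p-values. Groups are ordered
    lexicographically by label; the fold change is of the second group
    relative to the first. This is a deliberately simple rank test — results
    are labeled as such and must not be presented as DESeq2 output.
    """
    labels = pd.Series(dict(group_labels)) if not isinstance(
        group_labels, pd.Series
    ) else group_labels
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValidationError(f"need exactly 2 groups, got {groups}")
    a_samples = sorted(labels.index[labels == groups[0]])
    b_samples = sorted(labels.index[labels == groups[1]])
    if min(len(a_samples), len(b_samples)) < 2:
        raise ValidationError("each group needs at least 2 samples")
    missing = sorted((set(a_samples) | set(b_samples)) - set(table.columns))
    if missing:
        raise ValidationError(f"labeled samples absent from table: {missing}")
    if paired:
        if pairing is None:
            raise ValidationError("paired mode requires a pairing map")
        a_samples = sorted(pairing)
        b_samples = [pairing[s] for s in a_samples]

    a = table[a_samples].to_numpy(dtype=float)
    b = table[b_samples].to_numpy(dtype=float)
    raw_p = np.ones(len(table))
    for i in range(len(table)):
        if paired:
            diffs = b[i] - a[i]
            if np.all(diffs == 0):
                raw_p[i] = 1.0
            else:
                raw_p[i] = float(sps.wilcoxon(a[i], b[i]).pvalue)
        else:
            if np.all(a[i] == a[i, 0]) and np.all(b[i] == a[i, 0]):
                raw_p[i] = 1.0
            else:
                raw_p[i] = float(sps.mannwhitneyu(a[i], b[i]).pvalue)
    adjusted = multipletests(raw_p, method="fdr_bh")[1]
    lfc = np.log2((b.mean(axis=1) + pseudocount) / (a.mean(axis=1) + pseudocount))
    out = pd.DataFrame(
        {
            "function_id": table.index.astype(str),
            "log2_fold_change": lfc,
            "p_value": raw_p,
            "adjusted_p": adjusted,
        }
    ).reset_index(drop=True)
    out.attrs["method"] = DE_METHOD_LABEL
    out.attrs["groups"] = groups
    return out


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    """Write a DE result TSV with the method recorded as a comment header."""
    path = Path(path)
    method = de.attrs.get("method", "external")
    with path.open("w") as fh:
        fh.write(f"# method: {method}\n")
        de.to_csv(fh, sep="\t", index=False)


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a DE result TSV; accepts DESeq2-style column names."""
    de = pd.read_csv(path, sep="\t", comment="#")
    return _as_de_frame(de, str(path)).reset_index()
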