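"""Replicated expression pipeline: normalization, fold changes, DE calls, binning.

The pipeline mirrors a standard two-group microarray workflow with unequal
replicate numbers (e.g. 4 control vs. 3 mutant arrays): probe-to-gene
summarization by arithmetic mean, quantile normalization on the linear
scale, log2 transform, per-gene Welch t-tests, classification of genes as
up/down-regulated at |log2FC| >= 1 and P < 0.05, and stratification of the
up/down fractions by control-strain expression level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CONTROL = "control"
MUTANT = "mutant"

REG_UP = "up"
REG_DOWN = "down"
REG_UNCHANGED = "unchanged"


@dataclass
class SignalMatrix:
    """Genes x samples intensity table with group labels.

    ``values`` is a DataFrame (rows = gene or probe ids, columns = sample
    ids). ``groups`` maps each sample id to 'control' or 'mutant'.
    Intensities are linear and non-negative until :func:`log2_transform`
    sets ``log2_transformed``.
    """

    values: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)
    log2_transformed: bool = False

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("SignalMatrix must not contain missing cells")
        if self.groups:  # empty mapping = unlabeled matrix (pre-grouping)
            unknown = [s for s in self.values.columns if s not in self.groups]
            if unknown:
                raise ValueError(f"samples without a group label: {unknown}")
        bad = {g for g in self.groups.values()} - {CONTROL, MUTANT}
        if bad:
            raise ValueError(
                f"group labels must be {CONTROL!r} or {MUTANT!r}, got {sorted(bad)}"
            )
        if not self.log2_transformed and (self.values.to_numpy() < 0).any():
            raise ValueError("linear intensities must be non-negative")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def copy(self) -> "SignalMatrix":
        return SignalMatrix(
            values=self.values.copy(),
            groups=dict(self.groups),
            log2_transformed=self.log2_transformed,
        )


@dataclass(frozen=True)
class DEResult:
    """Per-gene differential-expression call."""

    gene_id: str
    log2fc: float
    pvalue: float
    reg_class: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError(f"pvalue outside [0,1]: {self.pvalue}")
        if self.reg_class not in (REG_UP, REG_DOWN, REG_UNCHANGED):
            raise ValueError(f"unknown regulation class {self.reg_class!r}")


def summarize_probes(
    probe_values: pd.DataFrame,
    probe_to_gene: Mapping[str, str],
    groups: Mapping[str, str] | None = None,
) -> SignalMatrix:
    """Collapse a probes x samples table to genes by per-gene mean intensity.

    Every probe must map to exactly one gene. Gene order in the output is
    sorted by gene id for determinism.
    """
    unmapped = [p for p in probe_values.index if p not in probe_to_gene]
    if unmapped:
        raise KeyError(f"probes without a gene mapping: {unmapped[:5]}")
    gene_of = pd.Series({p: probe_to_gene[p] for p in probe_values.index})
    summarized = probe_values.groupby(gene_of).mean().sort_index()
    return SignalMatrix(
        values=summarized,
        groups=dict(groups) if groups is not None else {},
        log2_transformed=False,
    )


def quantile_normalize(m: SignalMatrix) -> SignalMatrix:
    """Force all samples onto the mean-of-order-statistics reference distribution.

    After normalization every column has the same sorted values. Ties within
    a column receive the mean of the reference values their ranks span (the
    common dialect; dialects differ in tie handling, so this one is pinned
    here and in the docs).
    """
    if m.log2_transformed:
        logger.warning("quantile-normalizing log2-scale data; the default "
                       "pipeline normalizes on the linear scale")
    X = m.values.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if n_samples < 2:
        warnings.warn("quantile_normalize is a no-op with a single sample")
        return m.copy()
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(n_samples):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n_genes)
        assigned[order] = reference
        # ties: average the reference values the tied ranks span
        ser = pd.Series(assigned)
        out[:, j] = ser.groupby(col, sort=False).transform("mean").to_numpy()
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return SignalMatrix(values=values, groups=dict(m.groups),
                        log2_transformed=m.log2_transformed)


def log2_transform(m: SignalMatrix, floor: float = 1.0) -> SignalMatrix:
    """Replace intensities by log2(max(value, floor)).

    ``floor`` (default 1.0 linear intensity) guards against -inf at zero
    signal. Transforming twice is a state error.
    """
    if m.log2_transformed:
        raise ValueError("SignalMatrix is already log2-transformed")
    if floor <= 0:
        raise ValueError("floor must be > 0")
    values = np.log2(m.values.clip(lower=floor))
    return SignalMatrix(values=values, groups=dict(m.groups), log2_transformed=True)


def _require_groups(m: SignalMatrix, min_reps: int = 1) -> tuple[list[str], list[str]]:
    ctrl = m.samples_in(CONTROL)
    mut = m.samples_in(MUTANT)
    if not ctrl or not mut:
        raise ValueError("both 'control' and 'mutant' groups are required")
    if len(ctrl) < min_reps or len(mut) < min_reps:
        raise ValueError(f"need at least {min_reps} replicates per group")
    return ctrl, mut


def compute_fold_change(m: SignalMatrix) -> pd.Series:
    """Per-gene log2 fold change: mean(mutant) - mean(control) on log2 scale."""
    if not m.log2_transformed:
        raise ValueError("compute_fold_change requires log2-scale data")
    ctrl, mut = _require_groups(m)
    fc = m.values[mut].mean(axis=1) - m.values[ctrl].mean(axis=1)
    fc.name = "log2fc"
    return fc


def test_differential(m: SignalMatrix) -> pd.Series:
    """Two-sided Welch t-test per gene (mutant vs. control replicates).

    Degenerate genes — zero variance in both groups — get p = 1 when the
    group means are equal and p = 0 otherwise.
    """
    if not m.log2_transformed:
        raise ValueError("test_differential requires log2-scale data")
    ctrl, mut = _require_groups(m, min_reps=2)
    a = m.values[mut].to_numpy(dtype=float)
    b = m.values[ctrl].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-identical replicate vectors trigger a scipy precision warning;
        # degenerate genes are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        pvals = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(pvals)
    if degenerate.any():
        equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
        pvals[degenerate & equal_means] = 1.0
        pvals[degenerate & ~equal_means] = 0.0
    out = pd.Series(pvals, index=m.values.index, name="pvalue")
    return out


def classify_de(
    log2fc: pd.Series | Sequence[float],
    pvalue: pd.Series | Sequence[float],
    fc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.Series:
    """Classify genes as up / down / unchanged.

    A gene is 'up' iff log2FC >= fc_threshold and P < alpha, 'down' iff
    log2FC <= -fc_threshold and P < alpha. The fold-change boundary is
    inclusive, the significance boundary exclusive.
    """
    if fc_threshold <= 0:
        raise ValueError("fc_threshold must be > 0")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0,1)")
    fc = pd.Series(log2fc)
    p = pd.Series(pvalue)
    if isinstance(log2fc, pd.Series) and isinstance(pvalue, pd.Series):
        p = p.reindex(fc.index)
    sig = p < alpha
    out = pd.Series(REG_UNCHANGED, index=fc.index, name="reg_class", dtype=object)
    out[sig & (fc >= fc_threshold)] = REG_UP
    out[sig & (fc <= -fc_threshold)] = REG_DOWN
    return out


def benjamini_hochberg(pvalues: pd.Series) -> pd.Series:
    """Benjamini-Hochberg adjusted p-values (optional, off by default)."""
    p = pd.Series(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p.to_numpy(), kind="mergesort")
    ranked = p.to_numpy()[order] * n / (np.arange(n) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adjusted, 0.0, 1.0)
    return pd.Series(out, index=p.index, name="padj")


def run_de(
    m: SignalMatrix,
    fc_threshold: float = 1.0,
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Full DE table: log2fc, pvalue, reg_class per gene (log2-scale input)."""
    fc = compute_fold_change(m)
    p = test_differential(m)
    p_used = benjamini_hochberg(p) if adjust else p
    cls = classify_de(fc, p_used, fc_threshold=fc_threshold, alpha=alpha)
    return pd.DataFrame({"log2fc": fc, "pvalue": p_used, "reg_class": cls})


def estimate_expression_level(m: SignalMatrix) -> pd.Series:
    """Per-gene expression level: mean of log2 signal over control replicates."""
    if not m.log2_transformed:
        raise ValueError("estimate_expression_level requires log2-scale data")
    ctrl = m.samples_in(CONTROL)
    if not ctrl:
        raise ValueError("control group is required")
    level = m.values[ctrl].mean(axis=1)
    level.name = "level"
    return level


def default_bin_edges(levels: pd.Series | Sequence[float]) -> np.ndarray:
    """Unit-width integer bin edges spanning the observed level range."""
    arr = np.asarray(levels, dtype=float)
    lo = int(np.floor(arr.min()))
    hi = int(np.ceil(arr.max()))
    if hi == lo:
        hi = lo + 1
    return np.arange(lo, hi + 1, dtype=float)


def bin_by_expression(
    levels: pd.Series,
    edges: Sequence[float],
) -> pd.Series:
    """Label each gene with its half-open expression bin [e_i, e_{i+1}).

    Values below the first edge / at or above the last edge go to open-ended
    bins. Edges must be strictly increasing.
    """
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise ValueError("edges must be a strictly increasing 1-D sequence")
    labels = bin_labels(edges)
    idx = np.searchsorted(edges, np.asarray(levels, dtype=float), side="right")
    out = pd.Series(
        pd.Categorical.from_codes(idx, categories=labels, ordered=True),
        index=levels.index,
        name="bin_label",
    )
    return out


def bin_labels(edges: Sequence[float]) -> list[str]:
    edges = np.asarray(edges, dtype=float)

    def fmt(x: float) -> str:
        return f"{x:g}"

    labels = [f"(-inf,{fmt(edges[0])})"]
    labels += [f"[{fmt(a)},{fmt(b)})" for a, b in zip(edges[:-1], edges[1:])]
    labels.append(f"[{fmt(edges[-1])},inf)")
    return labels


def summarize_de_by_bin(
    de: pd.DataFrame,
    levels: pd.Series,
    bins: pd.Series,
) -> pd.DataFrame:
    """Per-bin counts and percent up/down-regulated genes.

    ``de`` must carry a 'reg_class' column; ``levels`` and ``bins`` are
    gene-indexed. Empty bins are reported with n_genes = 0 and NaN
    percentages.
    """
    if set(de.index) != set(levels.index) or set(de.index) != set(bins.index):
        raise ValueError("de, levels and bins must cover the same gene set")
    bins = bins.reindex(de.index)
    levels = levels.reindex(de.index)
    rows = []
    categories = (
        bins.cat.categories if isinstance(bins.dtype, pd.CategoricalDtype)
        else sorted(bins.unique())
    )
    for label in categories:
        mask = (bins == label).to_numpy()
        n = int(mask.sum())
        if n == 0:
            rows.append((label, 0, np.nan, np.nan, np.nan))
            continue
        cls = de.loc[mask, "reg_class"]
        pct_up = 100.0 * (cls == REG_UP).sum() / n
        pct_down = 100.0 * (cls == REG_DOWN).sum() / n
        rows.append((label, n, pct_up, pct_down, float(levels[mask].mean())))
    return pd.DataFrame(
        rows, columns=["bin_label", "n_genes", "pct_up", "pct_down", "mean_level"]
    )


def top_expressed_overlap(
    levels_a: pd.Series,
    levels_b: pd.Series,
    n: int = 100,
) -> float:
    """Percent overlap between the top-n most highly expressed gene lists.

    Used to compare expression-level rankings from raw vs. normalized
    signal. Ties at rank n are broken by gene id for determinism.
    """
    if set(levels_a.index) != set(levels_b.index):
        raise ValueError("the two rankings must share a gene universe")
    if n > len(levels_a):
        raise ValueError(f"n={n} exceeds the gene count {len(levels_a)}")

    def top_n(levels: pd.Series) -> set[str]:
        df = pd.DataFrame(
            {"level": np.asarray(levels), "gene_id": list(levels.index)}
        )
        df = df.sort_values(["level", "gene_id"], ascending=[False, True],
                            kind="mergesort")
        return set(df["gene_id"].iloc[:n])

    return 100.0 * len(top_n(levels_a) & top_n(levels_b)) / n


def count_by_category(
    de: pd.DataFrame,
    categories: pd.Series,
) -> pd.DataFrame:
    """Tally up/down calls per externally supplied functional category.

    Categories are an accepted input column (e.g. database annotations),
    never computed here.
    """
    cats = categories.reindex(de.index)
    tab = pd.crosstab(cats, de["reg_class"])
    for col in (REG_UP, REG_DOWN, REG_UNCHANGED):
        if col not in tab.columns:
            tab[col] = 0
    return tab[[REG_UP, REG_DOWN, REG_UNCHANGED]]
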