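"""Seeded generators for promoter sets and replicated expression matrices.

Both generators emit a ground-truth table next to the data so recovery can
be scored exactly: planted -10/-35 offsets, spacers and extended -10 flags
for promoters; planted log2 fold changes and DE labels for expression.
Defaults mirror the experimental design the package targets — 60-nt
upstream windows with a -10 element inside -14..-5 and a 16-18 nt spacer,
and a 4-control vs. 3-mutant replicate structure with log-normal
intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from omegatx.expression import CONTROL, MUTANT, SignalMatrix
from omegatx.io_formats import PromoterSet
from omegatx.motif import (
    DEFAULT_MINUS10_WINDOW,
    DEFAULT_WIDTH,
    admissible_offsets_minus10,
)

BASES = "ACGT"


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be in [0,1], got {p}")


@dataclass
class PromoterSimConfig:
    """Parameters of the planted-promoter generator.

    ``conservation`` is the per-position probability of emitting the
    consensus base inside each planted element (the remaining mass is split
    evenly over the other three bases). Offsets are drawn from
    ``offset_distribution`` over the admissible -10 starts, spacers from
    ``spacer_distribution`` over 16..18. ``extended10_prob`` plants a TG
    dinucleotide immediately 5' of the -10; ``spacer_at_bias`` and
    ``background_at`` set the A+T probability inside the spacer and
    elsewhere.
    """

    n_seqs: int = 100
    L: int = 60
    minus10_consensus: str = "TATAAT"
    minus35_consensus: str = "TTGACA"
    conservation: float = 0.9
    offset_distribution: Mapping[int, float] | None = None  # None = uniform
    spacer_distribution: Mapping[int, float] | None = None  # None = uniform 16-18
    extended10_prob: float = 0.0
    spacer_at_bias: float = 0.5
    background_at: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        _check_prob("conservation", self.conservation)
        _check_prob("extended10_prob", self.extended10_prob)
        _check_prob("spacer_at_bias", self.spacer_at_bias)
        _check_prob("background_at", self.background_at)
        if self.n_seqs < 1:
            raise ValueError("n_seqs must be >= 1")
        width = len(self.minus10_consensus)
        min_start = min(admissible_offsets_minus10(L=self.L, width=width))
        deepest = min_start - 18 - len(self.minus35_consensus)
        if deepest < -self.L:
            raise ValueError(
                f"L={self.L} too short: the most upstream -35 start would be "
                f"{deepest}"
            )


@dataclass
class ExpressionSimConfig:
    """Parameters of the replicated-expression generator.

    Gene base levels are normal on the log2 scale (default mean 10, sd 2.5,
    the shape of typical log2 microarray signal); replicate noise is
    additive log2 noise of sd ``noise_sd``. A ``de_fraction`` of genes gets
    a planted effect of magnitude ``effect_size`` in the mutant;
    ``level_coupling`` is the probability that a gene expressed above the
    median is planted *down* and one below the median *up*, coupling the
    direction of regulation to expression level.
    """

    n_genes: int = 2000
    reps: tuple[int, int] = (4, 3)  # (control, mutant)
    level_mean: float = 10.0
    level_sd: float = 2.5
    noise_sd: float = 0.25
    de_fraction: float = 0.2
    effect_size: float = 2.0
    level_coupling: float = 0.8
    heavy_tail_df: float | None = None  # log-t levels when set
    seed: int = 0

    def __post_init__(self) -> None:
        _check_prob("de_fraction", self.de_fraction)
        _check_prob("level_coupling", self.level_coupling)
        if min(self.reps) < 2:
            raise ValueError("need >= 2 replicates per group")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.noise_sd < 0 or self.effect_size < 0:
            raise ValueError("noise_sd and effect_size must be >= 0")


def _draw_categorical(
    rng: np.random.Generator,
    support: Sequence[int],
    dist: Mapping[int, float] | None,
    size: int,
) -> np.ndarray:
    if dist is None:
        probs = np.full(len(support), 1.0 / len(support))
    else:
        missing = set(dist) - set(support)
        if missing:
            raise ValueError(f"distribution over unsupported values: {missing}")
        probs = np.array([dist.get(v, 0.0) for v in support], dtype=float)
        if probs.sum() <= 0:
            raise ValueError("distribution has zero total mass")
        probs = probs / probs.sum()
    return rng.choice(np.asarray(support), size=size, p=probs)


def _random_bases(rng: np.random.Generator, n: int, at_prob: float) -> np.ndarray:
    p = np.array([at_prob / 2, (1 - at_prob) / 2, (1 - at_prob) / 2, at_prob / 2])
    return rng.choice(np.arange(4), size=n, p=p)


def _plant(
    rng: np.random.Generator,
    seq: np.ndarray,
    start_idx: int,
    consensus: str,
    conservation: float,
) -> None:
    for j, base in enumerate(consensus):
        c = BASES.index(base)
        if rng.random() < conservation:
            seq[start_idx + j] = c
        else:
            others = [b for b in range(4) if b != c]
            seq[start_idx + j] = others[int(rng.integers(3))]


def generate_promoters(
    cfg: PromoterSimConfig,
) -> tuple[PromoterSet, pd.DataFrame]:
    """Generate promoters with planted -10/-35 elements and return the truth.

    Truth columns: gene_id, minus10_start, minus35_start, spacer_len,
    extended10 (planted values, promoter-relative coordinates).
    """
    rng = np.random.default_rng(cfg.seed)
    width = len(cfg.minus10_consensus)
    starts = admissible_offsets_minus10(
        L=cfg.L, width=width, window=DEFAULT_MINUS10_WINDOW
    )
    m10_starts = _draw_categorical(rng, starts, cfg.offset_distribution, cfg.n_seqs)
    spacers = _draw_categorical(
        rng, [16, 17, 18], cfg.spacer_distribution, cfg.n_seqs
    )
    n_digits = max(4, len(str(cfg.n_seqs)))
    sequences: dict[str, str] = {}
    truth_rows = []
    for i in range(cfg.n_seqs):
        gene_id = f"g{i + 1:0{n_digits}d}"
        seq = _random_bases(rng, cfg.L, cfg.background_at)
        m10 = int(m10_starts[i])
        gap = int(spacers[i])
        m35 = m10 - gap - len(cfg.minus35_consensus)
        # spacer region with its own A+T bias
        gap_idx = m35 + len(cfg.minus35_consensus) + cfg.L
        seq[gap_idx:gap_idx + gap] = _random_bases(rng, gap, cfg.spacer_at_bias)
        _plant(rng, seq, m35 + cfg.L, cfg.minus35_consensus, cfg.conservation)
        _plant(rng, seq, m10 + cfg.L, cfg.minus10_consensus, cfg.conservation)
        extended = bool(rng.random() < cfg.extended10_prob)
        if extended:
            seq[m10 + cfg.L - 2] = BASES.index("T")
            seq[m10 + cfg.L - 1] = BASES.index("G")
        sequences[gene_id] = "".join(BASES[b] for b in seq)
        truth_rows.append((gene_id, m10, m35, gap, extended))
    truth = pd.DataFrame(truth_rows, columns=[
        "gene_id", "minus10_start", "minus35_start", "spacer_len", "extended10",
    ])
    return PromoterSet(sequences), truth


def generate_expression(
    cfg: ExpressionSimConfig,
) -> tuple[SignalMatrix, pd.DataFrame]:
    """Generate a linear-scale replicated signal matrix plus the DE truth.

    Truth columns: gene_id, level (planted log2 base level), is_de,
    true_log2fc.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    n_digits = max(4, len(str(n)))
    gene_ids = [f"g{i + 1:0{n_digits}d}" for i in range(n)]
    if cfg.heavy_tail_df is not None:
        levels = cfg.level_mean + cfg.level_sd * rng.standard_t(cfg.heavy_tail_df, n)
    else:
        levels = rng.normal(cfg.level_mean, cfg.level_sd, n)
    is_de = rng.random(n) < cfg.de_fraction
    high = levels > np.median(levels)
    follows_coupling = rng.random(n) < cfg.level_coupling
    # coupled: high-level genes go down, low-level genes go up
    sign = np.where(high == follows_coupling, -1.0, 1.0)
    true_fc = np.where(is_de, sign * cfg.effect_size, 0.0)
    n_ctrl, n_mut = cfg.reps
    columns = [f"CS_{r + 1}" for r in range(n_ctrl)] + [
        f"dRpoZ_{r + 1}" for r in range(n_mut)
    ]
    groups = {c: CONTROL for c in columns[:n_ctrl]}
    groups.update({c: MUTANT for c in columns[n_ctrl:]})
    log2_signal = np.empty((n, n_ctrl + n_mut))
    log2_signal[:, :n_ctrl] = levels[:, None]
    log2_signal[:, n_ctrl:] = (levels + true_fc)[:, None]
    if cfg.noise_sd > 0:
        log2_signal += rng.normal(0.0, cfg.noise_sd, log2_signal.shape)
    values = pd.DataFrame(
        np.exp2(log2_signal), index=pd.Index(gene_ids, name="gene_id"),
        columns=columns,
    )
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "level": levels,
        "is_de": is_de,
        "true_log2fc": true_fc,
    })
    return SignalMatrix(values=values, groups=groups), truth


def generate_probe_table(
    m: SignalMatrix,
    probes_per_gene: int = 3,
    probe_noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Expand a gene-level matrix to noisy probe replicates.

    Probe intensities are the gene intensity times 2^eps with eps ~
    N(0, probe_noise_sd) — multiplicative noise on the linear scale, so
    probe summarization by the arithmetic mean approximately inverts the
    expansion. Returns (probes x samples table, probe -> gene map).
    """
    if probes_per_gene < 1:
        raise ValueError("probes_per_gene must be >= 1")
    rng = np.random.default_rng(seed)
    gene_vals = m.values.to_numpy()
    n_genes, n_samples = gene_vals.shape
    probe_ids = []
    probe_to_gene = {}
    for g in m.values.index:
        for p in range(probes_per_gene):
            pid = f"{g}_p{p + 1}"
            probe_ids.append(pid)
            probe_to_gene[pid] = g
    expanded = np.repeat(gene_vals, probes_per_gene, axis=0)
    if probe_noise_sd > 0:
        expanded = expanded * np.exp2(
            rng.normal(0.0, probe_noise_sd, expanded.shape)
        )
    probes = pd.DataFrame(
        expanded, index=pd.Index(probe_ids, name="probe_id"),
        columns=m.values.columns,
    )
    return probes, probe_to_gene
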