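"""Constrained discovery of bacterial -10/-35 promoter elements.

Given fixed-length upstream sequences anchored at the TSS, the module
places, per sequence, a 6-nt -10 element whose start must lie so that the
element fits inside positions -14..-5, by maximizing the total information
content (in bits) of the resulting ungapped alignment; it then places a
6-nt -35 element separated from the -10 by a spacer of 16-18 nt, again by
information-content maximization. Information content per alignment column
is the Schneider logo statistic R_j = 2 - H_j, with H_j the Shannon entropy
of the column's base frequencies.

The search space per sequence is tiny (5 candidate -10 starts, 3 spacers),
so an exact exhaustive optimizer is used whenever the joint space
|choices|^N fits under a cap; otherwise seeded coordinate ascent with
random restarts (optionally Gibbs sampling) is used. Ties are broken by
preferring the most upstream offset per sequence, in lexicographic gene-id
order, so results are deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from omegatx.io_formats import PromoterSet

logger = logging.getLogger(__name__)

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_CODE["N"] = 4

LN2 = math.log(2.0)

DEFAULT_WIDTH = 6
DEFAULT_MINUS10_WINDOW = (-14, -5)
DEFAULT_CAP = 10 ** 7
_TOL = 1e-12
_MAX_SWEEPS = 500


@dataclass(frozen=True)
class SpacerConstraint:
    """Admissible spacer lengths between the -35 and -10 elements.

    The spacer counts nucleotides strictly between the 3' end of the -35
    element and the 5' start of the -10 element (canonical sigma70 spacing
    is ~17 nt).
    """

    min_gap: int = 16
    max_gap: int = 18

    def __post_init__(self) -> None:
        if not (0 <= self.min_gap <= self.max_gap):
            raise ValueError("need 0 <= min_gap <= max_gap")

    @property
    def gaps(self) -> list[int]:
        return list(range(self.min_gap, self.max_gap + 1))


@dataclass
class MotifAlignment:
    """An ungapped fixed-width element alignment with its logo statistics.

    ``offsets`` maps gene id -> element start in promoter-relative
    coordinates (e.g. -12 means the element occupies -12..-7). ``pfm`` holds
    per-position base counts (columns ordered A,C,G,T; N characters carry no
    count mass), ``freqs`` the column-normalized frequencies, ``ic`` the
    per-position information content in bits.
    """

    element_width: int
    offsets: dict[str, int]
    pfm: np.ndarray
    freqs: np.ndarray
    ic: np.ndarray
    total_ic: float
    strategy: str = "unspecified"
    verified_exhaustive: bool = False
    spacers: dict[str, int] | None = None

    @classmethod
    def from_offsets(
        cls,
        seqs: PromoterSet,
        offsets: Mapping[str, int],
        width: int = DEFAULT_WIDTH,
        pseudocount: float = 0.0,
        **meta,
    ) -> "MotifAlignment":
        if not offsets:
            raise ValueError("cannot build an alignment from zero sequences")
        pfm = np.zeros((width, 4), dtype=float)
        for gene_id, start in offsets.items():
            window = seqs.slice_relative(gene_id, start, width)
            for j, base in enumerate(window):
                if base != "N":
                    pfm[j, _CODE[base]] += 1.0
        denom = pfm.sum(axis=1, keepdims=True) + 4.0 * pseudocount
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs = (pfm + pseudocount) / denom
        freqs[denom[:, 0] == 0] = 0.25  # all-N column: uninformative
        ic = np.array([
            information_content(pfm[j]) if pfm[j].sum() > 0 else 0.0
            for j in range(width)
        ])
        return cls(
            element_width=width,
            offsets=dict(offsets),
            pfm=pfm,
            freqs=freqs,
            ic=ic,
            total_ic=float(ic.sum()),
            **meta,
        )

    def consensus(self) -> str:
        return "".join(BASES[j] for j in self.pfm.argmax(axis=1))

    def logo_table(self, correction: bool = False) -> pd.DataFrame:
        """Per-position logo matrix (element-relative positions 0..width-1)."""
        rows = []
        for j in range(self.element_width):
            counts = self.pfm[j]
            n = counts.sum()
            ic = information_content(counts, correction=correction) if n > 0 else 0.0
            rows.append([j, *counts, *self.freqs[j], ic])
        return pd.DataFrame(rows, columns=[
            "position",
            "count_A", "count_C", "count_G", "count_T",
            "freq_A", "freq_C", "freq_G", "freq_T",
            "ic",
        ])


def information_content(
    counts: Sequence[float],
    correction: bool = False,
) -> float:
    """Information content of one alignment column, in bits.

    With base frequencies f_b = count_b / n this is 2 + sum_b f_b log2 f_b
    (zero-frequency terms contribute 0). With ``correction=True`` the
    small-sample correction e(n) = 3 / (2 ln2 n) is subtracted; the
    corrected value can dip below 0 for small n.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (4,):
        raise ValueError("expected a length-4 count vector (A,C,G,T)")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    n = counts.sum()
    if n < 1:
        raise ValueError("column has no counts")
    f = counts / n
    nz = f > 0
    ic = 2.0 + float(np.sum(f[nz] * np.log2(f[nz])))
    if correction:
        ic -= 3.0 / (2.0 * LN2 * n)
    return ic


def admissible_offsets_minus10(
    L: int = 60,
    width: int = DEFAULT_WIDTH,
    window: tuple[int, int] = DEFAULT_MINUS10_WINDOW,
) -> list[int]:
    """Admissible -10 element start positions (promoter-relative).

    Starts s with s >= window[0] and s + width - 1 <= window[1]; the
    defaults give {-14, -13, -12, -11, -10}.
    """
    lo, hi = window
    if lo < -L or hi > -1 or lo > hi:
        raise ValueError(f"window {window} does not fit in a {L}-nt promoter")
    starts = [s for s in range(lo, hi + 1) if s + width - 1 <= hi]
    if not starts:
        raise ValueError(
            f"element of width {width} does not fit inside window {window}"
        )
    return starts


def window_ic(
    seqs: PromoterSet,
    offsets: Mapping[str, int],
    width: int = DEFAULT_WIDTH,
) -> float:
    """Total information content of the alignment induced by ``offsets``."""
    return MotifAlignment.from_offsets(seqs, offsets, width).total_ic


# ---------------------------------------------------------------------------
# optimizer internals


def _encode(seqs: PromoterSet, gene_ids: Sequence[str]) -> np.ndarray:
    L = seqs.length
    arr = np.empty((len(gene_ids), L), dtype=np.int8)
    for i, g in enumerate(gene_ids):
        arr[i] = [_CODE[b] for b in seqs[g]]
    return arr


def _contributions(
    encoded: np.ndarray,
    candidates: Sequence[Sequence[int]],
    width: int,
    L: int,
) -> list[np.ndarray]:
    """Per sequence, per candidate start: width x 4 one-hot count blocks."""
    out = []
    for i, cands in enumerate(candidates):
        block = np.zeros((len(cands), width, 4), dtype=np.float64)
        for k, start in enumerate(cands):
            idx = start + L
            codes = encoded[i, idx:idx + width]
            for j, c in enumerate(codes):
                if c < 4:
                    block[k, j, c] = 1.0
        out.append(block)
    return out


def _batch_total_ic(counts: np.ndarray) -> np.ndarray:
    """Total IC for a batch of count tensors shaped (..., width, 4)."""
    tot = counts.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = counts / tot[..., None]
        plogp = np.where(counts > 0, f * np.log2(f), 0.0)
    ic = 2.0 + plogp.sum(axis=-1)
    ic = np.where(tot > 0, ic, 0.0)
    return ic.sum(axis=-1)


def _score_assignment(contribs: list[np.ndarray], idx: Sequence[int]) -> float:
    counts = sum(contribs[i][k] for i, k in enumerate(idx))
    return float(_batch_total_ic(counts))


def _exhaustive(
    contribs: list[np.ndarray],
    chunk: int = 200_000,
) -> tuple[np.ndarray, float]:
    """Exact scan of every candidate combination.

    Combinations are enumerated with sequence 0 as the most significant
    digit and candidates in ascending-offset order, so the first argmax is
    the lexicographically smallest optimum — exactly the documented
    tie-break.
    """
    radices = [c.shape[0] for c in contribs]
    n_seqs = len(radices)
    total = 1
    for r in radices:
        total *= r
    width = contribs[0].shape[1]
    place = np.empty(n_seqs, dtype=np.int64)
    acc = 1
    for i in range(n_seqs - 1, -1, -1):
        place[i] = acc
        acc *= radices[i]
    best_score = -np.inf
    best_idx: np.ndarray | None = None
    for start in range(0, total, chunk):
        combos = np.arange(start, min(start + chunk, total), dtype=np.int64)
        counts = np.zeros((len(combos), width, 4), dtype=np.float64)
        digits = np.empty((len(combos), n_seqs), dtype=np.int64)
        for i in range(n_seqs):
            digits[:, i] = (combos // place[i]) % radices[i]
            counts += contribs[i][digits[:, i]]
        scores = _batch_total_ic(counts)
        k = int(np.argmax(scores))
        if scores[k] > best_score + _TOL:
            best_score = float(scores[k])
            best_idx = digits[k].copy()
    assert best_idx is not None
    return best_idx, best_score


def _coordinate_ascent(
    contribs: list[np.ndarray],
    init: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Greedy per-sequence updates until a local optimum.

    Accepts a move if it strictly improves the total IC, or keeps the score
    (within tolerance) while moving to a more upstream candidate — the
    latter drives the result toward the documented tie-break and cannot
    cycle because (score, index vector) improves lexicographically.
    """
    idx = np.asarray(init, dtype=np.int64).copy()
    counts = sum(contribs[i][idx[i]] for i in range(len(idx)))
    for _ in range(_MAX_SWEEPS):
        moved = False
        for i in range(len(idx)):
            base = counts - contribs[i][idx[i]]
            scores = _batch_total_ic(base[None] + contribs[i])
            cur = scores[idx[i]]
            k = int(np.argmax(scores))
            if scores[k] > cur + _TOL or (
                k < idx[i] and scores[k] >= cur - _TOL
            ):
                counts = base + contribs[i][k]
                idx[i] = k
                moved = True
        if not moved:
            break
    return idx, float(_batch_total_ic(counts))


def _gibbs(
    contribs: list[np.ndarray],
    rng: np.random.Generator,
    n_iter: int = 200,
    pseudocount: float = 0.5,
) -> tuple[np.ndarray, float]:
    """Leave-one-out Gibbs sampler; the best visited state is polished with
    coordinate ascent."""
    n_seqs = len(contribs)
    idx = np.array([int(rng.integers(c.shape[0])) for c in contribs])
    counts = sum(contribs[i][idx[i]] for i in range(n_seqs))
    best_idx, best_score = idx.copy(), float(_batch_total_ic(counts))
    for _ in range(n_iter):
        for i in rng.permutation(n_seqs):
            base = counts - contribs[i][idx[i]]
            f = (base + pseudocount) / (
                base.sum(axis=-1, keepdims=True) + 4.0 * pseudocount
            )
            # predictive log-likelihood of each candidate window
            loglik = (contribs[i] * np.log(f)[None]).sum(axis=(1, 2))
            w = np.exp(loglik - loglik.max())
            w /= w.sum()
            k = int(rng.choice(len(w), p=w))
            counts = base + contribs[i][k]
            idx[i] = k
        score = float(_batch_total_ic(counts))
        if score > best_score + _TOL:
            best_score, best_idx = score, idx.copy()
    return _coordinate_ascent(contribs, best_idx)


def _optimize(
    contribs: list[np.ndarray],
    strategy: str,
    restarts: int,
    rng: np.random.Generator,
    cap: int,
) -> tuple[np.ndarray, float, str, bool]:
    n_combos = 1.0
    for c in contribs:
        n_combos *= c.shape[0]
    if strategy == "auto":
        strategy = "exhaustive" if n_combos <= cap else "coordinate_ascent"
    if strategy == "exhaustive":
        if n_combos > cap:
            raise ValueError(
                f"exhaustive search over {n_combos:.3g} combinations exceeds "
                f"the cap ({cap}); use coordinate_ascent or gibbs"
            )
        idx, score = _exhaustive(contribs)
        return idx, score, "exhaustive", True
    if strategy == "coordinate_ascent":
        inits = [np.zeros(len(contribs), dtype=np.int64)]
        inits += [
            np.array([int(rng.integers(c.shape[0])) for c in contribs])
            for _ in range(max(restarts - 1, 0))
        ]
        best: tuple[float, tuple[int, ...]] | None = None
        for init in inits:
            idx, score = _coordinate_ascent(contribs, init)
            key = (score, tuple(-k for k in idx))
            if best is None or key > best:
                best = key
                best_idx = idx
        return best_idx, best[0], "coordinate_ascent", False
    if strategy == "gibbs":
        best = None
        for _ in range(max(restarts, 1)):
            idx, score = _gibbs(contribs, rng)
            key = (score, tuple(-k for k in idx))
            if best is None or key > best:
                best = key
                best_idx = idx
        return best_idx, best[0], "gibbs", False
    raise ValueError(f"unknown strategy {strategy!r}")


def _usable_genes(
    seqs: PromoterSet,
    candidates_of: Callable[[str], list[int]],
    width: int,
) -> list[str]:
    """Genes with at least one informative (not all-N) candidate window."""
    usable = []
    L = seqs.length
    for g in sorted(seqs.gene_ids):
        windows = [
            seqs[g][s + L: s + L + width] for s in candidates_of(g)
        ]
        if any(set(w) != {"N"} for w in windows):
            usable.append(g)
        else:
            logger.warning("excluding gene %s: all admissible windows are N-only", g)
    return usable


# ---------------------------------------------------------------------------
# public alignment API


def align_minus10(
    seqs: PromoterSet,
    width: int = DEFAULT_WIDTH,
    window: tuple[int, int] = DEFAULT_MINUS10_WINDOW,
    strategy: str = "auto",
    restarts: int = 20,
    seed: int = 0,
    cap: int = DEFAULT_CAP,
) -> MotifAlignment:
    """Place a -10 element per sequence inside the admissible window.

    The per-sequence start offsets jointly maximize the total information
    content of the width-nt alignment. ``strategy`` is 'exhaustive' (exact;
    requires |starts|^N <= cap), 'coordinate_ascent' or 'gibbs' (seeded
    heuristics keeping the best of ``restarts`` initializations), or 'auto'
    (exhaustive when it fits under the cap).
    """
    if len(seqs) == 0:
        raise ValueError("cannot align an empty promoter set")
    L = seqs.length
    starts = admissible_offsets_minus10(L=L, width=width, window=window)
    gene_ids = _usable_genes(seqs, lambda g: starts, width)
    if not gene_ids:
        raise ValueError("no usable sequences after N-filtering")
    encoded = _encode(seqs, gene_ids)
    contribs = _contributions(encoded, [starts] * len(gene_ids), width, L)
    rng = np.random.default_rng(seed)
    idx, score, used, exact = _optimize(contribs, strategy, restarts, rng, cap)
    offsets = {g: starts[k] for g, k in zip(gene_ids, idx)}
    aln = MotifAlignment.from_offsets(
        seqs, offsets, width, strategy=used, verified_exhaustive=exact
    )
    return aln


def align_minus35(
    seqs: PromoterSet,
    minus10: MotifAlignment,
    width: int = DEFAULT_WIDTH,
    spacer: SpacerConstraint = SpacerConstraint(),
    strategy: str = "auto",
    restarts: int = 20,
    seed: int = 0,
    cap: int = DEFAULT_CAP,
    spacer_mode: str = "gap",
) -> MotifAlignment:
    """Place a -35 element per sequence, 16-18 nt upstream of its -10.

    With ``spacer_mode='gap'`` (default) the constraint bounds the number
    of nucleotides strictly between the elements, so a -10 start m10 and
    gap g put the -35 start at m10 - g - width. The alternative reading
    ``spacer_mode='start_to_start'`` bounds the start-to-start distance.
    The -10 offsets are held fixed; spacers are chosen jointly to maximize
    the -35 alignment's information content.
    """
    if spacer_mode not in ("gap", "start_to_start"):
        raise ValueError(f"unknown spacer_mode {spacer_mode!r}")
    if not minus10.offsets:
        raise ValueError("minus10 alignment is empty")
    L = seqs.length
    gaps = spacer.gaps

    def candidates_of(g: str) -> list[int]:
        m10 = minus10.offsets[g]
        if spacer_mode == "gap":
            cands = [m10 - gap - width for gap in gaps]
        else:
            cands = [m10 - gap for gap in gaps]
        return sorted(cands)

    gene_ids = sorted(minus10.offsets)
    for g in gene_ids:
        for start in candidates_of(g):
            if start + L < 0:
                raise ValueError(
                    f"candidate -35 window at {start} runs off the promoter "
                    f"for gene {g!r} (L={L})"
                )
    gene_ids = _usable_genes(seqs.subset(gene_ids), candidates_of, width)
    if not gene_ids:
        raise ValueError("no usable sequences after N-filtering")
    cand_lists = [candidates_of(g) for g in gene_ids]
    encoded = _encode(seqs, gene_ids)
    contribs = _contributions(encoded, cand_lists, width, L)
    rng = np.random.default_rng(seed)
    idx, score, used, exact = _optimize(contribs, strategy, restarts, rng, cap)
    offsets = {g: cand_lists[i][k] for i, (g, k) in enumerate(zip(gene_ids, idx))}
    if spacer_mode == "gap":
        spacers = {g: minus10.offsets[g] - offsets[g] - width for g in gene_ids}
    else:
        spacers = {g: minus10.offsets[g] - offsets[g] for g in gene_ids}
    return MotifAlignment.from_offsets(
        seqs, offsets, width,
        strategy=used, verified_exhaustive=exact, spacers=spacers,
    )


def detect_extended_minus10(
    seqs: PromoterSet,
    minus10: MotifAlignment,
) -> tuple[float, dict[str, bool]]:
    """Fraction of promoters with a TG dinucleotide immediately 5' of the -10.

    The extended -10 motif (TG at positions start-2, start-1) strengthens
    sigma70-type promoters and is typical of highly expressed genes. N never
    matches. Returns (fraction, per-gene booleans).
    """
    L = seqs.length
    flags: dict[str, bool] = {}
    for g, start in minus10.offsets.items():
        if start - 2 + L < 0:
            raise ValueError(f"extended -10 check runs off the promoter for {g!r}")
        di = seqs.slice_relative(g, start - 2, 2)
        flags[g] = di == "TG"
    fraction = sum(flags.values()) / len(flags) if flags else 0.0
    return fraction, flags


def spacer_at_fraction(
    seqs: PromoterSet,
    minus10: MotifAlignment,
    minus35: MotifAlignment,
) -> tuple[float, dict[str, float]]:
    """A+T fraction of the spacer strictly between the -35 and -10 elements.

    Returns (mean over genes, per-gene fractions). N characters count
    toward the length but not toward A+T.
    """
    per_gene: dict[str, float] = {}
    for g in minus35.offsets:
        m10 = minus10.offsets[g]
        m35 = minus35.offsets[g]
        gap_start = m35 + minus35.element_width
        gap_len = m10 - gap_start
        if gap_len <= 0:
            raise ValueError(f"zero-length spacer for gene {g!r}")
        region = seqs.slice_relative(g, gap_start, gap_len)
        per_gene[g] = sum(b in "AT" for b in region) / gap_len
    aggregate = float(np.mean(list(per_gene.values()))) if per_gene else 0.0
    return aggregate, per_gene


def annotate_elements(
    seqs: PromoterSet,
    minus10: MotifAlignment,
    minus35: MotifAlignment,
    spacer: SpacerConstraint = SpacerConstraint(),
) -> pd.DataFrame:
    """Per-gene element table: -35 start, spacer length, -10 start,
    extended -10 flag and spacer A+T fraction.

    Geometry is re-validated: every spacer must lie inside the constraint
    and both elements inside the promoter.
    """
    _, ext = detect_extended_minus10(seqs, minus10)
    _, at = spacer_at_fraction(seqs, minus10, minus35)
    L = seqs.length
    w = minus10.element_width
    rows = []
    for g in sorted(minus35.offsets):
        m10, m35 = minus10.offsets[g], minus35.offsets[g]
        gap = m10 - (m35 + minus35.element_width)
        if not (spacer.min_gap <= gap <= spacer.max_gap):
            raise ValueError(f"spacer {gap} outside constraint for gene {g!r}")
        if m35 < -L or m10 + w - 1 > -1:
            raise ValueError(f"element outside promoter for gene {g!r}")
        rows.append((g, m35, gap, m10, ext[g], at[g]))
    return pd.DataFrame(rows, columns=[
        "gene_id", "minus35_start", "spacer_len", "minus10_start",
        "extended10", "spacer_at_fraction",
    ])


def build_logo(
    seqs: PromoterSet,
    minus10: MotifAlignment,
    minus35: MotifAlignment,
    flank: int = 3,
) -> pd.DataFrame:
    """Promoter logo matrix re-registered on the -10 element start.

    Aligned coordinate 0 is each gene's -10 start. Columns span from the
    most upstream -35 start minus ``flank`` to the -10 end plus ``flank``.
    Because spacers vary per gene, inter-element columns mix offsets; each
    column reports its own effective count. Output feeds
    :func:`omegatx.io_formats.write_logo_matrix`.
    """
    if set(minus10.offsets) != set(minus35.offsets):
        raise ValueError("-10 and -35 alignments cover different gene sets")
    L = seqs.length
    w = minus10.element_width
    rel35 = {g: minus35.offsets[g] - minus10.offsets[g] for g in minus35.offsets}
    lo = min(rel35.values()) - flank
    hi = w - 1 + flank
    rows = []
    for a in range(lo, hi + 1):
        counts = np.zeros(4)
        for g, m10 in minus10.offsets.items():
            pos = m10 + a
            if -L <= pos <= -1:
                base = seqs.slice_relative(g, pos, 1)
                if base != "N":
                    counts[_CODE[base]] += 1
        n = counts.sum()
        if n > 0:
            freqs = counts / n
            ic = information_content(counts)
        else:
            freqs = np.full(4, 0.25)
            ic = 0.0
        rows.append([a, *counts, *freqs, ic])
    return pd.DataFrame(rows, columns=[
        "position",
        "count_A", "count_C", "count_G", "count_T",
        "freq_A", "freq_C", "freq_G", "freq_T",
        "ic",
    ])


def compare_element_ic(
    alignment_a: MotifAlignment,
    alignment_b: MotifAlignment,
    seqs_a: PromoterSet | None = None,
    seqs_b: PromoterSet | None = None,
    n_perm: int = 0,
    seed: int = 0,
    aligner: Callable[[PromoterSet], MotifAlignment] | None = None,
) -> dict:
    """Compare total/per-position information content between two groups.

    Reports total_ic for each alignment, their difference (a - b), and the
    per-position differences. With ``n_perm`` > 0 and both promoter sets
    supplied, a permutation p-value is computed by shuffling group labels
    of the pooled promoters and realigning each permuted group with
    ``aligner`` (default: :func:`align_minus10` with coordinate ascent);
    the p-value is (1 + #{|perm diff| >= |observed|}) / (n_perm + 1).
    """
    if alignment_a.element_width != alignment_b.element_width:
        raise ValueError("alignments have different element widths")
    report = {
        "total_ic_a": alignment_a.total_ic,
        "total_ic_b": alignment_b.total_ic,
        "difference": alignment_a.total_ic - alignment_b.total_ic,
        "per_position_difference": (alignment_a.ic - alignment_b.ic).tolist(),
    }
    if n_perm > 0:
        if seqs_a is None or seqs_b is None:
            raise ValueError("permutation test needs both promoter sets")
        if aligner is None:
            def aligner(s: PromoterSet) -> MotifAlignment:
                return align_minus10(s, strategy="coordinate_ascent",
                                     restarts=3, seed=seed)
        pooled = {**{f"a::{g}": seqs_a[g] for g in seqs_a.gene_ids},
                  **{f"b::{g}": seqs_b[g] for g in seqs_b.gene_ids}}
        ids = list(pooled)
        n_a = len(seqs_a)
        rng = np.random.default_rng(seed)
        obs = abs(report["difference"])
        hits = 0
        for _ in range(n_perm):
            perm = rng.permutation(ids)
            grp_a = PromoterSet({g: pooled[g] for g in perm[:n_a]})
            grp_b = PromoterSet({g: pooled[g] for g in perm[n_a:]})
            d = aligner(grp_a).total_ic - aligner(grp_b).total_ic
            if abs(d) >= obs - _TOL:
                hits += 1
        report["perm_pvalue"] = (1 + hits) / (n_perm + 1)
        report["n_perm"] = n_perm
    return report
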