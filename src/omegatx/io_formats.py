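"""Readers/writers for the package's external formats and coordinate conventions.

Conventions enforced at this boundary:

* genome coordinates are 1-based inclusive;
* promoter-relative positions are negative integers ``-L..-1``, with ``-1``
  the nucleotide immediately 5' of the transcription start site (TSS); the
  TSS itself is excluded from the promoter window;
* promoter sequences are stored 5'->3' on the coding strand, so string
  index ``0`` is position ``-L`` and index ``L-1`` is position ``-1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from omegatx.expression import SignalMatrix

logger = logging.getLogger(__name__)

PROMOTER_ALPHABET = frozenset("ACGTN")

_LOGO_COLUMNS = [
    "position",
    "count_A", "count_C", "count_G", "count_T",
    "freq_A", "freq_C", "freq_G", "freq_T",
    "ic",
]


@dataclass(frozen=True)
class TSSRecord:
    """An experimentally determined transcription start site.

    ``tss`` is the 1-based genomic position of the first transcribed
    nucleotide on ``strand`` of replicon ``replicon_id``.
    """

    gene_id: str
    replicon_id: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        strand = "-" if self.strand in ("-", "−") else self.strand
        object.__setattr__(self, "strand", strand)
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 1:
            raise ValueError(f"tss must be >= 1 (1-based), got {self.tss}")


@dataclass
class PromoterSet:
    """Fixed-length upstream sequences anchored at the TSS.

    ``sequences`` maps gene id -> sequence over {A,C,G,T,N}; all sequences
    share the same length ``length``. Index 0 is position -L, index L-1 is
    position -1.
    """

    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned: dict[str, str] = {}
        length = None
        for gene_id, seq in self.sequences.items():
            seq = normalize_sequence(seq, gene_id)
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise ValueError(
                    f"length mismatch: record {gene_id!r} has length "
                    f"{len(seq)}, expected {length}"
                )
            cleaned[gene_id] = seq
        self.sequences = cleaned

    @property
    def length(self) -> int:
        if not self.sequences:
            raise ValueError("empty PromoterSet has no defined length")
        return len(next(iter(self.sequences.values())))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, gene_id: str) -> str:
        return self.sequences[gene_id]

    def subset(self, gene_ids: Iterable[str]) -> "PromoterSet":
        wanted = [g for g in gene_ids if g in self.sequences]
        return PromoterSet({g: self.sequences[g] for g in wanted})

    def slice_relative(self, gene_id: str, start: int, width: int) -> str:
        """Sequence at promoter-relative positions [start, start+width)."""
        L = self.length
        idx = start + L
        if idx < 0 or idx + width > L:
            raise ValueError(
                f"window [{start}, {start + width}) outside promoter "
                f"coordinates [-{L}, -1] for gene {gene_id!r}"
            )
        return self.sequences[gene_id][idx:idx + width]


def normalize_sequence(seq: str, record_id: str = "<anonymous>") -> str:
    """Uppercase, map U->T, and validate the {A,C,G,T,N} alphabet."""
    if not seq:
        raise ValueError(f"record {record_id!r} is empty")
    seq = str(seq).upper().replace("U", "T")
    illegal = set(seq) - PROMOTER_ALPHABET
    if illegal:
        raise ValueError(
            f"record {record_id!r} contains illegal characters: "
            f"{sorted(illegal)}"
        )
    return seq


def read_fasta(path: str | Path) -> PromoterSet:
    """Read a promoter FASTA into a :class:`PromoterSet`.

    Sequences are uppercased with U mapped to T; heterogeneous lengths or
    characters outside {A,C,G,T,N} raise ``ValueError``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    sequences: dict[str, str] = {}
    for rec in records:
        if rec.id in sequences:
            raise ValueError(f"duplicate gene id {rec.id!r} in {path}")
        sequences[rec.id] = str(rec.seq)
    return PromoterSet(sequences)


def write_fasta(promoters: PromoterSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=gene_id, description="")
        for gene_id, seq in promoters.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_tss_table(path: str | Path) -> list[TSSRecord]:
    """Read a TSS table (TSV: gene_id, replicon_id, strand, tss)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "replicon_id": str, "strand": str})
    required = {"gene_id", "replicon_id", "strand", "tss"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"TSS table missing columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids in TSS table: {dupes}")
    return [
        TSSRecord(r.gene_id, r.replicon_id, r.strand, int(r.tss))
        for r in df.itertuples(index=False)
    ]


def write_tss_table(records: Iterable[TSSRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.gene_id, r.replicon_id, r.strand, r.tss) for r in records],
        columns=["gene_id", "replicon_id", "strand", "tss"],
    )
    df.to_csv(path, sep="\t", index=False)


def extract_upstream(
    genome_sequences: Mapping[str, str],
    tss_table: Iterable[TSSRecord],
    length: int = 60,
    circular: bool = False,
) -> PromoterSet:
    """Extract ``length``-nt upstream sequences for each TSS.

    For strand '+' this is genomic positions [tss-length, tss-1]; for
    strand '-' the reverse complement of [tss+1, tss+length]. Windows
    running off a linear replicon end are dropped with a warning unless
    ``circular=True``, in which case they wrap.
    """
    sequences: dict[str, str] = {}
    for rec in tss_table:
        if rec.replicon_id not in genome_sequences:
            raise KeyError(
                f"replicon {rec.replicon_id!r} (gene {rec.gene_id!r}) "
                "not present in the genome"
            )
        genome = normalize_sequence(genome_sequences[rec.replicon_id], rec.replicon_id)
        G = len(genome)
        if rec.strand == "+":
            start0, end0 = rec.tss - length - 1, rec.tss - 1  # 0-based half-open
        else:
            start0, end0 = rec.tss, rec.tss + length
        if start0 < 0 or end0 > G:
            if not circular:
                logger.warning(
                    "dropping gene %s: upstream window runs off linear "
                    "replicon %s", rec.gene_id, rec.replicon_id,
                )
                continue
            doubled = genome + genome
            seq = doubled[start0 % G: start0 % G + length]
        else:
            seq = genome[start0:end0]
        if rec.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        sequences[rec.gene_id] = seq
    return PromoterSet(sequences)


def read_signal_table(
    path: str | Path,
    sample_map: Mapping[str, str],
) -> SignalMatrix:
    """Read a gene/probe x sample intensity TSV into a :class:`SignalMatrix`.

    The first column holds gene/probe ids; the header row holds sample ids,
    each of which must appear in ``sample_map`` (sample id -> group label).
    All entries must be numeric and non-negative; missing cells are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty signal table: {path}")
    unmapped = [s for s in df.columns if s not in sample_map]
    if unmapped:
        raise ValueError(f"samples missing from sample_map: {unmapped}")
    for col in df.columns:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(
                f"non-numeric or missing value at row {bad[0]!r}, "
                f"column {col!r} in {path}"
            )
    values = df.astype(float)
    if (values.to_numpy() < 0).any():
        raise ValueError(f"negative intensities found in {path}")
    groups = {s: sample_map[s] for s in values.columns}
    return SignalMatrix(values=values, groups=groups, log2_transformed=False)


def write_signal_table(m: SignalMatrix, path: str | Path) -> None:
    m.values.rename_axis("gene_id").to_csv(path, sep="\t")


def read_sample_map(path: str | Path) -> dict[str, str]:
    """Read a sample->group TSV with columns sample_id, group."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(df.columns):
        raise ValueError("sample map needs columns 'sample_id' and 'group'")
    return dict(zip(df["sample_id"], df["group"]))


def write_sample_map(sample_map: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(sample_map), "group": list(sample_map.values())}
    ).to_csv(path, sep="\t", index=False)


def write_logo_matrix(logo: pd.DataFrame, path: str | Path) -> None:
    """Write a logo matrix (one row per aligned position) as TSV.

    ``logo`` is the frame produced by :func:`omegatx.motif.build_logo` or
    :meth:`omegatx.motif.MotifAlignment.logo_table`: position label, base
    counts, base frequencies and per-position information content in bits.
    The file round-trips losslessly through :func:`read_logo_matrix`.
    """
    if logo is None or len(logo) == 0:
        raise ValueError("cannot write an empty logo matrix")
    missing = [c for c in _LOGO_COLUMNS if c not in logo.columns]
    if missing:
        raise ValueError(f"logo matrix missing columns: {missing}")
    logo.loc[:, _LOGO_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_logo_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _LOGO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"logo matrix missing columns: {missing}")
    return df
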