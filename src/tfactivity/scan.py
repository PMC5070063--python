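"""Promoter windows and strand-aware motif scanning over a parameter grid.

Coordinates are relative to the transcription start site (TSS) with half-open
interval semantics: position 0 is the first transcribed base, so a stored
span of [-1000, +200) holds 1200 bases and string index 0 corresponds to
TSS-relative position -1000.

Hit counting slides the motif one base at a time over the forward sequence
and over its reverse complement; every offset whose mat_sim score reaches the
threshold is a hit, overlapping hits included.  Prevalence downstream is the
expected hit density per promoter, so all hits count (a presence/absence
variant is available via ``binary=True``).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pwm import PWM, encode_complement, encode_sequence, sliding_scores

logger = logging.getLogger(__name__)

DEFAULT_SPAN = (-1000, 200)
DEFAULT_THRESHOLDS = (0.80, 0.90, 0.95)
DEFAULT_WINDOWS = ((-300, 200), (-600, 200), (-1000, 200))


class ScanError(ValueError):
    pass


@dataclass(frozen=True)
class ScanParams:
    """One point of the stringency x window grid."""

    threshold: float
    window: tuple[int, int]

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ScanError(f"mat_sim threshold must be in (0, 1]: {self.threshold}")
        if self.window[0] >= self.window[1]:
            raise ScanError(f"window start must precede end: {self.window}")

    def label(self) -> str:
        return f"sim{self.threshold:.2f}_win{self.window[0]}:{self.window[1]:+d}"


def default_grid() -> list[ScanParams]:
    """The canonical nine-combo grid: 3 thresholds x 3 promoter windows."""
    return [
        ScanParams(t, w)
        for t, w in itertools.product(DEFAULT_THRESHOLDS, DEFAULT_WINDOWS)
    ]


@dataclass
class PromoterSet:
    """TSS-anchored promoter sequences keyed by gene id.

    ``span`` records the TSS-relative interval [start, end) covered by every
    stored sequence; all sequences must have length ``end - start``.
    """

    sequences: dict[str, str]
    span: tuple[int, int] = DEFAULT_SPAN

    def __post_init__(self) -> None:
        width = self.span[1] - self.span[0]
        if width <= 0:
            raise ScanError(f"invalid span {self.span}")
        for gene, seq in self.sequences.items():
            if len(seq) != width:
                raise ScanError(
                    f"promoter {gene!r}: length {len(seq)} != span width {width}"
                )

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.sequences)


def extract_window(promoters: PromoterSet, window: tuple[int, int]) -> PromoterSet:
    """Restrict every promoter to a TSS-relative half-open window."""
    start, end = promoters.span
    if window[0] < start or window[1] > end:
        raise ScanError(
            f"window {window} outside stored span [{start}, {end}) "
            f"(genes: {', '.join(itertools.islice(promoters.sequences, 3))}...)"
        )
    lo = window[0] - start
    hi = window[1] - start
    return PromoterSet(
        {g: s[lo:hi] for g, s in promoters.sequences.items()}, span=window
    )


@dataclass
class ScanHits:
    """Hits of one matrix on one sequence.

    ``forward`` holds 0-based offsets on the given sequence; ``reverse`` holds
    offsets on its reverse complement.
    """

    forward: list[int] = field(default_factory=list)
    reverse: list[int] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.forward) + len(self.reverse)


def scan_sequence(pwm: PWM, sequence: str, threshold: float) -> ScanHits:
    """All motif hits with mat_sim >= threshold on both strands."""
    if len(sequence) < len(pwm):
        warnings.warn(
            f"sequence shorter than matrix {pwm.name!r} "
            f"({len(sequence)} < {len(pwm)}); 0 hits",
            stacklevel=2,
        )
        return ScanHits()
    codes = encode_sequence(sequence)
    fwd = sliding_scores(pwm, codes)[0]
    rev = sliding_scores(pwm, encode_complement(codes)[::-1])[0]
    return ScanHits(
        forward=np.flatnonzero(fwd >= threshold).tolist(),
        reverse=np.flatnonzero(rev >= threshold).tolist(),
    )


# ---------------------------------------------------------------------------
# Grid tabulation
# ---------------------------------------------------------------------------

COUNT_COLUMNS = ["gene", "matrix", "threshold", "window_start", "window_end", "count"]


def build_count_table(
    promoters: PromoterSet,
    pwms: list[PWM],
    grid: list[ScanParams] | None = None,
    binary: bool = False,
) -> pd.DataFrame:
    """Hit counts for every gene x matrix x grid combination.

    Equivalent to scanning ``extract_window(promoters, p.window)`` with
    ``scan_sequence`` at each grid point, but scores each full-length promoter
    once per matrix and strand and re-thresholds/re-windows the cached scores.
    With ``binary=True`` counts are clipped to presence/absence (0/1).
    """
    if grid is None:
        grid = default_grid()
    if not grid:
        raise ScanError("scan grid must be nonempty")
    for p in grid:
        if p.window[0] < promoters.span[0] or p.window[1] > promoters.span[1]:
            raise ScanError(
                f"grid window {p.window} outside promoter span {promoters.span}"
            )

    genes = promoters.gene_ids
    full_len = promoters.span[1] - promoters.span[0]
    enc = np.vstack([encode_sequence(promoters.sequences[g]) for g in genes])
    enc_rc = encode_complement(enc)[:, ::-1]

    records: list[tuple] = []
    for pwm in pwms:
        L = len(pwm)
        fwd = sliding_scores(pwm, enc)      # (n, full_len - L + 1)
        rev = sliding_scores(pwm, enc_rc)
        for p in grid:
            lo = p.window[0] - promoters.span[0]
            hi = p.window[1] - promoters.span[0]
            if hi - lo < L:
                counts = np.zeros(len(genes), dtype=int)
            else:
                # forward offsets local to the window map to lo..hi-L on the
                # full sequence; the window's reverse complement is the slice
                # [full_len-hi, full_len-lo) of the full reverse complement
                f = (fwd[:, lo : hi - L + 1] >= p.threshold).sum(axis=1)
                rlo = full_len - hi
                rhi = full_len - lo
                r = (rev[:, rlo : rhi - L + 1] >= p.threshold).sum(axis=1)
                counts = f + r
            if binary:
                counts = np.minimum(counts, 1)
            records.extend(
                (g, pwm.name, p.threshold, p.window[0], p.window[1], int(c))
                for g, c in zip(genes, counts)
            )
    return pd.DataFrame(records, columns=COUNT_COLUMNS)


# ---------------------------------------------------------------------------
# FASTA I/O (header convention: ">GENEID tss_window=-1000:+200")
# ---------------------------------------------------------------------------


def write_promoters_fasta(promoters: PromoterSet, path) -> None:
    records = [
        SeqRecord(
            Seq(seq),
            id=gene,
            description=f"tss_window={promoters.span[0]}:{promoters.span[1]:+d}",
        )
        for gene, seq in promoters.sequences.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_promoters_fasta(path, span: tuple[int, int] | None = None) -> PromoterSet:
    """Read promoters; the span comes from the header tag unless overridden."""
    sequences: dict[str, str] = {}
    header_span = None
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            sequences[rec.id] = str(rec.seq).upper()
            if header_span is None and "tss_window=" in rec.description:
                tag = rec.description.split("tss_window=")[1].split()[0]
                lo, hi = tag.split(":")
                header_span = (int(lo), int(hi))
    if not sequences:
        raise ScanError(f"no FASTA records in {path}")
    return PromoterSet(sequences, span=span or header_span or DEFAULT_SPAN)


def write_count_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_count_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
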