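"""Position weight matrices and information-weighted matrix-similarity scoring.

A motif is represented by a position count matrix in A,C,G,T column order.
Counts are converted to per-position base frequencies after adding a small
pseudocount, and each position receives an information weight

    I_i = 2 + sum_b p_ib * log2(p_ib)        (0*log2(0) := 0)

ranging from 0 bits (uninformative position) to 2 bits (fully conserved).
The matrix-similarity score of a subsequence x of motif length L is

    mat_sim(x) = sum_i I_i * p_i(x_i) / sum_i I_i * max_b(p_ib)

so the consensus sequence scores exactly 1.0 and any other sequence scores
less.  The score is invariant to positive rescaling of the weights, so the
2-bit ceiling is a convention, not a tunable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# N (and any other ambiguity code) is encoded as 4 and carries probability 0.
N_CODE = 4

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0, C=1, G=2, T=3, other=4)."""
    out = np.full(len(seq), N_CODE, dtype=np.int8)
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    for base, code in BASE_INDEX.items():
        out[arr == ord(base)] = code
    return out


def encode_complement(codes: np.ndarray) -> np.ndarray:
    """Complement already-encoded codes (N stays N)."""
    return np.where(codes == N_CODE, N_CODE, 3 - codes).astype(np.int8)


class PWMError(ValueError):
    """Malformed position matrix or matrix file."""


@dataclass
class PWM:
    """A position count matrix with derived frequencies and information weights.

    Parameters
    ----------
    name:
        Matrix identifier, e.g. ``V$CREB_01`` or a synthetic name.
    counts:
        Array of shape (length, 4), nonnegative, columns in A,C,G,T order.
    pseudocount:
        Added to every cell before frequency conversion (default 0.5).
    """

    name: str
    counts: np.ndarray
    pseudocount: float = 0.5
    frequencies: np.ndarray = field(init=False, repr=False)
    info_weights: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise PWMError(
                f"matrix {self.name!r}: counts must be positions x 4, "
                f"got shape {counts.shape}"
            )
        if counts.shape[0] == 0:
            raise PWMError(f"matrix {self.name!r}: empty matrix")
        if np.any(counts < 0):
            raise PWMError(f"matrix {self.name!r}: negative count")
        if self.pseudocount < 0:
            raise PWMError(f"matrix {self.name!r}: negative pseudocount")
        self.counts = counts
        padded = counts + self.pseudocount
        row_sums = padded.sum(axis=1, keepdims=True)
        if np.any(row_sums == 0):
            raise PWMError(
                f"matrix {self.name!r}: all-zero count row with zero pseudocount"
            )
        freq = padded / row_sums
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
        self.frequencies = freq
        self.info_weights = 2.0 + plogp.sum(axis=1)

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.frequencies.argmax(axis=1))

    @property
    def max_weighted_score(self) -> float:
        """Denominator of mat_sim: sum_i I_i * max_b p_ib."""
        return float((self.info_weights * self.frequencies.max(axis=1)).sum())

    def _prob_lookup(self) -> np.ndarray:
        """(length, 5) table of p_i(base code); column 4 (N) is zero."""
        return np.hstack([self.frequencies, np.zeros((len(self), 1))])


def mat_sim_score(pwm: PWM, subsequence: str) -> float:
    """Information-weighted similarity of ``subsequence`` to ``pwm``, in [0, 1].

    The subsequence must have exactly the motif length.  An N base contributes
    probability 0 at its position.  A fully uniform matrix (denominator 0)
    scores 0 by convention.
    """
    if len(subsequence) != len(pwm):
        raise PWMError(
            f"matrix {pwm.name!r}: subsequence length {len(subsequence)} "
            f"!= motif length {len(pwm)}"
        )
    denom = pwm.max_weighted_score
    if denom == 0.0:
        return 0.0
    codes = encode_sequence(subsequence)
    probs = pwm._prob_lookup()
    num = float((pwm.info_weights * probs[np.arange(len(pwm)), codes]).sum())
    return num / denom


def sliding_scores(pwm: PWM, codes: np.ndarray) -> np.ndarray:
    """mat_sim at every offset of one or many equal-length encoded sequences.

    ``codes`` is int8 of shape (seq_len,) or (n_seqs, seq_len).  Returns
    scores of shape (..., seq_len - motif_len + 1).  Sequences shorter than
    the motif yield an empty score axis.
    """
    L = len(pwm)
    codes = np.atleast_2d(codes)
    if codes.shape[-1] < L:
        return np.zeros(codes.shape[:-1] + (0,))
    denom = pwm.max_weighted_score
    windows = np.lib.stride_tricks.sliding_window_view(codes, L, axis=-1)
    if denom == 0.0:
        return np.zeros(windows.shape[:-1])
    contrib = pwm.info_weights[:, None] * pwm._prob_lookup()  # (L, 5)
    scores = contrib[np.arange(L), windows].sum(axis=-1) / denom
    return scores


# ---------------------------------------------------------------------------
# TRANSFAC flat-file parsing
# ---------------------------------------------------------------------------

_ROW_RE = re.compile(r"^\s*(\d+)\s+(.*)$")


def parse_transfac(text: str, pseudocount: float = 0.5) -> list[PWM]:
    """Parse TRANSFAC flat-file matrix blocks into :class:`PWM` objects.

    Blocks are delimited by ``//``.  The matrix name is taken from the ``NA``
    line if present, else the ``ID`` line.  Position rows start with a row
    number followed by four counts in A,C,G,T order and an optional consensus
    letter; a ``P0``/``PO`` header line is ignored.
    """
    pwms: list[PWM] = []
    name: str | None = None
    rows: list[list[float]] = []
    saw_content = False

    def flush(line_no: int) -> None:
        nonlocal name, rows
        if rows:
            pwms.append(PWM(name or f"MATRIX_{len(pwms) + 1}",
                            np.array(rows), pseudocount))
        elif name is not None:
            raise PWMError(f"line {line_no}: matrix {name!r} has no count rows")
        name, rows = None, []

    lines = text.splitlines()
    for i, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("//"):
            flush(i)
            continue
        saw_content = True
        tag = stripped[:2].upper()
        if tag in ("P0", "PO"):
            continue
        if tag == "NA":
            name = stripped[2:].strip()
            continue
        if tag == "ID" and name is None:
            name = stripped[2:].strip()
            continue
        m = _ROW_RE.match(stripped)
        if m:
            fields = m.group(2).split()
            numeric: list[float] = []
            for tok in fields:
                try:
                    numeric.append(float(tok))
                except ValueError:
                    break  # trailing consensus symbol(s)
            if len(numeric) != 4:
                raise PWMError(
                    f"line {i}: expected 4 numeric count fields, "
                    f"got {len(numeric)}: {stripped!r}"
                )
            if any(v < 0 for v in numeric):
                raise PWMError(f"line {i}: negative count: {stripped!r}")
            rows.append(numeric)
    flush(len(lines))
    if not pwms:
        raise PWMError(
            "no matrix blocks found" if saw_content else "empty matrix file"
        )
    return pwms


def write_transfac(pwms: list[PWM]) -> str:
    """Serialize matrices back to TRANSFAC flat-file text."""
    out = []
    for pwm in pwms:
        out.append(f"ID {pwm.name}")
        out.append(f"NA {pwm.name}")
        out.append("P0      A      C      G      T")
        for i, row in enumerate(pwm.counts, start=1):
            cells = "  ".join(f"{v:6.1f}" if v % 1 else f"{int(v):6d}"
                              for v in row)
            out.append(f"{i:02d}  {cells}  {pwm.consensus[i - 1]}")
        out.append("//")
    return "\n".join(out) + "\n"
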