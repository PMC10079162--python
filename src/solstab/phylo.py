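"""Multiple sequence alignments and position-specific scoring matrices.

A PSSM is built per alignment column from gap-excluded amino-acid counts
smoothed with a background-proportional pseudocount.  With at least 50
aligned sequences the matrix stores natural-log likelihood ratios
against the background; below that threshold log-odds become noisy and a
raw-frequency position weight matrix (PWM) is used instead.  The
per-column conservation index is the complement of the normalised
Shannon entropy of the raw (unsmoothed) column frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

from .data import AA_INDEX, AMINO_ACIDS, UNIFORM_BACKGROUND

PWM_SEQUENCE_THRESHOLD = 50  # below this, raw frequencies replace log-odds
PWM_ALLOWED_FREQ = 0.05  # PWM analogue of "log-likelihood > 0"

_VALID_CHARS = set(AMINO_ACIDS) | {"-", "X"}


@dataclass
class Msa:
    """An alignment in the coordinate system of its master sequence."""

    master_sequence: str
    rows: list[str]

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    def __post_init__(self) -> None:
        L = len(self.master_sequence)
        if L == 0:
            raise ValueError("empty master sequence")
        for i, row in enumerate(self.rows):
            if len(row) != L:
                raise ValueError(
                    f"alignment row {i} has length {len(row)}, master has {L}"
                )


def _clean_row(seq: str, label: str) -> str:
    seq = seq.upper().replace(".", "-")
    bad = set(seq) - _VALID_CHARS
    if bad:
        raise ValueError(f"illegal characters {sorted(bad)} in sequence {label!r}")
    return seq


def read_msa(path: str | Path, format: Optional[str] = None) -> Msa:
    """Read an aligned-FASTA or A3M alignment.

    A3M lowercase (insert-state) columns are removed so that every row
    matches the master length.  Aligned-FASTA rows must already share a
    common length; columns where the first (master) row carries a gap
    are dropped so positions index the master sequence.
    """
    path = Path(path)
    if format is None:
        format = "a3m" if path.suffix.lower() == ".a3m" else "fasta"
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty alignment file {path}")

    if format == "a3m":
        rows = []
        for rec in records:
            raw = str(rec.seq).replace(".", "")
            rows.append(_clean_row("".join(c for c in raw if not c.islower()), rec.id))
    elif format == "fasta":
        rows = [_clean_row(str(rec.seq), rec.id) for rec in records]
    else:
        raise ValueError(f"unknown alignment format {format!r}")

    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise ValueError(f"ragged alignment in {path}: row lengths {sorted(lengths)}")

    master = rows[0]
    if "-" in master:
        keep = [i for i, c in enumerate(master) if c != "-"]
        rows = ["".join(r[i] for i in keep) for r in rows]
        master = rows[0]
    return Msa(master_sequence=master, rows=rows)


@dataclass
class Pssm:
    """Per-position amino-acid scores plus conservation.

    ``matrix`` holds natural-log likelihood ratios (``kind='loglik'``)
    or smoothed frequencies (``kind='pwm'``), shape (L, 20) with columns
    ordered as :data:`AMINO_ACIDS`.
    """

    kind: str  # 'loglik' | 'pwm'
    matrix: np.ndarray
    background: np.ndarray
    conservation: np.ndarray
    n_sequences: int
    master_sequence: str
    low_confidence: np.ndarray = field(default=None)  # columns >= 50% gaps

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def sd(self) -> float:
        """Standard deviation over all matrix entries (score normaliser)."""
        return float(np.std(self.matrix))

    def score(self, position: int, aa: str) -> float:
        return float(self.matrix[position, AA_INDEX[aa]])

    def frequency(self, position: int, aa: str) -> float:
        """Smoothed frequency regardless of matrix kind."""
        if self.kind == "pwm":
            return float(self.matrix[position, AA_INDEX[aa]])
        return float(
            np.exp(self.matrix[position, AA_INDEX[aa]]) * self.background[AA_INDEX[aa]]
        )

    def consensus(self, position: int) -> str:
        return AMINO_ACIDS[int(np.argmax(self.matrix[position]))]

    def wt_low(self, position: int, wt: str) -> bool:
        """Is the wild-type residue rare at this position?"""
        if self.kind == "pwm":
            return self.frequency(position, wt) < PWM_ALLOWED_FREQ
        return self.score(position, wt) <= 0.0

    def delta_loglik(self, position: int, wt: str, mut: str) -> float:
        """Mutant-minus-wild-type score (frequency difference for PWMs)."""
        return self.score(position, mut) - self.score(position, wt)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.matrix, columns=list(AMINO_ACIDS))
        df.insert(0, "position", np.arange(self.length) + 1)
        df.insert(1, "wt", list(self.master_sequence))
        df["conservation"] = self.conservation
        df.to_csv(path, index=False)


def build_pssm(
    msa: Msa,
    pseudocount: float = 1.0,
    background: Optional[np.ndarray] = None,
) -> Pssm:
    """Build a PSSM (or PWM for small alignments) from an alignment.

    Column frequencies are gap-excluded counts plus a total pseudocount
    weight distributed proportionally to the background.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    if bg.shape != (20,) or (bg <= 0).any():
        raise ValueError("background must be 20 strictly positive frequencies")
    bg = bg / bg.sum()

    L = len(msa.master_sequence)
    counts = np.zeros((L, 20))
    gaps = np.zeros(L)
    for row in msa.rows:
        for j, c in enumerate(row):
            if c in AA_INDEX:
                counts[j, AA_INDEX[c]] += 1
            else:
                gaps[j] += 1

    n_obs = counts.sum(axis=1)
    freqs = np.empty_like(counts)
    conservation = np.empty(L)
    for j in range(L):
        if n_obs[j] == 0:
            warnings.warn(f"alignment column {j} has no amino-acid observations; "
                          "using background frequencies")
            freqs[j] = bg
            raw = bg
        else:
            freqs[j] = (counts[j] + pseudocount * bg) / (n_obs[j] + pseudocount)
            raw = counts[j] / n_obs[j]
        nz = raw[raw > 0]
        entropy = float(-(nz * np.log(nz)).sum())
        conservation[j] = 1.0 - entropy / np.log(20.0)
    conservation = np.clip(conservation, 0.0, 1.0)

    low_confidence = gaps >= 0.5 * msa.n_sequences
    if low_confidence.any():
        warnings.warn(
            f"{int(low_confidence.sum())} alignment columns are >=50% gaps; "
            "scores there are low-confidence"
        )

    if msa.n_sequences < PWM_SEQUENCE_THRESHOLD:
        kind, matrix = "pwm", freqs
    else:
        kind, matrix = "loglik", np.log(freqs / bg)
    return Pssm(
        kind=kind,
        matrix=matrix,
        background=bg,
        conservation=conservation,
        n_sequences=msa.n_sequences,
        master_sequence=msa.master_sequence,
        low_confidence=low_confidence,
    )


def conservation_index(pssm: Pssm) -> np.ndarray:
    """Per-position conservation in [0, 1] (normalised-entropy complement)."""
    return pssm.conservation.copy()


def allowed_substitutions(
    pssm: Pssm,
    position: int,
    wt: str,
    mode: str = "ll_and_delta",
) -> set[str]:
    """Substitutions the phylogenetic record permits at a position.

    ``ll_pos`` keeps amino acids observed more often than background
    (log-likelihood > 0; PWM analogue: frequency >= 0.05).
    ``ll_and_delta`` additionally requires the mutant to be more
    frequent than the wild type.  The wild type itself is never
    returned.
    """
    if wt not in AA_INDEX:
        raise ValueError(f"wild-type {wt!r} is not a standard amino acid")
    if mode not in ("ll_pos", "ll_and_delta"):
        raise ValueError(f"unknown PSSM mode {mode!r}")
    row = pssm.matrix[position]
    allowed: set[str] = set()
    for aa in AMINO_ACIDS:
        if aa == wt:
            continue
        v = row[AA_INDEX[aa]]
        if pssm.kind == "pwm":
            ok = v >= PWM_ALLOWED_FREQ
            if ok and mode == "ll_and_delta":
                ok = v > row[AA_INDEX[wt]]
        else:
            ok = v > 0.0
            if ok and mode == "ll_and_delta":
                ok = v - row[AA_INDEX[wt]] > 0.0
        if ok:
            allowed.add(aa)
    return allowed
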