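"""Disorder scoring, disorder-to-order substitution scanning, and alignment
column conservation for protein sequences.

The disorder predictor implemented here is a charge/hydropathy surrogate in
the FoldIndex/TopIDP family: each residue receives a score in [0, 1] from a
logistic transform of a windowed linear combination of mean net-charge
magnitude and mean (min-max normalised) hydropathy.  Trained machine-learning
predictors assign related but not identical profiles; this predictor is
deliberately closed-form so that the scan procedure built on top of it —
replace every position with each of the other 19 residues, re-score, and rank
by predicted order gain — is fully reproducible.  Scores >= 0.5 are labelled
disordered, the conventional boundary for this family of predictors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

#: Residue sets by conformational tendency (Dunker-style composition bias).
ORDER_PROMOTING = frozenset("WCFIYVLN")
DISORDER_PROMOTING = frozenset("ARGQSPEK")


class NonCanonicalResidueError(ValueError):
    """A sequence contains a character outside the 20 canonical residues."""

    def __init__(self, sequence_id: str, position: int, residue: str):
        self.sequence_id = sequence_id
        self.position = position  # 1-based
        self.residue = residue
        super().__init__(
            f"sequence {sequence_id!r}: non-canonical residue {residue!r} "
            f"at position {position}"
        )


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence over the 20 canonical one-letter codes."""

    id: str
    residues: str

    def __post_init__(self):
        if len(self.residues) == 0:
            raise ValueError(f"sequence {self.id!r} is empty")
        for i, aa in enumerate(self.residues, start=1):
            if aa not in AMINO_ACIDS:
                raise NonCanonicalResidueError(self.id, i, aa)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, position: int) -> str:
        """Residue at 1-based ``position``."""
        if not 1 <= position <= len(self):
            raise IndexError(
                f"position {position} outside [1, {len(self)}] for {self.id!r}"
            )
        return self.residues[position - 1]


@dataclass(frozen=True)
class ResiduePropensityScale:
    """A named mapping from each canonical residue to a real number."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self):
        keys = set(self.values)
        if keys != set(AMINO_ACIDS):
            missing = sorted(set(AMINO_ACIDS) - keys)
            extra = sorted(keys - set(AMINO_ACIDS))
            raise ValueError(
                f"scale {self.name!r} must cover exactly the 20 canonical "
                f"residues (missing {missing}, unexpected {extra})"
            )
        for aa, v in self.values.items():
            if not math.isfinite(v):
                raise ValueError(f"scale {self.name!r}: non-finite value for {aa}")

    def as_array(self, residues: str) -> np.ndarray:
        return np.array([self.values[aa] for aa in residues], dtype=float)

    def normalized(self) -> "ResiduePropensityScale":
        """Min-max rescaling of the values onto [0, 1]."""
        vals = np.array([self.values[aa] for aa in AMINO_ACIDS])
        lo, hi = vals.min(), vals.max()
        if hi == lo:
            normed = {aa: 0.0 for aa in AMINO_ACIDS}
        else:
            normed = {aa: (self.values[aa] - lo) / (hi - lo) for aa in AMINO_ACIDS}
        return ResiduePropensityScale(self.name + "_norm01", normed)


def load_scale(path: str | Path, name: str | None = None) -> ResiduePropensityScale:
    """Read a two-column (residue TAB value) propensity scale from text.

    Lines starting with '#' are comments.
    """
    path = Path(path)
    values: dict[str, float] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, raw = line.split()
        values[aa] = float(raw)
    return ResiduePropensityScale(name or path.stem, values)


def _packaged_scale(filename: str, name: str) -> ResiduePropensityScale:
    ref = resources.files("idrkit.data").joinpath(filename)
    with resources.as_file(ref) as path:
        return load_scale(path, name)


def default_hydropathy_scale() -> ResiduePropensityScale:
    """Kyte-Doolittle hydropathy, shipped as swappable plain text."""
    return _packaged_scale("hydropathy_kyte_doolittle.tsv", "kyte_doolittle")


def default_charge_scale() -> ResiduePropensityScale:
    """Formal side-chain net charge at neutral pH."""
    return _packaged_scale("net_charge.tsv", "net_charge")


@dataclass(frozen=True)
class DisorderProfile:
    """Per-residue disorder scores in [0, 1]; >= 0.5 means disordered."""

    sequence_id: str
    window_halfwidth: int
    scores: np.ndarray

    DISORDER_THRESHOLD = 0.5

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 1 or scores.size == 0:
            raise ValueError("scores must be a non-empty 1-d array")
        if np.any(scores < 0) or np.any(scores > 1):
            raise ValueError("disorder scores must lie in [0, 1]")

    def __len__(self) -> int:
        return self.scores.size

    @property
    def disordered_positions(self) -> list[int]:
        """1-based positions with score >= 0.5."""
        return [i + 1 for i in np.flatnonzero(self.scores >= self.DISORDER_THRESHOLD)]

    def mean(self) -> float:
        return float(self.scores.mean())


def _windowed_mean(values: np.ndarray, halfwidth: int) -> np.ndarray:
    """Mean over [i-h, i+h], truncated (not mirrored) at the termini."""
    if halfwidth == 0:
        return values.astype(float)
    n = values.size
    csum = np.concatenate([[0.0], np.cumsum(values)])
    idx = np.arange(n)
    lo = np.maximum(idx - halfwidth, 0)
    hi = np.minimum(idx + halfwidth, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


# FoldIndex-style coefficients for the windowed charge/hydropathy combination.
# The charge weight sits below hydropathy_weight * dHnorm(E->W) = 2.785*(3.6/9)
# so that swapping an acidic residue for tryptophan can never raise the score.
DEFAULT_HYDROPATHY_WEIGHT = 2.785
DEFAULT_CHARGE_WEIGHT = 0.8
DEFAULT_INTERCEPT = 1.151
DEFAULT_STEEPNESS = 3.0
DEFAULT_WINDOW_HALFWIDTH = 10


def score_disorder(
    seq: ProteinSequence,
    scale: ResiduePropensityScale | None = None,
    charge_scale: ResiduePropensityScale | None = None,
    window_halfwidth: int = DEFAULT_WINDOW_HALFWIDTH,
    *,
    hydropathy_weight: float = DEFAULT_HYDROPATHY_WEIGHT,
    charge_weight: float = DEFAULT_CHARGE_WEIGHT,
    intercept: float = DEFAULT_INTERCEPT,
    steepness: float = DEFAULT_STEEPNESS,
) -> DisorderProfile:
    """Score per-residue disorder from windowed charge and hydropathy.

    score_i = logistic(k * (intercept + w_q*|<q>_i| - w_h*<H>_i)) where <.>_i
    is the mean over the window [i-h, i+h] (truncated at the termini), q is
    the net-charge scale and H the hydropathy scale min-max normalised to
    [0, 1].  Higher = more disordered.

    Parameters
    ----------
    window_halfwidth
        Residues on each side of i entering the window; 0 makes the score
        depend on residue i alone.
    """
    if window_halfwidth < 0:
        raise ValueError("window_halfwidth must be >= 0")
    scale = scale if scale is not None else default_hydropathy_scale()
    charge_scale = (
        charge_scale if charge_scale is not None else default_charge_scale()
    )
    hnorm = scale.normalized().as_array(seq.residues)
    q = charge_scale.as_array(seq.residues)
    mean_h = _windowed_mean(hnorm, window_halfwidth)
    mean_q = _windowed_mean(q, window_halfwidth)
    arg = intercept + charge_weight * np.abs(mean_q) - hydropathy_weight * mean_h
    scores = 1.0 / (1.0 + np.exp(-steepness * arg))
    return DisorderProfile(seq.id, window_halfwidth, scores)


def region_mean_disorder(profile: DisorderProfile, start: int, end: int) -> float:
    """Mean score over the closed 1-based interval [start, end]."""
    if not (1 <= start <= end <= len(profile)):
        raise ValueError(
            f"interval [{start}, {end}] invalid for profile of length {len(profile)}"
        )
    return float(profile.scores[start - 1 : end].mean())


def apply_substitution(
    seq: ProteinSequence, position: int, residue: str
) -> ProteinSequence:
    """Return a copy of ``seq`` with 1-based ``position`` set to ``residue``.

    A substitution by the wild-type residue is legal but flagged with a
    warning since it is a no-op.
    """
    if residue not in AMINO_ACIDS:
        raise NonCanonicalResidueError(seq.id, position, residue)
    if not 1 <= position <= len(seq):
        raise IndexError(
            f"position {position} outside [1, {len(seq)}] for {seq.id!r}"
        )
    wild = seq[position]
    if wild == residue:
        warnings.warn(
            f"{seq.id}: substitution {wild}{position}{residue} is a no-op",
            stacklevel=2,
        )
        return seq
    residues = seq.residues[: position - 1] + residue + seq.residues[position:]
    return ProteinSequence(f"{seq.id}_{wild}{position}{residue}", residues)


@dataclass(frozen=True)
class SubstitutionEffect:
    """Predicted effect of one point substitution on mean disorder.

    ``delta_mean_disorder`` is wild-type mean score minus variant mean score,
    so positive values are order-conferring (disorder-to-order) changes.
    """

    position: int
    wild: str
    substitute: str
    delta_mean_disorder: float

    def __post_init__(self):
        if self.substitute == self.wild:
            raise ValueError("substitute must differ from the wild-type residue")

    @property
    def label(self) -> str:
        return f"{self.wild}{self.position}{self.substitute}"


@dataclass(frozen=True)
class ScanResult:
    """Ranked substitution effects from a replace-and-test scan."""

    sequence_id: str
    effects: tuple[SubstitutionEffect, ...]
    scope: tuple[int, ...]

    def top(self, k: int = 10) -> tuple[SubstitutionEffect, ...]:
        return self.effects[:k]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "position": [e.position for e in self.effects],
                "wild": [e.wild for e in self.effects],
                "substitute": [e.substitute for e in self.effects],
                "delta_mean_disorder": [e.delta_mean_disorder for e in self.effects],
                "rank": np.arange(1, len(self.effects) + 1),
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


Predictor = Callable[[ProteinSequence], DisorderProfile]


def scan_substitutions(
    seq: ProteinSequence,
    predictor: Predictor | None = None,
    positions: Iterable[int] | None = None,
    region: tuple[int, int] | None = None,
) -> ScanResult:
    """Replace-and-test scan: try each of the 19 alternatives at every
    scanned position, re-score the full variant sequence, and rank by
    predicted order gain.

    Parameters
    ----------
    predictor
        Callable mapping a sequence to a :class:`DisorderProfile`; defaults
        to :func:`score_disorder` with default scales.
    positions
        1-based subset of positions to scan (default: all).
    region
        Optional closed interval over which mean scores are compared;
        default is the whole sequence.

    Returns
    -------
    ScanResult sorted descending by ``delta_mean_disorder`` (greatest
    order-conferring substitution first), ties broken by position then by
    substitute residue alphabetically.
    """
    if predictor is None:
        predictor = score_disorder
    if positions is None:
        scope = tuple(range(1, len(seq) + 1))
    else:
        scope = tuple(sorted(set(positions)))
        if not scope:
            raise ValueError("empty position subset")
        if scope[0] < 1 or scope[-1] > len(seq):
            raise IndexError(f"positions {scope} outside [1, {len(seq)}]")
    if region is None:
        lo, hi = 1, len(seq)
    else:
        lo, hi = region
    wild_mean = region_mean_disorder(predictor(seq), lo, hi)

    effects = []
    for pos in scope:
        wild = seq[pos]
        for alt in AMINO_ACIDS:
            if alt == wild:
                continue
            variant = ProteinSequence(
                seq.id, seq.residues[: pos - 1] + alt + seq.residues[pos:]
            )
            var_mean = region_mean_disorder(predictor(variant), lo, hi)
            effects.append(
                SubstitutionEffect(pos, wild, alt, wild_mean - var_mean)
            )
    effects.sort(key=lambda e: (-e.delta_mean_disorder, e.position, e.substitute))
    return ScanResult(seq.id, tuple(effects), scope)


@dataclass(frozen=True)
class ColumnConservation:
    """Conservation of one alignment column: 1 - H/ln(20), gaps excluded.

    ``score`` is None for an all-gap column; ``high_gap`` flags columns with
    more than 50% gaps, whose scores rest on few residues.
    """

    column: int
    score: float | None
    gap_fraction: float

    @property
    def high_gap(self) -> bool:
        return self.gap_fraction > 0.5


def _validate_alignment(alignment: Sequence[ProteinSequence | str]) -> list[str]:
    rows = []
    for entry in alignment:
        rows.append(entry.residues if isinstance(entry, ProteinSequence) else entry)
    if len(rows) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
    for r in rows:
        for i, aa in enumerate(r, start=1):
            if aa != GAP and aa not in AMINO_ACIDS:
                raise NonCanonicalResidueError("<alignment>", i, aa)
    return rows


def column_conservation(
    alignment: Sequence[ProteinSequence | str],
) -> list[ColumnConservation]:
    """Shannon-entropy conservation per column of an aligned set of sequences.

    Aligned rows may be :class:`ProteinSequence` objects or plain strings with
    '-' gaps.  Gaps are removed before the entropy is taken over the residue
    frequencies; score = 1 - H/ln(20), i.e. 1 for an invariant column and 0
    for a maximally diverse one.  All-gap columns get ``score=None``.
    """
    rows = _validate_alignment(alignment)
    n_cols = len(rows[0])
    out = []
    for j in range(n_cols):
        col = [r[j] for r in rows]
        residues = [aa for aa in col if aa != GAP]
        gap_fraction = 1.0 - len(residues) / len(col)
        if not residues:
            out.append(ColumnConservation(j + 1, None, gap_fraction))
            continue
        _, counts = np.unique(residues, return_counts=True)
        freqs = counts / counts.sum()
        entropy = float(-(freqs * np.log(freqs)).sum())
        score = 1.0 - entropy / math.log(20)
        out.append(ColumnConservation(j + 1, score, gap_fraction))
    return out


# ---------------------------------------------------------------------------
# FASTA I/O (aligned FASTA uses '-' gaps and round-trips through the same
# functions; gapped records are returned as plain strings).


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return [ProteinSequence(r.id, str(r.seq).upper()) for r in records]


def read_alignment_fasta(path: str | Path) -> list[str]:
    """Aligned FASTA rows as strings (gaps kept); validated for shape."""
    records = list(SeqIO.parse(str(path), "fasta"))
    rows = [str(r.seq).upper() for r in records]
    _validate_alignment(rows)
    return rows


def write_fasta(path: str | Path, sequences: Iterable[ProteinSequence]) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")
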