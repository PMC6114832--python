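"""Segment extraction and dataset I/O.

The unit of analysis is an :class:`RNASegment`: a window of length 2ξ+1 over
{A,C,G,U} with an invariant uridine at the center. Benchmark datasets are
balanced collections of such segments labeled positive (experimentally
validated Ψ site) or negative (unvalidated U). This module reads and writes
those datasets as plain FASTA with the label encoded in the header, builds
segments from arbitrary query sequences with mirror-image padding at the
termini, and generates synthetic datasets with planted class-conditional
position-specific nucleotide biases for testing and calibration.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO

from pseui.errors import FormatError, ValidationError

ALPHABET = "ACGU"
#: nucleotide -> integer code, A=0 C=1 G=2 U=3 (alphabetical; used everywhere)
NT_INDEX = {nt: i for i, nt in enumerate(ALPHABET)}

_VALID_RE = re.compile(r"^[ACGU]+$")

#: default header convention of the benchmark FASTA dialect:
#: ">pos_17" is a positive sample, ">neg_3" a negative one.
DEFAULT_LABEL_REGEX = r"^(?P<label>pos|neg)"


def _normalize_sequence(raw: str, record: str) -> str:
    """Upper-case, map T->U, reject anything outside {A,C,G,U}."""
    seq = raw.upper().replace("T", "U")
    if not seq:
        raise ValidationError(f"record {record!r}: empty sequence")
    m = _VALID_RE.match(seq)
    if not m or m.end() != len(seq):
        bad = next(i for i, ch in enumerate(seq) if ch not in NT_INDEX)
        raise ValidationError(
            f"record {record!r}: invalid character {seq[bad]!r} at position {bad + 1}"
        )
    return seq


@dataclass(frozen=True)
class RNASegment:
    """A fixed-length RNA window with a central uridine.

    Parameters
    ----------
    sequence
        String of length 2·xi+1 over {A,C,G,U} with ``sequence[xi] == 'U'``.
    xi
        Half-window size ξ: number of nucleotides flanking the center on
        each side.
    origin
        Optional ``(sequence_id, center_position)`` provenance, with the
        center position 1-based on the source sequence.
    """

    sequence: str
    xi: int
    origin: Optional[tuple[Optional[str], int]] = None

    def __post_init__(self) -> None:
        if self.xi < 1:
            raise ValidationError(f"xi must be >= 1, got {self.xi}")
        L = 2 * self.xi + 1
        if len(self.sequence) != L:
            raise ValidationError(
                f"segment length {len(self.sequence)} != 2*xi+1 = {L}"
            )
        if not _VALID_RE.fullmatch(self.sequence):
            raise ValidationError(
                f"segment {self.sequence!r} contains characters outside {{A,C,G,U}}"
            )
        if self.sequence[self.xi] != "U":
            raise ValidationError(
                f"segment center must be U, got {self.sequence[self.xi]!r}"
            )

    @property
    def length(self) -> int:
        return 2 * self.xi + 1

    def codes(self) -> np.ndarray:
        """Integer codes (A=0,C=1,G=2,U=3), shape (2ξ+1,)."""
        return np.fromiter((NT_INDEX[c] for c in self.sequence), dtype=np.int64)


@dataclass
class LabeledDataset:
    """Segments with binary Ψ labels sharing one half-window size.

    ``labels`` is a boolean array: True = positive (validated Ψ site),
    False = negative.
    """

    segments: list[RNASegment]
    labels: np.ndarray
    xi: int
    name: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        if len(self.segments) != len(self.labels):
            raise ValidationError(
                f"{len(self.segments)} segments but {len(self.labels)} labels"
            )
        for seg in self.segments:
            if seg.xi != self.xi:
                raise ValidationError(
                    f"segment xi={seg.xi} differs from dataset xi={self.xi}"
                )

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int((~self.labels).sum())

    def require_both_classes(self) -> None:
        if self.n_positive < 1 or self.n_negative < 1:
            raise ValidationError(
                f"dataset {self.name!r} needs >=1 sample of each class for "
                f"fitting (N+={self.n_positive}, N-={self.n_negative})"
            )

    def subset(self, indices: Sequence[int] | np.ndarray, name: str = "") -> "LabeledDataset":
        idx = np.asarray(indices)
        return LabeledDataset(
            segments=[self.segments[i] for i in idx],
            labels=self.labels[idx],
            xi=self.xi,
            name=name or self.name,
        )

    def code_matrix(self) -> np.ndarray:
        """Integer-coded segments, shape (n, 2ξ+1)."""
        return np.stack([seg.codes() for seg in self.segments])


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions for the synthetic benchmark generator.

    The generator emulates the structure of the Ψ benchmark sets: balanced
    classes of fixed-length central-U segments where positives carry a
    motif-like, position-specific nucleotide skew and negatives are uniform.

    ``bias_strength`` b in [0,1] linearly interpolates each biased position's
    distribution in positives between uniform (b=0) and a point mass on the
    planted nucleotide (b=1): P(planted) = 1/4 + 3b/4.

    Defaults are the package's standard study conditions: ξ=10 windows,
    100 segments per class, b=0.6, and biased positions at center±1..±4 with
    planted nucleotides cycling A,C,G,U so the two classes have matched
    aggregate composition (signal is positional, not compositional).
    """

    xi: int = 10
    n_pos: int = 100
    n_neg: int = 100
    bias_strength: float = 0.6
    biased_positions: tuple[int, ...] | None = None  # 1-based, None -> center±1..±4
    planted: tuple[str, ...] | None = None  # one nucleotide per biased position
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.bias_strength <= 1.0:
            raise ValidationError(
                f"bias_strength must be in [0,1], got {self.bias_strength}"
            )
        if self.xi < 1:
            raise ValidationError(f"xi must be >= 1, got {self.xi}")
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValidationError("n_pos and n_neg must be >= 1")
        center = self.xi + 1
        for p in self.resolved_positions():
            if not 1 <= p <= 2 * self.xi + 1 or p == center:
                raise ValidationError(
                    f"biased position {p} outside 1..{2 * self.xi + 1} or at center"
                )
        if self.planted is not None:
            if len(self.planted) != len(self.resolved_positions()):
                raise ValidationError("planted must match biased_positions in length")
            for nt in self.planted:
                if nt not in NT_INDEX:
                    raise ValidationError(f"planted nucleotide {nt!r} not in {{A,C,G,U}}")

    def resolved_positions(self) -> tuple[int, ...]:
        if self.biased_positions is not None:
            return tuple(self.biased_positions)
        center = self.xi + 1
        span = min(4, self.xi)
        return tuple(
            p for off in range(1, span + 1) for p in (center - off, center + off)
        )

    def resolved_planted(self) -> tuple[str, ...]:
        if self.planted is not None:
            return tuple(self.planted)
        pos = self.resolved_positions()
        return tuple(ALPHABET[i % 4] for i in range(len(pos)))


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file of RNA (or DNA) sequences.

    Sequences are upper-cased and T is mapped to U; any remaining character
    outside {A,C,G,U} raises :class:`ValidationError` naming the record and
    position. Records are returned in file order as ``(id, sequence)``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return [(rec.id, _normalize_sequence(str(rec.seq), rec.id)) for rec in records]


def _default_label_rule(header: str) -> Optional[bool]:
    m = re.match(DEFAULT_LABEL_REGEX, header, flags=re.IGNORECASE)
    if m is None:
        return None
    return m.group("label").lower() == "pos"


def make_label_rule(regex: str) -> Callable[[str], Optional[bool]]:
    """Build a label rule from a regex with a ``label`` group matching
    ``pos``/``neg`` (case-insensitive) in record headers."""
    pattern = re.compile(regex, flags=re.IGNORECASE)

    def rule(header: str) -> Optional[bool]:
        m = pattern.search(header)
        if m is None:
            return None
        return m.group("label").lower() == "pos"

    return rule


def load_benchmark(
    path: str | Path,
    xi: int,
    label_rule: Callable[[str], Optional[bool]] | None = None,
    name: str = "",
) -> LabeledDataset:
    """Load a labeled benchmark FASTA of fixed-length central-U segments.

    Every record must have length 2·xi+1 with U at the center; the header
    determines the class via ``label_rule`` (default: ``pos``/``neg`` header
    prefix). Raises :class:`ValidationError` for wrong lengths or centers and
    :class:`FormatError` for unlabeled headers.
    """
    rule = label_rule or _default_label_rule
    records = read_fasta(path)
    segments: list[RNASegment] = []
    labels: list[bool] = []
    for rec_id, seq in records:
        label = rule(rec_id)
        if label is None:
            raise FormatError(
                f"{path}: header {rec_id!r} does not match the label convention"
            )
        if len(seq) != 2 * xi + 1:
            raise ValidationError(
                f"{path}: record {rec_id!r} has length {len(seq)}, expected {2 * xi + 1}"
            )
        segments.append(RNASegment(seq, xi, origin=(rec_id, xi + 1)))
        labels.append(label)
    return LabeledDataset(
        segments=segments,
        labels=np.asarray(labels, dtype=bool),
        xi=xi,
        name=name or Path(path).stem,
    )


def write_benchmark(dataset: LabeledDataset, path: str | Path) -> None:
    """Write a dataset in the benchmark FASTA dialect (``pos_i``/``neg_i``)."""
    path = Path(path)
    n_pos = n_neg = 0
    with path.open("w") as fh:
        for seg, label in zip(dataset.segments, dataset.labels):
            if label:
                n_pos += 1
                header = f"pos_{n_pos}"
            else:
                n_neg += 1
                header = f"neg_{n_neg}"
            fh.write(f">{header}\n{seg.sequence}\n")


def _reflect_index(i: int, n: int) -> int:
    """Mirror index i into [0, n): reflect about each terminus with the
    terminal base excluded from the reflection, repeating as needed."""
    if n == 1:
        raise ValidationError(
            "cannot mirror-pad a single-nucleotide sequence"
        )
    period = 2 * (n - 1)
    i = i % period
    if i < 0:
        i += period
    return i if i < n else period - i


def mirror_pad(sequence: str, center: int, xi: int) -> RNASegment:
    """Extract the 2ξ+1 window around a 1-based U position, mirror-padding
    whichever flank is shorter than ξ.

    The padding convention reflects the sequence about its terminal
    nucleotide with the terminus itself excluded from the reflection (so the
    boundary base is not duplicated), repeating the reflection when the
    sequence is shorter than the deficit.
    """
    seq = _normalize_sequence(sequence, "<query>")
    if not 1 <= center <= len(seq):
        raise ValidationError(
            f"center {center} out of range 1..{len(seq)}"
        )
    c = center - 1
    if seq[c] != "U":
        raise ValidationError(
            f"position {center} is {seq[c]!r}, not U"
        )
    n = len(seq)
    window = "".join(
        seq[i] if 0 <= i < n else seq[_reflect_index(i, n)]
        for i in range(c - xi, c + xi + 1)
    )
    return RNASegment(window, xi, origin=(None, center))


def extract_segments(
    sequence: str, xi: int, sequence_id: str = "<query>"
) -> list[RNASegment]:
    """One mirror-padded segment per uridine in the sequence, in order.

    The sequence must be at least 2ξ+1 long (the length gate applied to
    query submissions: ≥21 nt for ξ=10, ≥31 nt for ξ=15).
    """
    seq = _normalize_sequence(sequence, sequence_id)
    min_len = 2 * xi + 1
    if len(seq) < min_len:
        raise ValidationError(
            f"sequence {sequence_id!r} has length {len(seq)}; at least "
            f"{min_len} nt are required for xi={xi}"
        )
    out = []
    for pos0, ch in enumerate(seq):
        if ch == "U":
            seg = mirror_pad(seq, pos0 + 1, xi)
            out.append(RNASegment(seg.sequence, xi, origin=(sequence_id, pos0 + 1)))
    return out


def generate_synthetic(config: SyntheticConfig) -> LabeledDataset:
    """Generate a balanced synthetic benchmark dataset.

    Positives draw each biased position from the skewed distribution
    ``P(planted) = 1/4 + 3b/4`` (others share the remainder equally);
    negatives, and all unbiased positions in both classes, draw uniformly.
    The center is always U. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    L = 2 * config.xi + 1
    center0 = config.xi
    positions0 = [p - 1 for p in config.resolved_positions()]
    planted = [NT_INDEX[nt] for nt in config.resolved_planted()]
    b = config.bias_strength

    def draw(n: int, biased: bool) -> np.ndarray:
        codes = rng.integers(0, 4, size=(n, L))
        if biased and b > 0:
            p_hit = 0.25 + 0.75 * b
            for pos, plant in zip(positions0, planted):
                hit = rng.random(n) < p_hit
                others = [c for c in range(4) if c != plant]
                codes[:, pos] = np.where(
                    hit, plant, rng.choice(others, size=n)
                )
        codes[:, center0] = NT_INDEX["U"]
        return codes

    pos_codes = draw(config.n_pos, biased=True)
    neg_codes = draw(config.n_neg, biased=False)

    segments = []
    labels = []
    for codes, label in ((pos_codes, True), (neg_codes, False)):
        for row in codes:
            segments.append(
                RNASegment("".join(ALPHABET[c] for c in row), config.xi)
            )
            labels.append(label)
    return LabeledDataset(
        segments=segments,
        labels=np.asarray(labels, dtype=bool),
        xi=config.xi,
        name=f"synthetic_b{b:g}_seed{config.seed}",
    )
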