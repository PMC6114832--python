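"""Feature encoders for central-uridine RNA segments.

Five encodings are provided:

* **NC** — nucleotide composition: the 4 mononucleotide frequencies.
* **DC** — dinucleotide composition: the 16 overlapping 2-mer frequencies.
* **pseDNC** — pseudo dinucleotide composition: DC augmented with λ
  tier-correlation factors θ_1..θ_λ computed from z-scored physicochemical
  property differences (free energy, hydrophilicity, stacking energy) and
  down-weighted by w.
* **PSNP** — position-specific nucleotide propensity: for each position j,
  the difference Z⁺[N_j, j] − Z⁻[N_j, j] between the per-position nucleotide
  frequencies of the positive and negative training classes, looked up at
  the segment's own nucleotide.
* **PSDP** — the dinucleotide analog over the 2ξ overlapping pairs.

NC, DC and pseDNC are functions of the segment alone. PSNP and PSDP require
a :class:`PropensityMatrix` fitted from labeled training data — and from
training data only; refitting them inside each cross-validation fold is the
responsibility of :mod:`pseui.validation`.

Dinucleotides are indexed lexicographically (AA, AC, ..., UU) everywhere.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from pseui.errors import ValidationError
from pseui.segments_io import ALPHABET, NT_INDEX, LabeledDataset, RNASegment

#: lexicographic dinucleotide order, AA=0 ... UU=15 (index = 4*first+second)
DINUCLEOTIDES = tuple(a + b for a in ALPHABET for b in ALPHABET)
DI_INDEX = {d: i for i, d in enumerate(DINUCLEOTIDES)}

PROPERTY_NAMES = ("free_energy", "hydrophilicity", "stacking_energy")

FEATURE_NAMES = ("NC", "DC", "pseDNC", "PSNP", "PSDP")


@dataclass(frozen=True)
class PhysicochemicalTable:
    """Dinucleotide physicochemical properties.

    ``values`` has shape (16, n_properties) in lexicographic dinucleotide
    order; ``properties`` names the columns. ``normalized`` marks whether
    each column has been z-scored across the 16 dinucleotides.
    """

    values: np.ndarray
    properties: tuple[str, ...]
    normalized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (16, len(self.properties)):
            raise ValidationError(
                f"property table must be 16 x {len(self.properties)}, got {v.shape}"
            )
        object.__setattr__(self, "values", v)

    def select(self, properties: Sequence[str]) -> "PhysicochemicalTable":
        missing = [p for p in properties if p not in self.properties]
        if missing:
            raise ValidationError(f"unknown properties: {missing}")
        cols = [self.properties.index(p) for p in properties]
        return PhysicochemicalTable(
            self.values[:, cols], tuple(properties), self.normalized
        )


def load_property_table(path: str | Path | None = None) -> PhysicochemicalTable:
    """Load the dinucleotide property table (raw, un-normalized).

    With no argument, loads the packaged table of the three standard RNA
    dinucleotide properties: free energy, hydrophilicity, stacking energy.
    A user table must be a CSV with a ``dinucleotide`` column (T or U
    spelling accepted) and one column per property, all 16 dinucleotides
    present.
    """
    if path is None:
        ref = resources.files("pseui.data") / "rna_dinucleotide_properties.csv"
        with resources.as_file(ref) as p:
            return load_property_table(p)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "dinucleotide" not in reader.fieldnames:
            raise ValidationError(f"{path}: missing 'dinucleotide' column")
        props = tuple(c for c in reader.fieldnames if c != "dinucleotide")
        values = np.full((16, len(props)), np.nan)
        for row in reader:
            d = row["dinucleotide"].strip().upper().replace("T", "U")
            if d not in DI_INDEX:
                raise ValidationError(f"{path}: invalid dinucleotide {row['dinucleotide']!r}")
            values[DI_INDEX[d]] = [float(row[p]) for p in props]
    if np.isnan(values).any():
        missing = [DINUCLEOTIDES[i] for i in np.where(np.isnan(values).any(axis=1))[0]]
        raise ValidationError(f"{path}: missing dinucleotides {missing}")
    return PhysicochemicalTable(values, props, normalized=False)


def normalize_properties(table: PhysicochemicalTable) -> PhysicochemicalTable:
    """Z-score each property across the 16 dinucleotides (mean 0, SD 1).

    Properties on wildly different scales (stacking energies near −15
    kcal/mol vs hydrophilicities near 0.3) would otherwise dominate the
    pseDNC correlation function.
    """
    mean = table.values.mean(axis=0)
    sd = table.values.std(axis=0)  # population SD, ddof=0
    if np.any(sd == 0):
        raise ValidationError("cannot normalize a constant property column")
    return PhysicochemicalTable(
        (table.values - mean) / sd, table.properties, normalized=True
    )


@dataclass(frozen=True)
class PseDNCConfig:
    """pseDNC hyperparameters: λ correlation tiers, weight w, property subset.

    λ must not exceed L−2 for segment length L (tier j correlates
    dinucleotides j apart, of which there are L−1−j ≥ 1). Defaults λ=2,
    w=0.5 with all three properties.
    """

    lam: int = 2
    w: float = 0.5
    properties: tuple[str, ...] = PROPERTY_NAMES

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValidationError(f"lambda must be >= 0, got {self.lam}")
        if self.w <= 0:
            raise ValidationError(f"w must be > 0, got {self.w}")
        if not self.properties:
            raise ValidationError("property subset must be nonempty")


@dataclass(frozen=True)
class PropensityMatrix:
    """Class-difference propensity matrix fitted from labeled segments.

    ``Z_plus``/``Z_minus`` are per-position occurrence-frequency matrices of
    the positive and negative training classes — 4×(2ξ+1) over nucleotides
    for kind ``"PSNP"``, 16×2ξ over overlapping dinucleotides for kind
    ``"PSDP"`` — and ``Z = Z_plus − Z_minus`` is the propensity used for
    encoding. Columns of Z⁺ and Z⁻ are probability vectors, so columns of Z
    sum to 0 and entries lie in [−1, 1]; the PSNP center column is zero
    because the center is U in every sample of both classes.
    """

    kind: str
    Z_plus: np.ndarray
    Z_minus: np.ndarray
    xi: int

    def __post_init__(self) -> None:
        if self.kind not in ("PSNP", "PSDP"):
            raise ValidationError(f"kind must be PSNP or PSDP, got {self.kind!r}")
        L = 2 * self.xi + 1
        expected = (4, L) if self.kind == "PSNP" else (16, L - 1)
        for nm, m in (("Z_plus", self.Z_plus), ("Z_minus", self.Z_minus)):
            if m.shape != expected:
                raise ValidationError(
                    f"{nm} shape {m.shape} != expected {expected} for {self.kind}"
                )

    @property
    def Z(self) -> np.ndarray:
        return self.Z_plus - self.Z_minus


def _position_frequencies(codes: np.ndarray, n_symbols: int) -> np.ndarray:
    """Column-stochastic frequency matrix (n_symbols x n_positions)."""
    n, L = codes.shape
    freq = np.zeros((n_symbols, L))
    for s in range(n_symbols):
        freq[s] = (codes == s).sum(axis=0)
    return freq / n


def _dinucleotide_codes(codes: np.ndarray) -> np.ndarray:
    """Map integer nucleotide codes (n, L) to dinucleotide codes (n, L-1)."""
    return 4 * codes[:, :-1] + codes[:, 1:]


def fit_propensity(dataset: LabeledDataset, kind: str) -> PropensityMatrix:
    """Fit a PSNP or PSDP propensity matrix from a labeled dataset.

    Frequencies are plain maximum-likelihood counts (no pseudocounts),
    computed separately from the positive and the negative class.
    """
    dataset.require_both_classes()
    codes = dataset.code_matrix()
    if kind == "PSDP":
        codes = _dinucleotide_codes(codes)
        n_symbols = 16
    elif kind == "PSNP":
        n_symbols = 4
    else:
        raise ValidationError(f"kind must be PSNP or PSDP, got {kind!r}")
    Z_plus = _position_frequencies(codes[dataset.labels], n_symbols)
    Z_minus = _position_frequencies(codes[~dataset.labels], n_symbols)
    return PropensityMatrix(kind=kind, Z_plus=Z_plus, Z_minus=Z_minus, xi=dataset.xi)


def encode_nc(segment: RNASegment) -> np.ndarray:
    """4-dim nucleotide composition (A, C, G, U frequencies; sums to 1)."""
    counts = np.bincount(segment.codes(), minlength=4)
    return counts / segment.length


def encode_dc(segment: RNASegment) -> np.ndarray:
    """16-dim dinucleotide composition over the L−1 overlapping pairs
    (lexicographic AA..UU; sums to 1)."""
    codes = segment.codes()
    di = 4 * codes[:-1] + codes[1:]
    counts = np.bincount(di, minlength=16)
    return counts / (segment.length - 1)


def _theta(
    di_codes: np.ndarray, lam: int, table: PhysicochemicalTable
) -> np.ndarray:
    """Tier-correlation factors θ_1..θ_λ.

    θ_j averages Θ(D_i, D_{i+j}) over all i, where Θ is the mean squared
    difference of the (normalized) property values of the two dinucleotides.
    """
    P = table.values  # (16, n_props)
    thetas = np.empty(lam)
    for j in range(1, lam + 1):
        a = P[di_codes[:-j]]
        b = P[di_codes[j:]]
        thetas[j - 1] = np.mean(np.sum((a - b) ** 2, axis=1) / P.shape[1])
    return thetas


def encode_psednc(
    segment: RNASegment,
    cfg: PseDNCConfig | None = None,
    table: PhysicochemicalTable | None = None,
) -> np.ndarray:
    """(16+λ)-dim pseudo dinucleotide composition.

    The first 16 components are the dinucleotide frequencies f_u and the
    last λ are the weighted tier correlations, jointly normalized:

        d_u = f_u / (Σf + w·Σθ)           u = 1..16
        d_{16+j} = w·θ_j / (Σf + w·Σθ)    j = 1..λ

    so the vector is non-negative and sums to 1, and λ=0 reduces exactly
    to DC. ``table`` is normalized automatically if passed raw.
    """
    cfg = cfg or PseDNCConfig()
    L = segment.length
    if cfg.lam > L - 2:
        raise ValidationError(
            f"lambda={cfg.lam} too large for segment length {L} (max {L - 2})"
        )
    f = encode_dc(segment)
    if cfg.lam == 0:
        return f
    if table is None:
        table = load_property_table()
    table = table.select(cfg.properties)
    if not table.normalized:
        table = normalize_properties(table)
    codes = segment.codes()
    di = 4 * codes[:-1] + codes[1:]
    thetas = _theta(di, cfg.lam, table)
    denom = f.sum() + cfg.w * thetas.sum()
    return np.concatenate([f, cfg.w * thetas]) / denom


def _check_xi(segment: RNASegment, matrix: PropensityMatrix) -> None:
    if segment.xi != matrix.xi:
        raise ValidationError(
            f"segment xi={segment.xi} does not match matrix xi={matrix.xi}"
        )


def encode_psnp(segment: RNASegment, matrix: PropensityMatrix) -> np.ndarray:
    """(2ξ+1)-dim PSNP encoding: component j is Z[N_j, j].

    The center component is always 0 (the center is U in both classes); it
    is kept so the vector length matches the matrix width.
    """
    if matrix.kind != "PSNP":
        raise ValidationError(f"expected a PSNP matrix, got {matrix.kind}")
    _check_xi(segment, matrix)
    codes = segment.codes()
    return matrix.Z[codes, np.arange(len(codes))]


def encode_psdp(segment: RNASegment, matrix: PropensityMatrix) -> np.ndarray:
    """2ξ-dim PSDP encoding: component j is Z[D_j, j] over the overlapping
    dinucleotides D_1..D_2ξ."""
    if matrix.kind != "PSDP":
        raise ValidationError(f"expected a PSDP matrix, got {matrix.kind}")
    _check_xi(segment, matrix)
    codes = segment.codes()
    di = 4 * codes[:-1] + codes[1:]
    return matrix.Z[di, np.arange(len(di))]


@dataclass(frozen=True)
class FeatureRecipe:
    """An ordered, duplicate-free combination of feature types.

    ``names`` is drawn from {NC, DC, pseDNC, PSNP, PSDP}; encoding
    concatenates the component vectors in this order. ``psednc`` holds the
    pseDNC hyperparameters when that feature participates.
    """

    names: tuple[str, ...]
    psednc: PseDNCConfig = field(default_factory=PseDNCConfig)

    def __post_init__(self) -> None:
        if not self.names:
            raise ValidationError("feature recipe must be nonempty")
        if len(set(self.names)) != len(self.names):
            raise ValidationError(f"duplicate feature names in {self.names}")
        unknown = [n for n in self.names if n not in FEATURE_NAMES]
        if unknown:
            raise ValidationError(f"unknown feature names: {unknown}")

    @property
    def needs_fitting(self) -> bool:
        return any(n in ("PSNP", "PSDP") for n in self.names)

    def required_matrices(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if n in ("PSNP", "PSDP"))

    def dimension(self, xi: int) -> int:
        dims = {
            "NC": 4,
            "DC": 16,
            "pseDNC": 16 + self.psednc.lam,
            "PSNP": 2 * xi + 1,
            "PSDP": 2 * xi,
        }
        return sum(dims[n] for n in self.names)

    def __str__(self) -> str:
        return "+".join(self.names)


def fit_recipe_matrices(
    dataset: LabeledDataset, recipe: FeatureRecipe
) -> dict[str, PropensityMatrix]:
    """Fit every propensity matrix the recipe needs, from ``dataset`` only."""
    return {k: fit_propensity(dataset, k) for k in recipe.required_matrices()}


def encode(
    segment: RNASegment,
    recipe: FeatureRecipe,
    fitted: Mapping[str, PropensityMatrix] | None = None,
    table: PhysicochemicalTable | None = None,
) -> np.ndarray:
    """Concatenated feature vector for one segment, in recipe order."""
    fitted = fitted or {}
    parts = []
    for name in recipe.names:
        if name == "NC":
            parts.append(encode_nc(segment))
        elif name == "DC":
            parts.append(encode_dc(segment))
        elif name == "pseDNC":
            parts.append(encode_psednc(segment, recipe.psednc, table))
        else:  # PSNP / PSDP
            if name not in fitted:
                raise ValidationError(
                    f"recipe requires a fitted {name} matrix; none provided"
                )
            enc = encode_psnp if name == "PSNP" else encode_psdp
            parts.append(enc(segment, fitted[name]))
    return np.concatenate(parts)


def encode_dataset(
    segments: Iterable[RNASegment],
    recipe: FeatureRecipe,
    fitted: Mapping[str, PropensityMatrix] | None = None,
    table: PhysicochemicalTable | None = None,
) -> np.ndarray:
    """Feature matrix (n_segments x dimension) for a collection of segments."""
    return np.stack([encode(s, recipe, fitted, table) for s in segments])


def feature_component_names(recipe: FeatureRecipe, xi: int) -> list[str]:
    """Column labels for exported feature matrices."""
    labels: list[str] = []
    for name in recipe.names:
        if name == "NC":
            labels += [f"NC_{nt}" for nt in ALPHABET]
        elif name == "DC":
            labels += [f"DC_{d}" for d in DINUCLEOTIDES]
        elif name == "pseDNC":
            labels += [f"pseDNC_{d}" for d in DINUCLEOTIDES]
            labels += [f"pseDNC_theta{j}" for j in range(1, recipe.psednc.lam + 1)]
        elif name == "PSNP":
            labels += [f"PSNP_pos{j}" for j in range(1, 2 * xi + 2)]
        else:
            labels += [f"PSDP_pos{j}" for j in range(1, 2 * xi + 1)]
    return labels
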