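"""Model training, persistence, and Ψ-site scanning of query sequences.

A trained predictor is a :class:`ModelBundle`: the RBF-SVM, the propensity
matrices fitted on the full training set, the feature recipe and
hyperparameters, and provenance. ``scan_sequence`` applies a bundle to an
arbitrary RNA: every uridine becomes one fixed-length segment (mirror-padded
near the termini), is encoded with the bundle's matrices, and is scored by
the SVM decision function; a site is called Ψ when the score exceeds 0.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import yaml
from sklearn.svm import SVC

from pseui._version import __version__ as _pkg_version
from pseui.errors import BundleLoadError, ValidationError
from pseui.encoders import (
    FeatureRecipe,
    PhysicochemicalTable,
    PropensityMatrix,
    PseDNCConfig,
    encode_dataset,
    fit_recipe_matrices,
)
from pseui.segments_io import LabeledDataset, RNASegment, extract_segments
from pseui.validation import SVMConfig

#: bundle format version; bumped on any incompatible layout change
BUNDLE_FORMAT = 1


def config_hash(payload: Mapping) -> str:
    """Short stable hash of a run configuration, for artifact stamping."""
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class ModelBundle:
    """A deployable Ψ-site predictor.

    Bundles are self-contained: the SVM, the fitted propensity matrices,
    the feature recipe and SVM hyperparameters, the half-window size, and
    provenance (training-set name, species tag, config hash, package
    version) travel together so predictions are reproducible.
    """

    svc: SVC
    recipe: FeatureRecipe
    matrices: dict[str, PropensityMatrix]
    svm_config: SVMConfig
    xi: int
    species: str = ""
    training_set: str = ""
    config_digest: str = ""
    version: str = _pkg_version
    format: int = BUNDLE_FORMAT

    def __post_init__(self) -> None:
        for kind in self.recipe.required_matrices():
            if kind not in self.matrices:
                raise ValidationError(f"bundle missing fitted {kind} matrix")
            if self.matrices[kind].xi != self.xi:
                raise ValidationError(
                    f"{kind} matrix xi={self.matrices[kind].xi} != bundle xi={self.xi}"
                )

    @property
    def min_sequence_length(self) -> int:
        return 2 * self.xi + 1


@dataclass(frozen=True)
class SitePrediction:
    """One scored uridine site on a query sequence.

    ``position`` is the 1-based coordinate of the U on the input sequence;
    ``is_psi`` is True iff ``score`` exceeds the decision threshold 0.
    """

    sequence_id: str
    position: int
    score: float
    is_psi: bool
    segment: str


def train(
    dataset: LabeledDataset,
    recipe: FeatureRecipe,
    svm: SVMConfig,
    species: str = "",
    table: PhysicochemicalTable | None = None,
) -> ModelBundle:
    """Fit propensity matrices and the SVM on the full dataset.

    Deterministic: identical inputs give a bundle with identical behavior.
    """
    dataset.require_both_classes()
    matrices = fit_recipe_matrices(dataset, recipe)
    X = encode_dataset(dataset.segments, recipe, matrices, table)
    clf = svm.make_svc().fit(X, dataset.labels)
    digest = config_hash(
        {
            "dataset": dataset.name,
            "n": len(dataset),
            "xi": dataset.xi,
            "recipe": recipe.names,
            "psednc": (recipe.psednc.lam, recipe.psednc.w, recipe.psednc.properties),
            "c": svm.c,
            "s": svm.s,
        }
    )
    return ModelBundle(
        svc=clf,
        recipe=recipe,
        matrices=matrices,
        svm_config=svm,
        xi=dataset.xi,
        species=species,
        training_set=dataset.name,
        config_digest=digest,
    )


def predict_scores(
    bundle: ModelBundle,
    segments: Sequence[RNASegment],
    table: PhysicochemicalTable | None = None,
) -> np.ndarray:
    """SVM decision scores for segments; positive score means Ψ."""
    for seg in segments:
        if seg.xi != bundle.xi:
            raise ValidationError(
                f"segment xi={seg.xi} does not match bundle xi={bundle.xi}"
            )
    if not segments:
        return np.empty(0)
    X = encode_dataset(segments, bundle.recipe, bundle.matrices, table)
    return bundle.svc.decision_function(X)


def scan_sequence(
    bundle: ModelBundle,
    sequence_id: str,
    sequence: str,
    table: PhysicochemicalTable | None = None,
) -> list[SitePrediction]:
    """Score every uridine in a query RNA sequence.

    The sequence must be at least 2ξ+1 nt long for the bundle's ξ (21 nt
    for the ξ=10 models, 31 nt for ξ=15); uridines closer than ξ to a
    terminus are scored on mirror-padded segments.
    """
    if len(sequence) < bundle.min_sequence_length:
        raise ValidationError(
            f"sequence {sequence_id!r} has length {len(sequence)}; the "
            f"{bundle.species or 'loaded'} model requires at least "
            f"{bundle.min_sequence_length} nt"
        )
    segments = extract_segments(sequence, bundle.xi, sequence_id)
    scores = predict_scores(bundle, segments, table)
    return [
        SitePrediction(
            sequence_id=sequence_id,
            position=seg.origin[1],
            score=float(score),
            is_psi=bool(score > 0.0),
            segment=seg.sequence,
        )
        for seg, score in zip(segments, scores)
    ]


def save_bundle(bundle: ModelBundle, path: str | Path) -> None:
    """Persist a bundle (joblib archive with a format-version field)."""
    payload = {"format": BUNDLE_FORMAT, "version": bundle.version, "bundle": bundle}
    joblib.dump(payload, path)


def load_bundle(path: str | Path) -> ModelBundle:
    """Load a persisted bundle, checking the format version."""
    try:
        payload = joblib.load(path)
    except Exception as exc:  # corrupt / truncated / not a joblib file
        raise BundleLoadError(f"cannot read bundle {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format" not in payload:
        raise BundleLoadError(f"{path} is not a model bundle")
    if payload["format"] != BUNDLE_FORMAT:
        raise BundleLoadError(
            f"{path}: bundle format {payload['format']} unsupported "
            f"(expected {BUNDLE_FORMAT})"
        )
    bundle = payload["bundle"]
    if not isinstance(bundle, ModelBundle):
        raise BundleLoadError(f"{path}: payload is not a ModelBundle")
    return bundle


def load_species_preset(species: str) -> dict:
    """Load a shipped species preset (``human``, ``yeast`` or ``mouse``).

    Presets carry each species' half-window size, optimal feature recipe and
    SVM hyperparameters, and the name of the benchmark training set the
    deployed model is meant to be trained on.
    """
    ref = resources.files("pseui.data") / f"species_{species}.yaml"
    try:
        with resources.as_file(ref) as p:
            with open(p) as fh:
                raw = yaml.safe_load(fh)
    except FileNotFoundError as exc:
        raise ValidationError(
            f"unknown species {species!r} (expected human, yeast or mouse)"
        ) from exc
    return raw


def preset_recipe(preset: dict) -> FeatureRecipe:
    psednc = preset.get("psednc", {})
    return FeatureRecipe(
        tuple(preset["recipe"]),
        psednc=PseDNCConfig(
            lam=psednc.get("lambda", 2), w=psednc.get("w", 0.5)
        ),
    )


def preset_svm(preset: dict) -> SVMConfig:
    return SVMConfig(c=preset["box_constraint"], s=preset["kernel_scale"])
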