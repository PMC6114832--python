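"""Sequential forward feature selection over the five feature types.

A greedy wrapper: round 1 scores each candidate feature type alone via
jackknife (with a fresh hyperparameter grid search per candidate); every
later round scores each one-type extension of the incumbent recipe. The
search stops when no extension strictly improves the selection criterion;
the incumbent is the optimal subset. This mirrors how compact feature
combinations such as PSNP+DC are arrived at on the Ψ-site benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pseui.errors import ValidationError
from pseui.encoders import FEATURE_NAMES, FeatureRecipe, PhysicochemicalTable, PseDNCConfig
from pseui.metrics import MetricSet
from pseui.segments_io import LabeledDataset
from pseui.validation import GridSpec, SVMConfig, grid_search, jackknife


@dataclass(frozen=True)
class CandidateScore:
    """One evaluated candidate recipe: its best SVM config and metrics."""

    recipe: FeatureRecipe
    svm: SVMConfig
    metrics: MetricSet

    def criterion_value(self, criterion: str) -> float:
        return self.metrics.mcc if criterion == "MCC" else self.metrics.acc


@dataclass
class SFSTrace:
    """Full record of a sequential-forward-selection run.

    ``rounds[r]`` lists every candidate evaluated in round r+1; ``selected``
    holds the winner of each completed round (its criterion strictly
    improved on the previous round); ``final`` is the optimal subset. The
    last entry of ``rounds`` may be a non-improving round whose winner was
    rejected.
    """

    criterion: str
    rounds: list[list[CandidateScore]] = field(default_factory=list)
    selected: list[CandidateScore] = field(default_factory=list)

    @property
    def final(self) -> CandidateScore:
        return self.selected[-1]

    @property
    def n_jackknife_runs(self) -> int:
        """Number of jackknife evaluations performed (candidates × grid cells
        are accounted by the caller's grid size)."""
        return sum(len(r) for r in self.rounds)

    def as_rows(self) -> list[dict]:
        """Flat table mirroring the benchmark result tables: one row per
        evaluated candidate (feature subset, metrics, kernel scale, c)."""
        rows = []
        for rnd, cands in enumerate(self.rounds, start=1):
            for cand in cands:
                rows.append(
                    {
                        "round": rnd,
                        "features": str(cand.recipe),
                        **cand.metrics.as_dict(),
                        "kernel_scale": cand.svm.s,
                        "box_constraint": cand.svm.c,
                    }
                )
        return rows


def _best(cands: list[CandidateScore], criterion: str) -> CandidateScore:
    # tie-break: higher Acc, then fewer features (should not trigger within
    # a round where all candidates have equal size), then recipe name order
    return min(
        cands,
        key=lambda cs: (
            -cs.criterion_value(criterion),
            -cs.metrics.acc,
            len(cs.recipe.names),
            str(cs.recipe),
        ),
    )


def sfs(
    dataset: LabeledDataset,
    candidates: tuple[str, ...] = FEATURE_NAMES,
    grid: GridSpec | None = None,
    criterion: str = "MCC",
    psednc: PseDNCConfig | None = None,
    table: PhysicochemicalTable | None = None,
) -> SFSTrace:
    """Greedy forward selection of feature types with jackknife scoring.

    Every candidate recipe in every round gets its own grid search over the
    SVM hyperparameters. Continuation requires *strict* improvement of the
    criterion (``"MCC"`` default, or ``"Acc"``); equality stops the search.
    """
    if not candidates:
        raise ValidationError("need at least one candidate feature type")
    unknown = [c for c in candidates if c not in FEATURE_NAMES]
    if unknown:
        raise ValidationError(f"unknown candidate features: {unknown}")
    if criterion not in ("MCC", "Acc"):
        raise ValidationError(f"criterion must be MCC or Acc, got {criterion!r}")
    grid = grid or GridSpec()
    psednc = psednc or PseDNCConfig()

    trace = SFSTrace(criterion=criterion)
    incumbent: tuple[str, ...] = ()
    remaining = list(candidates)
    best_value = float("-inf")

    while remaining:
        round_cands = []
        for name in remaining:
            recipe = FeatureRecipe(incumbent + (name,), psednc=psednc)
            svm, _ = grid_search(dataset, recipe, grid, criterion, table)
            result = jackknife(dataset, recipe, svm, table)
            round_cands.append(
                CandidateScore(recipe=recipe, svm=svm, metrics=result.metrics)
            )
        trace.rounds.append(round_cands)
        winner = _best(round_cands, criterion)
        if winner.criterion_value(criterion) > best_value:
            best_value = winner.criterion_value(criterion)
            incumbent = winner.recipe.names
            trace.selected.append(winner)
            remaining = [c for c in candidates if c not in incumbent]
        else:
            break
    if not trace.selected:
        raise ValidationError("selection produced no rounds")  # unreachable
    return trace
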