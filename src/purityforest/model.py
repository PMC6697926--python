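"""Two-step random-forest regression of tumor purity on beta values.

Pipeline: stratified 70/30 train/test partition -> dip (or SD) screening on
the training partition only -> initial 500-tree forest to rank probes by
variable importance -> candidate-size sweep over fractions of the screened
set with out-of-bag (OOB) model selection -> final forest on the chosen
probe set.  The OOB error of a candidate is the mean squared error of each
training sample predicted only by trees whose bootstrap excluded it.

All randomness flows from one seed through named ``numpy`` seed sequences so
each stage is reproducible independently of cohort size; forests use
``max_features=1/3`` (the classical regression-forest default of one third
of the predictors per split).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from .dip import ProbeRanking, rank_probes_by_dip, rank_probes_by_sd, select_top_fraction
from .io import BetaMatrix, PurityTable, ValidationError

__all__ = [
    "Partition",
    "CandidateSweep",
    "TrainConfig",
    "PurityModel",
    "candidate_counts",
    "partition_samples",
    "train_initial_forest",
    "sweep_candidates",
    "train_purity_model",
    "predict_purity",
]

MAX_FEATURES = 1.0 / 3.0


def _stage_seed(seed: int, stage: str) -> int:
    """Stable 31-bit seed for a named pipeline stage."""
    ss = np.random.SeedSequence([seed, int.from_bytes(stage.encode(), "little") % (2**63)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass(frozen=True)
class Partition:
    """Disjoint train/test split of the labeled samples."""

    train_ids: tuple
    test_ids: tuple
    train_fraction: float
    stratify_on: str  # "group", "outcome-bins" or "none"
    pooled_fallback: bool = False

    def __post_init__(self):
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValidationError(f"train/test overlap: {sorted(overlap)[:5]}")


@dataclass(frozen=True)
class CandidateSweep:
    """Record of the candidate-size sweep and the OOB-selected model size."""

    fractions: tuple
    probe_counts: tuple
    oob_errors: tuple
    chosen: int

    def __post_init__(self):
        if list(self.probe_counts) != sorted(set(self.probe_counts)):
            raise ValidationError("candidate probe counts must be strictly increasing")
        if any(c < 1 for c in self.probe_counts):
            raise ValidationError("candidate probe counts must be >= 1")
        best = min(self.oob_errors)
        if self.oob_errors[self.chosen] != best:
            raise ValidationError("chosen candidate does not minimize the OOB error")
        for count, err in zip(self.probe_counts, self.oob_errors):
            if err == best:
                if count != self.probe_counts[self.chosen]:
                    raise ValidationError("OOB tie must resolve to the smallest probe count")
                break


@dataclass(frozen=True)
class TrainConfig:
    """Tunable parameters of the training pipeline (defaults follow the
    published protocol: dip screening at 20%, candidate fractions
    0.1/1/5/10% of the screened set, 500 trees)."""

    screening_method: str = "DIP"  # DIP or SD
    screening_fraction: float = 0.20
    candidate_fractions: tuple = (0.001, 0.01, 0.05, 0.10)
    n_trees: int = 500
    train_fraction: float = 0.70
    min_samples: int = 10
    importance: str = "impurity"  # or "permutation"
    seed: int = 0

    def __post_init__(self):
        if self.screening_method not in {"DIP", "SD"}:
            raise ValidationError(f"unknown screening method {self.screening_method!r}")
        if not 0.0 < self.screening_fraction <= 1.0:
            raise ValidationError("screening fraction must be in (0, 1]")
        if self.importance not in {"impurity", "permutation"}:
            raise ValidationError(f"unknown importance measure {self.importance!r}")

    def to_dict(self) -> dict:
        return {
            "screening.method": self.screening_method,
            "screening.fraction": self.screening_fraction,
            "sweep.fractions": list(self.candidate_fractions),
            "forest.n_trees": self.n_trees,
            "partition.train_fraction": self.train_fraction,
            "screening.min_samples": self.min_samples,
            "forest.importance": self.importance,
            "seed": self.seed,
        }


@dataclass
class PurityModel:
    """Trained two-step forest with its full training provenance."""

    final_probes: tuple
    ensemble: RandomForestRegressor
    screening_method: str
    screening_fraction: float
    candidate_record: tuple  # ((probe_count, oob_error), ...)
    selected_candidate: int
    label_source: str
    seed: int
    version: str
    train_ids: tuple
    test_ids: tuple
    training_medians: pd.Series  # per final probe, for imputation at predict time
    config_echo: dict = field(default_factory=dict)
    notes: tuple = ()

    def __post_init__(self):
        if len(self.final_probes) != len(set(self.final_probes)):
            raise ValidationError("duplicate probes in final model")
        errors = [e for _, e in self.candidate_record]
        if errors and errors[self.selected_candidate] != min(errors):
            raise ValidationError("selected candidate does not minimize OOB error")


# ---------------------------------------------------------------------------


def partition_samples(labels: PurityTable, train_fraction: float = 0.70, seed: int = 0) -> Partition:
    """Reproducible stratified train/test split.

    Stratifies on the group label when present (keeping each entity
    proportionally represented in training, as the published protocol
    checked), otherwise on outcome quintile bins.  A stratum with a single
    sample triggers a pooled, unstratified fallback flagged on the result.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValidationError("train_fraction must be in (0, 1)")
    if len(labels) < 2:
        raise ValidationError("need at least two labeled samples to partition")
    rng = np.random.default_rng(_stage_seed(seed, "partition"))
    ids = labels.sample_ids.to_numpy()

    if labels.group is not None:
        strata = labels.group.reindex(labels.sample_ids)
        stratify_on = "group"
    else:
        bins = pd.qcut(labels.purity.rank(method="first"), q=min(5, len(labels)), labels=False)
        strata = pd.Series(bins.to_numpy(), index=labels.sample_ids)
        stratify_on = "outcome-bins"

    pooled = strata.value_counts().min() < 2
    if pooled:
        strata = pd.Series(0, index=labels.sample_ids)
        stratify_on = "none"

    train, test = [], []
    for _, members in sorted(strata.groupby(strata).groups.items(), key=lambda kv: str(kv[0])):
        members = np.sort(np.asarray(members, dtype=object))
        perm = rng.permutation(len(members))
        n_train = int(round(train_fraction * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1) if len(members) > 1 else n_train
        shuffled = members[perm]
        train.extend(shuffled[:n_train])
        test.extend(shuffled[n_train:])
    # keep the original sample order for readability and determinism
    order = {s: i for i, s in enumerate(ids)}
    train.sort(key=order.get)
    test.sort(key=order.get)
    return Partition(
        train_ids=tuple(train),
        test_ids=tuple(test),
        train_fraction=train_fraction,
        stratify_on=stratify_on,
        pooled_fallback=pooled,
    )


def _forest(n_trees: int, seed: int, oob: bool = False) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=n_trees,
        max_features=MAX_FEATURES,
        oob_score=oob,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )


def _design(x: BetaMatrix, y: PurityTable) -> tuple:
    if not set(y.sample_ids).issubset(set(x.sample_ids)):
        missing = sorted(set(y.sample_ids) - set(x.sample_ids))
        raise ValidationError(f"labeled samples absent from the beta matrix: {missing[:5]}")
    mat = x.values.loc[:, y.sample_ids.tolist()]
    if mat.isna().any().any():
        raise ValidationError(
            "design matrix contains missing values; drop incomplete probes first"
        )
    return mat.T.to_numpy(dtype=float), y.purity.to_numpy(dtype=float), mat.index


def train_initial_forest(
    x: BetaMatrix,
    y: PurityTable,
    n_trees: int = 500,
    seed: int = 0,
    importance: str = "impurity",
) -> ProbeRanking:
    """First forest step: rank the screened probes by variable importance.

    Importance is the forest's built-in impurity (node-variance) decrease by
    default; permutation importance is available via ``importance``.
    A zero-variance outcome is tolerated and flagged in ``ProbeRanking.notes``.
    """
    design, target, probes = _design(x, y)
    if design.shape[0] < 2:
        raise ValidationError("need at least two training samples")
    notes = ()
    if np.ptp(target) == 0.0:
        notes = ("zero-variance outcome: importances are degenerate",)
    forest = _forest(n_trees, _stage_seed(seed, "initial-forest"))
    forest.fit(design, target)
    if importance == "impurity":
        scores = forest.feature_importances_
    elif importance == "permutation":
        perm = permutation_importance(
            forest, design, target, n_repeats=5,
            random_state=_stage_seed(seed, "permutation"),
        )
        scores = perm.importances_mean
    else:
        raise ValidationError(f"unknown importance measure {importance!r}")
    stats = pd.Series(scores, index=probes)
    frame = stats.rename("statistic").rename_axis("probe_id").reset_index()
    frame = frame.sort_values(["statistic", "probe_id"], ascending=[False, True], kind="mergesort")
    ordered = frame.set_index("probe_id")["statistic"]
    return ProbeRanking(
        probe_ids=tuple(ordered.index), statistic=ordered, method="IMPORTANCE", notes=notes
    )


def candidate_counts(n_probes: int, fractions) -> tuple:
    """Probe counts for the candidate sweep: ceil(fraction * n_probes).

    Fractions are taken of the *screened* probe set; 1% of a 20%-screened
    450K array (85,600 probes) gives the published 856-probe model size.
    Fractions must be increasing; on small screened sets two fractions can
    round to the same count, in which case the duplicate is dropped (the
    sweep would fit the identical model twice).
    """
    fractions = list(fractions)
    if fractions != sorted(fractions):
        raise ValidationError(f"candidate fractions must be increasing, got {fractions}")
    counts: list = []
    for frac in fractions:
        if not 0.0 < frac <= 1.0:
            raise ValidationError(f"candidate fraction {frac} out of (0, 1]")
        k = int(np.ceil(frac * n_probes))
        if k < 1:
            raise ValidationError(f"candidate fraction {frac} rounds to zero probes")
        if not counts or k > counts[-1]:
            counts.append(k)
    return tuple(counts)


def _oob_mse(forest: RandomForestRegressor, target: np.ndarray) -> float:
    pred = forest.oob_prediction_
    ok = ~np.isnan(pred)
    return float(np.mean((target[ok] - pred[ok]) ** 2))


def sweep_candidates(
    x: BetaMatrix,
    y: PurityTable,
    importance: ProbeRanking,
    fractions=(0.001, 0.01, 0.05, 0.10),
    n_trees: int = 500,
    seed: int = 0,
) -> CandidateSweep:
    """Fit one forest per candidate size and select the OOB-error minimizer.

    Ties in OOB error resolve to the smallest probe count.
    """
    if importance.method != "IMPORTANCE":
        raise ValidationError("sweep expects an IMPORTANCE ranking from the initial forest")
    if not set(x.probe_ids).issubset(set(importance.probe_ids)):
        raise ValidationError("importance ranking does not cover the candidate probes")
    counts = candidate_counts(len(importance), fractions)
    kept_fractions = []
    seen: set = set()
    for frac in fractions:
        k = int(np.ceil(frac * len(importance)))
        if k in counts and k not in seen:
            kept_fractions.append(frac)
            seen.add(k)
    errors = []
    for idx, k in enumerate(counts):
        top = tuple(importance.probe_ids[:k])
        sub = x.restrict_probes(top)
        design, target, _ = _design(sub, y)
        forest = _forest(n_trees, _stage_seed(seed, f"sweep-{idx}"), oob=True)
        forest.fit(design, target)
        errors.append(_oob_mse(forest, target))
    chosen = int(np.argmin(errors))  # argmin takes the first (smallest count) on ties
    return CandidateSweep(
        fractions=tuple(kept_fractions),
        probe_counts=counts,
        oob_errors=tuple(errors),
        chosen=chosen,
    )


def train_purity_model(
    m: BetaMatrix,
    labels: PurityTable,
    config: TrainConfig = TrainConfig(),
    partition: Partition | None = None,
) -> PurityModel:
    """End-to-end training: partition -> screening (train only) -> initial
    forest -> candidate sweep -> final forest on the chosen probe set.

    Screening and all model selection see only the training partition, so the
    held-out samples never influence the final probe set.  An explicit
    ``partition`` overrides the internal stratified split (e.g. to train on a
    pre-defined cohort subset).
    """
    if len(labels) == 0:
        raise ValidationError("empty label table")
    shared = [s for s in labels.sample_ids if s in set(m.sample_ids)]
    if not shared:
        raise ValidationError("no overlap between matrix samples and labels")
    labels = labels.restrict(shared)

    if partition is None:
        partition = partition_samples(labels, config.train_fraction, config.seed)
    else:
        unknown = set(partition.train_ids) - set(shared)
        if unknown:
            raise ValidationError(f"partition train ids not in the cohort: {sorted(unknown)[:5]}")

    y_train = labels.restrict(partition.train_ids)
    x_train = m.restrict_samples(partition.train_ids)

    # NA policy: a probe with any missing training value is dropped up front
    complete = x_train.values.notna().all(axis=1)
    x_train = BetaMatrix(x_train.values.loc[complete].copy())

    if config.screening_method == "DIP":
        ranking = rank_probes_by_dip(x_train, config.min_samples)
    else:
        ranking = rank_probes_by_sd(x_train, config.min_samples)
    screened = select_top_fraction(ranking, config.screening_fraction)
    x_screened = x_train.restrict_probes(screened)

    initial = train_initial_forest(
        x_screened, y_train, config.n_trees, config.seed, config.importance
    )
    sweep = sweep_candidates(
        x_screened, y_train, initial, config.candidate_fractions, config.n_trees, config.seed
    )
    final_probes = tuple(initial.probe_ids[: sweep.probe_counts[sweep.chosen]])
    x_final = x_screened.restrict_probes(final_probes)
    design, target, probes = _design(x_final, y_train)
    forest = _forest(config.n_trees, _stage_seed(config.seed, "final-forest"), oob=True)
    forest.fit(design, target)

    medians = x_final.values.median(axis=1)
    from . import __version__

    return PurityModel(
        final_probes=final_probes,
        ensemble=forest,
        screening_method=config.screening_method,
        screening_fraction=config.screening_fraction,
        candidate_record=tuple(zip(sweep.probe_counts, sweep.oob_errors)),
        selected_candidate=sweep.chosen,
        label_source=labels.source,
        seed=config.seed,
        version=__version__,
        train_ids=partition.train_ids,
        test_ids=partition.test_ids,
        training_medians=medians,
        config_echo=config.to_dict(),
        notes=initial.notes,
    )


def predict_purity(model: PurityModel, m: BetaMatrix) -> tuple:
    """Predict tumor purity for every sample of ``m``.

    Model probes absent from the matrix (or missing for a sample) are imputed
    with the training-set median stored in the model.  Returns a
    ``PurityTable`` with source ``RF_PREDICTED`` (values truncated into
    [0, 1]) and a per-sample Series with the fraction of imputed probes.
    """
    present = [p for p in model.final_probes if p in set(m.probe_ids)]
    if not present:
        raise ValidationError("none of the model probes are present in the matrix")
    frame = m.values.reindex(index=list(model.final_probes))
    imputed_fraction = frame.isna().mean(axis=0)
    filled = frame.apply(lambda col: col.fillna(model.training_medians), axis=0)
    design = filled.T.to_numpy(dtype=float)
    pred = np.clip(model.ensemble.predict(design), 0.0, 1.0)
    table = PurityTable(
        purity=pd.Series(pred, index=frame.columns, name="purity"),
        source="RF_PREDICTED",
    )
    imputed_fraction.name = "imputed_fraction"
    return table, imputed_fraction
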