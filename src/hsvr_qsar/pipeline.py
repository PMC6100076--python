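"""End-to-end modeling pipeline and run configuration.

Order of stages: descriptor filtering -> autoscaling -> Kennard-Stone
partition -> GA + RFE descriptor-subset selection -> per-subset grid
search building the candidate member pool -> Occam's-razor ensemble
growth with meta-SVR -> full validation battery (internal CV,
Y-scrambling, external statistics, criteria verdict).

All randomized stages derive deterministic substreams from the single run
seed, so a run is exactly reproducible end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from .ensemble import HsvrSelection, PoolEntry, build_candidate_pool, grow_and_select
from .feature_select import GeneticDescriptorSelector, RecursiveEliminator
from .preprocess import (
    Autoscaler,
    DescriptorFilter,
    FilterReport,
    PartitionResult,
    kennard_stone_split,
    random_split,
)
from .svr_engine import GridSpec
from .validation import (
    CriteriaThresholds,
    MetricReport,
    ScrambleReport,
    evaluate_predictions,
    y_scramble,
)

__all__ = ["RunConfig", "RunResult", "run_pipeline"]

# substream offsets keep per-stage randomness independent of one another
_STAGE_OFFSETS = {"split": 11, "ga": 23, "rfe": 37, "grid": 53, "scramble": 71}


def _stage_seed(seed: int, stage: str) -> int:
    return (seed * 1000 + _STAGE_OFFSETS[stage]) % (2**31 - 1)


@dataclass
class RunConfig:
    """Complete configuration of one modeling run."""

    seed: int = 0
    train_fraction: float = 0.8          # approximate 4:1 train:test
    split_method: Literal["kennard_stone", "random"] = "kennard_stone"
    normalization_policy: Literal["train", "all"] = "train"
    r2_threshold: float = 0.8
    variance_floor: float = 1e-8
    ga_population: int = 30
    ga_generations: int = 50
    subset_size_range: tuple[int, int] = (3, 7)
    rfe_floor_size: int = 3
    folds: int = 10
    grid: Literal["default", "coarse"] = "coarse"
    max_members: int = 4
    pool_cap: int = 12
    scramble_count: int = 25
    rm2_variant: Literal["sqrt", "printed"] = "sqrt"
    meta_inputs: Literal["oof", "insample"] = "oof"
    paper_faithful_selection: bool = False
    thresholds: CriteriaThresholds = field(default_factory=CriteriaThresholds)

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction <= 1.0:
            raise ValueError("train_fraction must be in (0, 1]")
        if self.scramble_count < 1:
            raise ValueError("scramble_count must be >= 1")

    def grid_spec(self) -> GridSpec:
        return GridSpec.default() if self.grid == "default" else GridSpec.coarse()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "thresholds" in raw:
            raw["thresholds"] = CriteriaThresholds(**raw["thresholds"])
        if "subset_size_range" in raw:
            raw["subset_size_range"] = tuple(raw["subset_size_range"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
            if k != "thresholds"
        }
        data["thresholds"] = dict(self.thresholds.__dict__)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class RunResult:
    """Everything a finished run produced."""

    config: RunConfig
    filter_report: FilterReport
    partition: PartitionResult
    scaler: Autoscaler
    selection_chosen: list[str]
    candidate_subsets: list[list[str]]
    pool: list[PoolEntry]
    selection: HsvrSelection
    train_report: MetricReport
    test_report: MetricReport | None
    scramble_report: ScrambleReport | None
    train_ids: list[str]
    test_ids: list[str]

    @property
    def model(self):
        return self.selection.model


def _candidate_subsets(
    surviving: list[str], ga_chosen: list[str], rfe_path: list[list[str]], cap: int
) -> list[list[str]]:
    """Candidate member subsets for the pool.

    The full surviving descriptor set, the GA winner, every RFE pruning
    stage, and the leave-one-out variants of the RFE terminal subset,
    deduplicated in that order and capped for desk-scale combination
    search.  Members trained on different subsets act as local models of
    differing granularity and emphasis; the leave-one-out variants give
    the ensemble complementary views of the response.  If selection
    collapsed to a single subset, it is split in half so an ensemble is
    still possible.
    """
    final = rfe_path[-1] if rfe_path else ga_chosen
    loo_bases = [final]
    if len(rfe_path) > 1:
        loo_bases.append(rfe_path[-2])
    loo_variants = [
        [n for n in base if n != drop]
        for base in loo_bases
        if len(base) > 2
        for drop in base
    ]
    out: list[list[str]] = []
    seen: set[frozenset] = set()
    for subset in [list(surviving), ga_chosen, *rfe_path, *loo_variants]:
        key = frozenset(subset)
        if key not in seen and subset:
            seen.add(key)
            out.append(list(subset))
    if len(out) < 2 and len(out[0]) >= 2:
        base = out[0]
        half = len(base) // 2
        for piece in (base[:half], base[half:]):
            if piece and frozenset(piece) not in seen:
                seen.add(frozenset(piece))
                out.append(list(piece))
    return out[:cap]


def run_pipeline(
    descriptors: pd.DataFrame,
    response: Sequence[float],
    config: RunConfig | None = None,
) -> RunResult:
    """Run the full modeling pipeline on a descriptor table + response.

    ``descriptors`` is indexed by sample id; ``response`` is the observed
    log ER aligned to its rows.
    """
    cfg = config or RunConfig()
    y = pd.Series(np.asarray(response, dtype=float), index=descriptors.index)

    filt = DescriptorFilter(r2_threshold=cfg.r2_threshold, variance_floor=cfg.variance_floor)
    filt.fit(descriptors, y)
    X_filt = filt.transform(descriptors)

    # partition distances live in normalized space: scale on all samples
    # for the split geometry, then refit scaling per the leakage policy
    split_scaler = Autoscaler().fit(X_filt)
    X_norm_all = split_scaler.transform(X_filt)
    if cfg.split_method == "kennard_stone":
        partition = kennard_stone_split(X_norm_all, cfg.train_fraction)
    else:
        partition = random_split(X_norm_all, cfg.train_fraction, seed=_stage_seed(cfg.seed, "split"))

    train_ids, test_ids = partition.train_ids, partition.test_ids
    X_train_raw, X_test_raw = X_filt.loc[train_ids], X_filt.loc[test_ids]
    y_train, y_test = y.loc[train_ids], y.loc[test_ids]

    scaler = Autoscaler().fit(X_train_raw if cfg.normalization_policy == "train" else X_filt)
    X_train = scaler.transform(X_train_raw)
    X_test = scaler.transform(X_test_raw) if len(test_ids) else None

    folds = min(cfg.folds, len(train_ids))
    ga = GeneticDescriptorSelector(
        population=cfg.ga_population,
        generations=cfg.ga_generations,
        subset_size_range=cfg.subset_size_range,
        folds=folds,
        seed=_stage_seed(cfg.seed, "ga"),
    )
    ga.fit(X_train, y_train)
    rfe = RecursiveEliminator(
        floor_size=cfg.rfe_floor_size, folds=folds, seed=_stage_seed(cfg.seed, "rfe")
    )
    rfe.fit(X_train, y_train, start_subset=ga.chosen_)

    subsets = _candidate_subsets(filt.surviving_, ga.chosen_, rfe.path_, cfg.pool_cap)
    grid = cfg.grid_spec()
    pool = build_candidate_pool(
        X_train, y_train, subsets, grid=grid, folds=folds, seed=_stage_seed(cfg.seed, "grid")
    )

    selection = grow_and_select(
        X_train,
        y_train,
        pool,
        X_test=X_test,
        y_test=None if X_test is None else y_test,
        thresholds=cfg.thresholds,
        max_members=cfg.max_members,
        meta_grid=None,  # second level uses the meta-specific default grid
        meta_inputs=cfg.meta_inputs,
        folds=folds,
        seed=_stage_seed(cfg.seed, "grid"),
        paper_faithful_selection=cfg.paper_faithful_selection,
    )

    model = selection.model
    train_report = evaluate_predictions(
        y_train,
        model.predict(X_train),
        context="training",
        q2_cv=selection.train_report.q2_cv,
        rm2_variant=cfg.rm2_variant,
    )
    test_report = None
    if X_test is not None and len(test_ids) >= 2:
        test_report = evaluate_predictions(
            y_test,
            model.predict(X_test),
            context="external",
            observed_train=y_train,
            rm2_variant=cfg.rm2_variant,
        )

    scramble = y_scramble(
        X_train,
        y_train,
        model_factory=model.frozen_clone,
        scrambles=cfg.scramble_count,
        seed=_stage_seed(cfg.seed, "scramble"),
    )

    return RunResult(
        config=cfg,
        filter_report=filt.report_,
        partition=partition,
        scaler=scaler,
        selection_chosen=ga.chosen_,
        candidate_subsets=subsets,
        pool=pool,
        selection=selection,
        train_report=train_report,
        test_report=test_report,
        scramble_report=scramble,
        train_ids=train_ids,
        test_ids=test_ids,
    )
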