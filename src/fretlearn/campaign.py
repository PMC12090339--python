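"""Multi-round create–test–learn campaign orchestration.

A campaign alternates between proposing variants (round 1: a random
combinatorial library; later rounds: Thompson sampling from an ensemble
surrogate trained on everything measured so far), measuring their fitness
(from simulated plates or from scored plate files handed in per round), and
folding the new sequence–fitness pairs back into the training data.  The
wild type is scored on every plate — it is the normalizer — but enters the
training set once, with fitness exactly 1.

The canonical replay configuration mirrors the original screen: region A
(positions 167/169/172) with rounds of 48 random + 10 proposed variants,
region B (217/218/219) with 48 + 32, for 138 measured variants in total.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .acquisition import ProposalBatch, random_batch, thompson_batch
from .fret_scoring import DEFAULT_TRUNCATION, read_plate, score_plate, write_plate
from .sequence_space import (REGION_A, REGION_B, RegionSpec, Variant,
                             enumerate_space)
from .surrogate import (DEFAULT_BOOTSTRAP_FRACTION, DEFAULT_ENSEMBLE_SIZE,
                        TrainingSet, fit_ensemble, save_ensemble)
from .synthetic_data import (KineticParams, LandscapeSpec, make_landscape,
                             simulate_plate, true_fitness)

logger = logging.getLogger("fretlearn.campaign")

#: Fitness above which a variant counts as "active" in round summaries.
DEFAULT_ACTIVITY_THRESHOLD = 0.05


class EnsembleConfig(BaseModel):
    n_members: int = DEFAULT_ENSEMBLE_SIZE
    bootstrap_fraction: float = DEFAULT_BOOTSTRAP_FRACTION


class RegionConfig(BaseModel):
    region_id: str
    positions: tuple[int, ...]
    wildtype: str

    def to_spec(self) -> RegionSpec:
        return RegionSpec(self.region_id, self.positions, self.wildtype)

    @classmethod
    def from_spec(cls, spec: RegionSpec) -> "RegionConfig":
        return cls(region_id=spec.region_id, positions=spec.positions,
                   wildtype=spec.wildtype)


class CampaignConfig(BaseModel):
    """Validated configuration of one region's campaign."""

    region: RegionConfig
    round_sizes: list[int] = Field(min_length=1)
    fret_threshold: float = DEFAULT_TRUNCATION
    activity_threshold: float = DEFAULT_ACTIVITY_THRESHOLD
    ensemble: EnsembleConfig = EnsembleConfig()
    seed: int = 0
    mode: Literal["simulated", "plate-files"] = "simulated"
    landscape_kind: Literal["sparse", "dense", "additive"] = "dense"

    @field_validator("round_sizes")
    @classmethod
    def _positive(cls, v):
        if any(s < 1 for s in v):
            raise ValueError("round sizes must be positive")
        return v

    @model_validator(mode="after")
    def _fits_in_space(self):
        if sum(self.round_sizes) > self.region.to_spec().space_size:
            raise ValueError("total round size exceeds sequence space")
        return self


@dataclass
class RoundRecord:
    """Everything measured and decided in one campaign round."""

    round_index: int                    # 1-based
    policy: str                         # "random" | "thompson"
    proposals: ProposalBatch
    scores: pd.DataFrame                # score_plate output for this round
    summary: dict = field(default_factory=dict)

    def fitness_of_proposals(self) -> pd.Series:
        table = self.scores.set_index("variant_id")["fitness"]
        ids = [p.variant.variant_id for p in self.proposals.proposals]
        return table.reindex(ids)


def summarize_round(record: RoundRecord,
                    activity_threshold: float = DEFAULT_ACTIVITY_THRESHOLD,
                    ) -> dict:
    """Mean/max/SD fitness and fraction active among the round's proposals."""
    f = record.fitness_of_proposals().dropna().to_numpy()
    if f.size == 0:
        return {"n": 0, "mean_fitness": np.nan, "max_fitness": np.nan,
                "sd_fitness": np.nan, "fraction_active": np.nan}
    return {
        "n": int(f.size),
        "mean_fitness": float(f.mean()),
        "max_fitness": float(f.max()),
        "sd_fitness": float(f.std(ddof=1)) if f.size > 1 else float("nan"),
        "fraction_active": float(np.mean(f > activity_threshold)),
    }


class PlateFileSource:
    """Fitness source backed by scored plate files in a directory.

    Expects ``round<r>_plate.csv`` and ``round<r>_layout.csv`` per round.
    A missing file pauses the campaign (raises :class:`CampaignPaused`).
    """

    def __init__(self, directory, wt_variant_id: str = "WT"):
        self.directory = Path(directory)
        self.wt_variant_id = wt_variant_id

    def measure(self, batch: ProposalBatch, round_index: int,
                config: CampaignConfig, rng_seed: int) -> pd.DataFrame:
        plate_path = self.directory / f"round{round_index}_plate.csv"
        layout_path = self.directory / f"round{round_index}_layout.csv"
        if not plate_path.exists() or not layout_path.exists():
            raise CampaignPaused(
                f"waiting for plate files for round {round_index} "
                f"in {self.directory}")
        plate = read_plate(plate_path, layout_path)
        return score_plate(plate, config.fret_threshold, self.wt_variant_id)


class SimulatedSource:
    """Fitness source backed by a ground-truth landscape and plate simulator."""

    def __init__(self, landscape: LandscapeSpec,
                 kinetics: KineticParams = KineticParams(),
                 wt_variant_id: str = "WT",
                 run_dir: Optional[Path] = None):
        self.landscape = landscape
        self.kinetics = kinetics
        self.wt_variant_id = wt_variant_id
        self.run_dir = run_dir

    def measure(self, batch: ProposalBatch, round_index: int,
                config: CampaignConfig, rng_seed: int) -> pd.DataFrame:
        plate = simulate_plate(batch.variants, self.landscape, self.kinetics,
                               seed=rng_seed, wt_variant_id=self.wt_variant_id)
        if self.run_dir is not None:
            rd = self.run_dir / f"round{round_index}"
            rd.mkdir(parents=True, exist_ok=True)
            write_plate(plate, rd / "plate.csv", rd / "layout.csv")
        return score_plate(plate, config.fret_threshold, self.wt_variant_id)


class CampaignPaused(RuntimeError):
    """Raised when a plate-files campaign is waiting for the next plate."""


def run_campaign(config: CampaignConfig, fitness_source=None,
                 run_dir=None) -> list[RoundRecord]:
    """Run (or replay) a full campaign; returns one record per round.

    Round 1 draws a random library; every later round fits the bootstrapped
    ensemble on all accumulated (variant, fitness) data — the WT included
    once with fitness 1 — and proposes the next batch by Thompson sampling
    over the enumerated space, excluding everything already measured.

    All randomness derives from ``config.seed`` through a seed tree, so a
    completed simulated campaign replays bit-for-bit from its config.
    """
    region = config.region.to_spec()
    run_dir = Path(run_dir) if run_dir is not None else None
    if run_dir is not None:
        run_dir.mkdir(parents=True, exist_ok=True)
        (run_dir / "config.json").write_text(config.model_dump_json(indent=2))

    ss = np.random.SeedSequence(config.seed)
    land_seed, *round_seeds = [int(s.generate_state(1)[0] % 2**31)
                               for s in ss.spawn(1 + 2 * len(config.round_sizes))]
    if fitness_source is None:
        if config.mode != "simulated":
            fitness_source = PlateFileSource(run_dir or ".")
        else:
            landscape = make_landscape(region, config.landscape_kind,
                                       seed=land_seed)
            fitness_source = SimulatedSource(landscape, run_dir=run_dir)

    candidates = enumerate_space(region)
    wt = region.wildtype_variant()
    measured: set[str] = {wt.identities}
    train_variants: list[Variant] = [wt]
    train_fitness: list[float] = [1.0]
    records: list[RoundRecord] = []

    for r, size in enumerate(config.round_sizes, start=1):
        propose_seed, plate_seed = round_seeds[2 * (r - 1): 2 * r]
        if r == 1:
            batch = random_batch(candidates, measured, size,
                                 rng=propose_seed, round_index=r)
        else:
            data = TrainingSet(region, list(train_variants),
                               np.asarray(train_fitness))
            ensemble = fit_ensemble(
                data, n_members=config.ensemble.n_members,
                bootstrap_fraction=config.ensemble.bootstrap_fraction,
                seed=propose_seed)
            if run_dir is not None:
                save_ensemble(ensemble, run_dir / f"round{r}" / "model")
            batch = thompson_batch(ensemble, candidates, region, measured,
                                   size, rng=propose_seed, round_index=r)
        # give proposals campaign-stable ids before measuring
        batch = _relabel(batch, region.region_id, r)
        scores = fitness_source.measure(batch, r, config, plate_seed)
        logger.info("round %d (%s): measured %d variants", r, batch.policy,
                    len(batch.proposals))
        for p in batch.proposals:
            measured.add(p.variant.identities)
            row = scores.loc[scores.variant_id == p.variant.variant_id]
            if row.empty or not np.isfinite(row.fitness.iloc[0]):
                continue        # unscorable replicate set: logged, not trained on
            train_variants.append(p.variant)
            train_fitness.append(float(row.fitness.iloc[0]))
        record = RoundRecord(r, batch.policy, batch, scores)
        record.summary = summarize_round(record, config.activity_threshold)
        records.append(record)
        if run_dir is not None:
            rd = run_dir / f"round{r}"
            rd.mkdir(parents=True, exist_ok=True)
            batch.to_table().to_csv(rd / "proposals.csv", index=False)
            scores.to_csv(rd / "scores.csv", index=False)
            (rd / "summary.json").write_text(json.dumps(record.summary,
                                                        indent=2))
    return records


def _relabel(batch: ProposalBatch, region_id: str, round_index: int,
             ) -> ProposalBatch:
    from .acquisition import Proposal
    relabeled = [
        Proposal(Variant(p.variant.region_id, p.variant.identities,
                         f"{region_id}R{round_index}_{i + 1:03d}"),
                 p.member_index, p.predicted_fitness)
        for i, p in enumerate(batch.proposals)]
    return ProposalBatch(batch.round_index, batch.policy, relabeled,
                         batch.batch_size, batch.short)


def total_measured(records: list[RoundRecord]) -> int:
    """Distinct non-WT variants measured across rounds (the WT, scored on
    every plate as the normalizer, is not counted)."""
    idents = {p.variant.identities
              for rec in records for p in rec.proposals.proposals}
    return len(idents)


def canonical_replay_configs(seed: int = 0) -> list[CampaignConfig]:
    """The canonical two-region replay: A = 48+10 (sparse), B = 48+32 (dense)."""
    return [
        CampaignConfig(region=RegionConfig.from_spec(REGION_A),
                       round_sizes=[48, 10], seed=seed,
                       landscape_kind="sparse"),
        CampaignConfig(region=RegionConfig.from_spec(REGION_B),
                       round_sizes=[48, 32], seed=seed + 1,
                       landscape_kind="dense"),
    ]
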