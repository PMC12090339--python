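"""Batch proposal policies: Thompson sampling and a random baseline.

Thompson sampling over a finite candidate space reduces to: draw one
posterior sample (here, a uniformly random ensemble member) and take the
argmax of its predicted fitness over candidates not yet measured.  For a
batch, the draw-and-argmax step repeats per slot, excluding both measured
variants and earlier slots; no model refit happens mid-batch, since no new
fitness data exists until the whole batch is assayed.  Ties break toward
the lowest enumeration index, which makes batches deterministic given the
member draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequence_space import RegionSpec, Variant, VariantOneHotEncoder
from .surrogate import BootstrapEnsembleRegressor


@dataclass
class Proposal:
    variant: Variant
    member_index: int | None     # ensemble member that selected it (None = random policy)
    predicted_fitness: float | None


@dataclass
class ProposalBatch:
    """An ordered batch of proposed variants for one campaign round."""

    round_index: int
    policy: str                  # "thompson" | "random"
    proposals: list[Proposal]
    batch_size: int              # requested size; len(proposals) may be smaller
    short: bool = False          # True if the candidate pool ran out

    @property
    def variants(self) -> list[Variant]:
        return [p.variant for p in self.proposals]

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rank": np.arange(1, len(self.proposals) + 1),
            "variant_id": [p.variant.variant_id for p in self.proposals],
            "identities": [p.variant.identities for p in self.proposals],
            "member_index": [p.member_index for p in self.proposals],
            "predicted_fitness": [p.predicted_fitness for p in self.proposals],
        })


def thompson_batch(ensemble: BootstrapEnsembleRegressor,
                   candidates: list[Variant],
                   region: RegionSpec,
                   measured: set[str],
                   batch_size: int,
                   rng: np.random.Generator | int,
                   round_index: int = 2) -> ProposalBatch:
    """Propose ``batch_size`` distinct unmeasured variants by Thompson sampling.

    Parameters
    ----------
    candidates : list of Variant
        The enumerated space in its canonical order (ties break toward the
        lowest index in this list).
    measured : set of str
        Identities already assayed in any prior round (the WT included).
    rng : numpy Generator or int seed
        Consumed only by the per-slot member draws.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    enc = VariantOneHotEncoder(region).fit()
    X = enc.transform(candidates)
    preds = ensemble.member_predictions(X)   # (k, n_candidates)
    excluded = np.array([c.identities in measured for c in candidates])
    proposals: list[Proposal] = []
    for _ in range(batch_size):
        if excluded.all():
            warnings.warn("candidate pool exhausted; returning short batch")
            break
        member = int(rng.integers(preds.shape[0]))
        scores = np.where(excluded, -np.inf, preds[member])
        best = int(np.argmax(scores))        # argmax takes the lowest index on ties
        excluded[best] = True
        proposals.append(Proposal(candidates[best], member,
                                  float(preds[member, best])))
    return ProposalBatch(round_index, "thompson", proposals, batch_size,
                         short=len(proposals) < batch_size)


def random_batch(candidates: list[Variant],
                 measured: set[str],
                 batch_size: int,
                 rng: np.random.Generator | int,
                 round_index: int = 1) -> ProposalBatch:
    """Uniform random sample of unmeasured candidates (baseline policy)."""
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    pool = [c for c in candidates if c.identities not in measured]
    if len(pool) < batch_size:
        warnings.warn("candidate pool exhausted; returning short batch")
    take = min(batch_size, len(pool))
    idx = rng.choice(len(pool), size=take, replace=False) if take else []
    proposals = [Proposal(pool[int(i)], None, None) for i in idx]
    return ProposalBatch(round_index, "random", proposals, batch_size,
                         short=take < batch_size)
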