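"""Combinatorial sequence space over a small set of mutable residues.

A *region* is an ordered set of mutable positions in a protein (1-based
residue numbering) together with their wild-type identities.  A *variant*
is an assignment of one amino acid to each mutable position; the rest of
the protein is held fixed, so a region with P positions spans a 20**P
combinatorial space.  This module defines those types, full enumeration
of the space, random library design with per-position coverage checking,
and a scikit-learn style one-hot encoder used by the surrogate model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

#: Canonical 20-letter amino-acid alphabet in fixed alphabetical order.
#: Any fixed order would do; this one is pinned for reproducibility of
#: enumeration order and one-hot bit layout.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"


class EmptyRegionError(ValueError):
    """Raised when a region has no mutable positions."""


class InfeasibleLibraryError(ValueError):
    """Raised when more distinct variants are requested than the space holds."""


@dataclass(frozen=True)
class RegionSpec:
    """A mutable region: ordered residue positions and wild-type identities.

    Parameters
    ----------
    region_id : str
        Short label, e.g. ``"A"`` or ``"B"``.
    positions : tuple of int
        Strictly increasing 1-based residue indices.
    wildtype : str
        Wild-type amino acid at each position, same length as ``positions``.
    alphabet : str
        Ordered amino-acid alphabet (20 unique letters).
    """

    region_id: str
    positions: tuple[int, ...]
    wildtype: str
    alphabet: str = AMINO_ACIDS

    def __post_init__(self) -> None:
        if len(self.positions) == 0:
            raise EmptyRegionError(f"region {self.region_id!r} has no positions")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("positions must be strictly increasing")
        if len(self.wildtype) != len(self.positions):
            raise ValueError("wildtype length must match number of positions")
        if len(set(self.alphabet)) != 20 or len(self.alphabet) != 20:
            raise ValueError("alphabet must contain 20 unique letters")
        if any(a not in self.alphabet for a in self.wildtype):
            raise ValueError("wildtype letters must be in the alphabet")

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    @property
    def space_size(self) -> int:
        """20**P, the number of variants in the combinatorial space."""
        return len(self.alphabet) ** self.n_positions

    def wildtype_variant(self, variant_id: str = "WT") -> "Variant":
        return Variant(region_id=self.region_id, identities=self.wildtype,
                       variant_id=variant_id)


@dataclass(frozen=True)
class Variant:
    """Amino-acid identities at the mutable positions of one region."""

    region_id: str
    identities: str
    variant_id: str = ""

    def validate(self, region: RegionSpec) -> None:
        if self.region_id != region.region_id:
            raise ValueError(
                f"variant belongs to region {self.region_id!r}, "
                f"not {region.region_id!r}")
        if len(self.identities) != region.n_positions:
            raise ValueError("identities length must match region positions")
        bad = [a for a in self.identities if a not in region.alphabet]
        if bad:
            raise ValueError(f"letters outside alphabet: {bad}")


# Standard regions of the Con1 protease used throughout the project:
# region A (H167/L169/F172) proved intolerant to mutation, region B
# (L217/Q218/E219) tolerant.
REGION_A = RegionSpec("A", (167, 169, 172), "HLF")
REGION_B = RegionSpec("B", (217, 218, 219), "LQE")


def enumerate_space(region: RegionSpec) -> list[Variant]:
    """All 20**P variants in lexicographic order (position-major, alphabet order).

    The first element is ``alphabet[0]`` at every position; the wild type
    appears exactly once.
    """
    variants = []
    for i, combo in enumerate(itertools.product(region.alphabet,
                                                repeat=region.n_positions)):
        ident = "".join(combo)
        variants.append(Variant(region.region_id, ident, f"v{i:05d}"))
    return variants


def random_library(region: RegionSpec, n: int, seed: int | np.random.Generator,
                   exclude_wildtype: bool = True) -> list[Variant]:
    """Draw ``n`` distinct random variants, each position uniform over the alphabet.

    Duplicates are rejected and redrawn, so the library lists ``n`` distinct
    identities.  The wild-type triple is excluded from the draw by default
    (it is appended separately to training sets, with fitness 1); pass
    ``exclude_wildtype=False`` to allow it.

    Raises
    ------
    InfeasibleLibraryError
        If ``n`` exceeds the number of available distinct variants.
    """
    rng = np.random.default_rng(seed)
    available = region.space_size - (1 if exclude_wildtype else 0)
    if n > available:
        raise InfeasibleLibraryError(
            f"requested {n} distinct variants but only {available} available")
    letters = list(region.alphabet)
    seen: set[str] = {region.wildtype} if exclude_wildtype else set()
    out: list[Variant] = []
    while len(out) < n:
        ident = "".join(rng.choice(letters, size=region.n_positions))
        if ident in seen:
            continue
        seen.add(ident)
        out.append(Variant(region.region_id, ident,
                           f"{region.region_id}{len(out) + 1:03d}"))
    return out


def coverage_report(library: list[Variant], region: RegionSpec) -> pd.DataFrame:
    """Per-position amino-acid count table for a designed library.

    Returns a P x 20 DataFrame (rows = region positions, columns = alphabet
    letters).  Column sums of each row equal the library size.  Uncovered
    (position, amino-acid) pairs — zero counts — are what a designer checks
    before ordering a library; use :func:`uncovered_pairs` to list them.
    """
    if not library:
        raise ValueError("empty library")
    for v in library:
        v.validate(region)
    counts = np.zeros((region.n_positions, 20), dtype=int)
    idx = {a: j for j, a in enumerate(region.alphabet)}
    for v in library:
        for p, a in enumerate(v.identities):
            counts[p, idx[a]] += 1
    return pd.DataFrame(counts, index=list(region.positions),
                        columns=list(region.alphabet))


def uncovered_pairs(report: pd.DataFrame) -> list[tuple[int, str]]:
    """(position, amino-acid) pairs with zero count in a coverage report."""
    pos, aa = np.nonzero(report.to_numpy() == 0)
    return [(report.index[i], report.columns[j]) for i, j in zip(pos, aa)]


class VariantOneHotEncoder(BaseEstimator, TransformerMixin):
    """One-hot encode variants of a region as binary vectors of length 20*P.

    Bit layout is position-major, then alphabet order: bits [20*p, 20*(p+1))
    encode position p, with exactly one bit set per block.  The encoding
    carries no notion of amino-acid chemistry and is invertible.

    Follows the scikit-learn transformer contract; ``fit`` only validates and
    records the region, so the encoder composes with sklearn pipelines.
    """

    def __init__(self, region: RegionSpec | None = None):
        self.region = region

    def fit(self, X=None, y=None) -> "VariantOneHotEncoder":
        if self.region is None:
            raise ValueError("region must be set before fitting")
        self.region_ = self.region
        self.n_features_out_ = 20 * self.region.n_positions
        self._index_ = {a: j for j, a in enumerate(self.region.alphabet)}
        return self

    def transform(self, X: list[Variant] | list[str]) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "region_")
        region = self.region_
        out = np.zeros((len(X), self.n_features_out_), dtype=float)
        for i, v in enumerate(X):
            ident = v.identities if isinstance(v, Variant) else v
            if len(ident) != region.n_positions:
                raise ValueError(f"identities {ident!r} have wrong length")
            for p, a in enumerate(ident):
                j = self._index_.get(a)
                if j is None:
                    raise ValueError(f"letter {a!r} outside alphabet")
                out[i, 20 * p + j] = 1.0
        return out

    def inverse_transform(self, X: np.ndarray) -> list[str]:
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "region_")
        region = self.region_
        X = np.asarray(X)
        idents = []
        for row in X.reshape(-1, self.n_features_out_):
            letters = []
            for p in range(region.n_positions):
                block = row[20 * p: 20 * (p + 1)]
                if block.sum() != 1:
                    raise ValueError("invalid one-hot block")
                letters.append(region.alphabet[int(np.argmax(block))])
            idents.append("".join(letters))
        return idents


def encode_one_hot(variant: Variant, region: RegionSpec) -> np.ndarray:
    """One-hot bit vector for a single variant (length 20*P)."""
    variant.validate(region)
    enc = VariantOneHotEncoder(region).fit()
    return enc.transform([variant])[0]


def decode_one_hot(bits: np.ndarray, region: RegionSpec) -> str:
    """Inverse of :func:`encode_one_hot`; returns the identities string."""
    enc = VariantOneHotEncoder(region).fit()
    return enc.inverse_transform(np.asarray(bits)[None, :])[0]


# ---------------------------------------------------------------------------
# External interfaces: variant tables and FASTA export
# ---------------------------------------------------------------------------

def variants_to_table(variants: list[Variant]) -> pd.DataFrame:
    return pd.DataFrame({
        "variant_id": [v.variant_id for v in variants],
        "region_id": [v.region_id for v in variants],
        "identities": [v.identities for v in variants],
    })


def variants_from_table(table: pd.DataFrame) -> list[Variant]:
    return [Variant(str(r.region_id), str(r.identities), str(r.variant_id))
            for r in table.itertuples(index=False)]


def write_variant_table(variants: list[Variant], path) -> None:
    variants_to_table(variants).to_csv(path, sep="\t", index=False)


def read_variant_table(path) -> list[Variant]:
    return variants_from_table(pd.read_csv(path, sep="\t", dtype=str))


def apply_to_sequence(protein_seq: str, region: RegionSpec,
                      variant: Variant) -> str:
    """Full-length protein sequence with the variant's substitutions applied.

    ``protein_seq`` uses 1-based numbering consistent with ``region.positions``
    and must carry the wild-type identity at every mutable position.
    """
    variant.validate(region)
    seq = list(protein_seq)
    for pos, wt, aa in zip(region.positions, region.wildtype, variant.identities):
        if pos > len(seq):
            raise ValueError(f"position {pos} beyond sequence length {len(seq)}")
        if seq[pos - 1] != wt:
            raise ValueError(
                f"sequence has {seq[pos - 1]!r} at {pos}, expected WT {wt!r}")
        seq[pos - 1] = aa
    return "".join(seq)


def export_fasta(variants: list[Variant], region: RegionSpec,
                 protein_seq: str, path) -> None:
    """Write full-length variant sequences as FASTA, one record per variant."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(apply_to_sequence(protein_seq, region, v)),
                         id=v.variant_id or v.identities, description="")
               for v in variants]
    seqio_write(records, path, "fasta")
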