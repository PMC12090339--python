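"""Ground-truth fitness landscapes and simulated FRET plates.

Every pipeline stage is testable in silico: a seeded Potts-like landscape
(per-position fields plus pairwise couplings) assigns a true fitness to each
of the 20**P variants of a region, and a kinetic model turns true fitness
into two-channel plate-reader traces with additive Gaussian channel noise.

Landscape kinds mirror the two experimental regimes observed when mutating
a protease at two three-residue regions:

* ``"sparse"`` — most of sequence space is inactive (fitness 0) and the wild
  type is near-optimal: an intolerant region where random variants are
  overwhelmingly dead.
* ``"dense"`` — every variant retains some activity and a few percent of the
  space beats the wild type: a tolerant region worth optimizing.
* ``"additive"`` — no pairwise couplings; fitness is a sum of per-position
  terms.  Used as an easy, fully checkable reference landscape.

All kinds are rescaled so the wild type's fitness is exactly 1, matching the
WT-normalized scale the scorer produces.

The kinetic model is a first-order approach to plateau: the FRET ratio of a
variant with true fitness f follows

    r(t) = r0 + (rmax - r0) * (1 - exp(-kappa * f * t))

so the initial slope is (rmax - r0) * kappa * f — proportional to fitness,
which is what initial-rate scoring assumes.  The two emission channels are
realized as F520 = blank + S/(1+r) + eps and F480 = blank + S*r/(1+r) + eps
(eps i.i.d. Gaussian); their blank-subtracted ratio is exactly r plus noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .fret_scoring import FluorescencePlate, write_plate
from .sequence_space import RegionSpec, Variant, random_library


@dataclass(frozen=True)
class KineticParams:
    """Parameters of the simulated cleavage kinetics and plate read-out.

    Defaults are chosen so that the wild type (f = 1) crosses the 0.55
    truncation threshold near the middle of a 60-minute assay read every
    minute, and so that WT replicate fitness SD is roughly 0.1 at default
    channel noise.
    """

    r0: float = 0.40              # starting FRET ratio
    rmax: float = 0.90            # plateau ratio
    kappa: float = 0.012          # rate constant per unit fitness, 1/min
    noise_sd: float = 10.0        # additive channel noise, AU
    blank_level: float = 50.0     # blank fluorescence, AU
    signal_scale: float = 1000.0  # total two-channel signal, AU
    timestep: float = 1.0         # minutes between reads
    duration: float = 60.0        # assay length, minutes
    replicates: int = 3           # wells per variant
    n_blanks: int = 4             # water-blank wells per plate

    def __post_init__(self) -> None:
        if not self.r0 < 0.55 < self.rmax:
            raise ValueError("need r0 < 0.55 < rmax for truncation scoring")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")

    def timepoints(self) -> np.ndarray:
        return np.arange(0.0, self.duration + 1e-9, self.timestep)


@dataclass
class LandscapeSpec:
    """A ground-truth fitness function over a region's 20**P space.

    ``fields`` has shape (P, 20); ``couplings`` has shape (n_pairs, 20, 20)
    with pairs in lexicographic position order.  ``fitness_table`` holds the
    fitness of every variant in canonical enumeration order, rescaled so the
    wild type is exactly 1.
    """

    region: RegionSpec
    kind: str
    seed: int
    fields: np.ndarray
    couplings: np.ndarray
    fitness_table: np.ndarray
    gate_fraction: float = 0.0     # fraction of space forced to 0 (sparse)

    @property
    def max_fitness(self) -> float:
        return float(self.fitness_table.max())

    def variant_index(self, identities: str) -> int:
        idx = 0
        for a in identities:
            idx = idx * 20 + self.region.alphabet.index(a)
        return idx


# Scale of the random per-position field terms and of the pairwise coupling
# terms, before rescaling to WT = 1.  Couplings are deliberately smaller than
# fields: epistasis modulates an additive backbone rather than drowning it.
FIELD_SD = 1.0
COUPLING_SD = 0.15


def make_landscape(region: RegionSpec, kind: str, seed: int,
                   gate_fraction: float = 0.9,
                   field_sd: float = FIELD_SD,
                   coupling_sd: float = COUPLING_SD) -> LandscapeSpec:
    """Generate a seeded landscape of the requested kind.

    sparse : at least ``gate_fraction`` of the space is exactly 0 and the
        wild type sits at the 98th percentile of the active scores.
    dense : every variant has positive fitness; the wild type is pinned at
        the 95th percentile so a few percent of the space beats it.
    additive : couplings are zero; dense-style rescaling.
    """
    if kind not in ("sparse", "dense", "additive"):
        raise ValueError(f"unknown landscape kind {kind!r}")
    rng = np.random.default_rng(seed)
    P = region.n_positions
    h = rng.normal(0.0, field_sd, size=(P, 20))
    n_pairs = P * (P - 1) // 2
    if kind == "additive":
        J = np.zeros((n_pairs, 20, 20))
    else:
        J = rng.normal(0.0, coupling_sd, size=(n_pairs, 20, 20))

    raw = _raw_scores(region, h, J)
    wt_idx = _index_of(region, region.wildtype)

    if kind == "sparse":
        if not 0.75 <= gate_fraction < 1:
            raise ValueError("sparse gate_fraction must be in [0.75, 1)")
        cut = np.quantile(raw, gate_fraction)
        fitness = np.where(raw > cut, raw, 0.0)
        # WT is the normalizer and must never be gated: pin it near the top
        # of the active score range (98th percentile of the full raw scores).
        fitness[wt_idx] = np.quantile(raw, 0.98)
        fitness /= fitness[wt_idx]
        gate = gate_fraction
    else:
        # Shift so every variant keeps some activity, then pin WT at the
        # 95th percentile: active, good, but beatable by ~5% of the space.
        shifted = raw - raw.min() + 0.05 * raw.std()
        shifted[wt_idx] = np.quantile(shifted, 0.95)
        fitness = shifted / shifted[wt_idx]
        gate = 0.0

    return LandscapeSpec(region=region, kind=kind, seed=seed, fields=h,
                         couplings=J, fitness_table=fitness,
                         gate_fraction=gate)


def _index_of(region: RegionSpec, identities: str) -> int:
    idx = 0
    for a in identities:
        idx = idx * 20 + region.alphabet.index(a)
    return idx


def _raw_scores(region: RegionSpec, h: np.ndarray, J: np.ndarray) -> np.ndarray:
    """Field + coupling score for every variant, in enumeration order."""
    P = region.n_positions
    size = 20 ** P
    # digits[i, p] = alphabet index of position p in variant i
    ar = np.arange(size)
    digits = np.empty((size, P), dtype=int)
    for p in range(P - 1, -1, -1):
        digits[:, p] = ar % 20
        ar = ar // 20
    raw = np.zeros(size)
    for p in range(P):
        raw += h[p, digits[:, p]]
    pair = 0
    for p in range(P):
        for q in range(p + 1, P):
            raw += J[pair, digits[:, p], digits[:, q]]
            pair += 1
    return raw


def true_fitness(landscape: LandscapeSpec, variant: Variant | str) -> float:
    """Ground-truth fitness of a variant (WT -> 1 exactly)."""
    ident = variant.identities if isinstance(variant, Variant) else variant
    return float(landscape.fitness_table[_index_of(landscape.region, ident)])


def ratio_trajectory(params: KineticParams, fitness: float,
                     t: np.ndarray | None = None) -> np.ndarray:
    """Noiseless FRET-ratio trace for a variant of given true fitness."""
    if fitness < 0:
        raise ValueError("fitness must be >= 0")
    t = params.timepoints() if t is None else np.asarray(t, float)
    return params.r0 + (params.rmax - params.r0) * (
        1.0 - np.exp(-params.kappa * fitness * t))


def simulate_plate(variants: list[Variant], landscape: LandscapeSpec,
                   kinetics: KineticParams = KineticParams(),
                   seed: int = 0,
                   wt_variant_id: str = "WT") -> FluorescencePlate:
    """Simulate a triplicate two-channel plate for the given variants.

    The wild type is added (as ``wt_variant_id``) if not already present —
    every plate carries its own WT wells because WT is the normalizer.
    Wells are laid out variant-major, then replicate; blank wells carry
    only blank level plus noise.
    """
    rng = np.random.default_rng(seed)
    t = kinetics.timepoints()
    idents = {v.identities for v in variants}
    plate_variants = list(variants)
    if landscape.region.wildtype not in idents:
        plate_variants.append(landscape.region.wildtype_variant(wt_variant_id))
    wells: dict[str, np.ndarray] = {}
    layout: dict[str, tuple[str, int]] = {}
    S, B, sd = kinetics.signal_scale, kinetics.blank_level, kinetics.noise_sd
    w = 0
    for v in plate_variants:
        v.validate(landscape.region)
        f = true_fitness(landscape, v)
        r = ratio_trajectory(kinetics, f, t)
        for rep in range(1, kinetics.replicates + 1):
            w += 1
            well = f"W{w:03d}"
            f520 = B + S / (1.0 + r) + rng.normal(0, sd, t.size)
            f480 = B + S * r / (1.0 + r) + rng.normal(0, sd, t.size)
            wells[well] = np.vstack([f480, f520])
            layout[well] = (v.variant_id, rep)
    blanks = []
    for b in range(1, kinetics.n_blanks + 1):
        well = f"BLK{b}"
        wells[well] = B + rng.normal(0, sd, (2, t.size))
        blanks.append(well)
    return FluorescencePlate(t, wells, blanks, layout)


# ---------------------------------------------------------------------------
# Serialization and ready-made fixtures
# ---------------------------------------------------------------------------

def save_landscape(landscape: LandscapeSpec, path) -> None:
    """Serialize a landscape (seed and all terms) to a JSON text file."""
    obj = {
        "region": {"region_id": landscape.region.region_id,
                   "positions": list(landscape.region.positions),
                   "wildtype": landscape.region.wildtype,
                   "alphabet": landscape.region.alphabet},
        "kind": landscape.kind,
        "seed": landscape.seed,
        "gate_fraction": landscape.gate_fraction,
        "fields": landscape.fields.tolist(),
        "couplings": landscape.couplings.tolist(),
        "fitness_table": landscape.fitness_table.tolist(),
    }
    Path(path).write_text(json.dumps(obj))


def load_landscape(path) -> LandscapeSpec:
    obj = json.loads(Path(path).read_text())
    region = RegionSpec(obj["region"]["region_id"],
                        tuple(obj["region"]["positions"]),
                        obj["region"]["wildtype"],
                        obj["region"]["alphabet"])
    return LandscapeSpec(region=region, kind=obj["kind"], seed=obj["seed"],
                         fields=np.array(obj["fields"]),
                         couplings=np.array(obj["couplings"]),
                         fitness_table=np.array(obj["fitness_table"]),
                         gate_fraction=obj["gate_fraction"])


def fixture_bundle(seed: int, outdir, n_variants: int = 48,
                   kinetics: KineticParams = KineticParams()) -> dict[str, dict]:
    """Write a ready-to-score plate + layout + landscape for each kind.

    For each landscape kind a random library of ``n_variants`` plus WT is
    simulated and written as ``<kind>_plate.csv`` / ``<kind>_layout.csv`` /
    ``<kind>_landscape.json``; a ``bundle.json`` manifest records the seed.
    Regeneration with the same seed is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    ss = np.random.SeedSequence(seed)
    region = RegionSpec("B", (217, 218, 219), "LQE")
    for kind, child in zip(("sparse", "dense", "additive"), ss.spawn(3)):
        lib_seed, plate_seed = [int(s.generate_state(1)[0] % 2**31)
                                for s in child.spawn(2)]
        land = make_landscape(region, kind, seed=lib_seed)
        lib = random_library(region, n_variants, seed=lib_seed)
        plate = simulate_plate(lib, land, kinetics, seed=plate_seed)
        plate_path = outdir / f"{kind}_plate.csv"
        layout_path = outdir / f"{kind}_layout.csv"
        land_path = outdir / f"{kind}_landscape.json"
        write_plate(plate, plate_path, layout_path)
        save_landscape(land, land_path)
        manifest[kind] = {"plate": plate_path.name, "layout": layout_path.name,
                          "landscape": land_path.name,
                          "lib_seed": lib_seed, "plate_seed": plate_seed}
    (outdir / "bundle.json").write_text(
        json.dumps({"seed": seed, "kinds": manifest}, indent=2, sort_keys=True))
    return manifest
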