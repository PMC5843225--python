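"""Synthetic-data generators for every stage of the pipeline.

These generators are first-class, tested code: they reproduce the
statistical structure each analysis stage assumes, so the whole pipeline
can be exercised end to end without any external data.

* Drift-correlated allele frequencies along a serial-founder chain, with an
  optional linear migratory-distance effect, plus the implied
  genetic-distance matrix and the true drift covariance.
* Null marker columns for the empirical inflation factor.
* Unphased two-locus genotype samples at specified haplotype frequencies.
* 4C-seq read sets under a distance-decay contact model with a
  dosage-dependent insulator attenuation.
* Noisy qPCR Ct replicates at a specified allelic template ratio.

All generators are pure functions of (configuration, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fourc import FourCParams, FragmentMap, digest, filter_fragments
from .popdata import (
    CtRecord,
    DriftDistanceMatrix,
    GenotypeTable,
    PopulationRecord,
    PopulationTable,
)

__all__ = [
    "DriftSimConfig",
    "DriftTruth",
    "FourCSimConfig",
    "simulate_drift_frequencies",
    "simulate_null_markers",
    "simulate_genotypes",
    "simulate_4c",
    "simulate_ct",
]


@dataclass(frozen=True)
class DriftSimConfig:
    """Serial-founder drift simulation settings.

    Populations sit along a migration route at ``route_km`` positions
    (default: evenly spaced over 0-28,000 km, the span of the study's
    distance table).  Allele frequencies evolve on the arcsine-sqrt scale:
    each population adds one backbone drift increment plus a private
    terminal increment, both N(0, drift_sd^2).  ``beta_true`` (km per
    radian) adds distance/beta_true to the arcsine value, so a GLS of
    distance on the transformed frequency has slope beta_true in the
    noiseless limit.  The default drift_sd of 0.03/split gives a cumulative
    dispersion (~0.2 rad over 43 populations) comparable to the real
    markers' spread, while keeping boundary clipping rare.
    """

    n_pops: int = 43
    route_km: tuple[float, ...] | None = None
    beta_true: float = 0.0
    drift_sd: float = 0.03
    p0: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pops < 3:
            raise ValueError("need at least 3 populations")
        if self.drift_sd < 0:
            raise ValueError("drift_sd must be nonnegative")
        if not 0 < self.p0 < 1:
            raise ValueError("ancestral frequency must be in (0, 1)")
        if self.route_km is not None and len(self.route_km) != self.n_pops:
            raise ValueError("route_km length must equal n_pops")

    @property
    def distances(self) -> np.ndarray:
        if self.route_km is not None:
            return np.asarray(self.route_km, dtype=float)
        return np.linspace(0.0, 28_000.0, self.n_pops)


@dataclass(frozen=True)
class DriftTruth:
    """Generating truth of one drift simulation replicate."""

    beta_true: float
    drift_sd: float
    x0: float
    cov: np.ndarray  # true covariance of the arcsine-scale drift noise
    n_clipped: int


def _chain_cov(n: int, drift_sd: float) -> np.ndarray:
    """Covariance of the serial-founder drift noise.

    Population i accumulates i backbone increments plus one private one:
    cov(i, j) = drift_sd^2 * min(i, j) off-diagonal, var(i) = drift_sd^2 *
    (i + 1).
    """
    idx = np.arange(n)
    M = np.minimum.outer(idx, idx).astype(float)
    M[np.diag_indices(n)] = idx + 1.0
    return drift_sd**2 * M


def simulate_drift_frequencies(
    cfg: DriftSimConfig,
) -> tuple[PopulationTable, DriftTruth, DriftDistanceMatrix]:
    """Simulate one marker column of drift-correlated allele frequencies.

    Returns the population table (single marker ``sim``), the generating
    truth (including the exact drift noise covariance, for calibrated GLS),
    and the implied genetic-distance matrix D^2 built from unshared branch
    lengths.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_pops
    d = cfg.distances
    x0 = math.asin(math.sqrt(cfg.p0))
    backbone = np.concatenate([[0.0], np.cumsum(rng.normal(0.0, cfg.drift_sd, n - 1))])
    private = rng.normal(0.0, cfg.drift_sd, n)
    x = x0 + backbone + private
    if cfg.beta_true != 0.0:
        x = x + d / cfg.beta_true
    clipped = np.clip(x, 0.0, math.pi / 2.0)
    n_clipped = int(np.sum(clipped != x))
    p = np.sin(clipped) ** 2

    names = tuple(f"pop{i:02d}" for i in range(n))
    records = tuple(
        PopulationRecord(name, float(d[i]), {"sim": float(p[i])})
        for i, name in enumerate(names)
    )
    table = PopulationTable(records, ("sim",))

    cov = _chain_cov(n, cfg.drift_sd)
    var = np.diag(cov)
    D2 = var[:, None] + var[None, :] - 2.0 * cov
    np.fill_diagonal(D2, 0.0)
    truth = DriftTruth(cfg.beta_true, cfg.drift_sd, x0, cov, n_clipped)
    return table, truth, DriftDistanceMatrix(names, D2)


def simulate_null_markers(
    table: PopulationTable,
    n_markers: int = 10_000,
    seed: int | None = None,
    mode: str = "permute",
    drift_sd: float | None = None,
) -> np.ndarray:
    """Null marker columns (no distance effect) for the inflation factor.

    ``mode="permute"`` (default) draws each null column as a random
    permutation of a randomly chosen real marker column: the association
    with distance is destroyed while the marginal frequency distribution is
    preserved.  ``mode="drift"`` draws fresh serial-founder chains (per-step
    sd ``drift_sd``, required) started at a random real marker's mean
    arcsine value — a drift-correlated null even when the input table is
    not.  Returns an (n_populations, n_markers) array.
    """
    rng = np.random.default_rng(seed)
    n = len(table)
    cols = np.column_stack([table.frequencies(m) for m in table.markers])
    cols = cols[:, ~np.any(np.isnan(cols), axis=0)]
    if cols.shape[1] == 0:
        raise ValueError("no complete marker columns to resample from")
    out = np.empty((n, n_markers))
    if mode == "permute":
        for j in range(n_markers):
            src = cols[:, rng.integers(cols.shape[1])]
            out[:, j] = src[rng.permutation(n)]
    elif mode == "drift":
        if drift_sd is None:
            raise ValueError("mode='drift' requires drift_sd")
        x_means = np.arcsin(np.sqrt(cols)).mean(axis=0)
        for j in range(n_markers):
            x0 = x_means[rng.integers(len(x_means))]
            backbone = np.concatenate([[0.0], np.cumsum(rng.normal(0.0, drift_sd, n - 1))])
            x = x0 + backbone + rng.normal(0.0, drift_sd, n)
            out[:, j] = np.sin(np.clip(x, 0.0, math.pi / 2.0)) ** 2
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def simulate_genotypes(
    h: Sequence[float], n_subjects: int, seed: int | None = None
) -> GenotypeTable:
    """Draw unphased two-locus genotypes from haplotype frequencies.

    ``h`` is (Sin-C, Sin-T, Dup-C, Dup-T); each subject is two iid
    haplotype draws with phase erased.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0) or abs(h.sum() - 1.0) > 1e-9:
        raise ValueError("haplotype frequencies must lie on the simplex")
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    rng = np.random.default_rng(seed)
    haps = [("Sin", "C"), ("Sin", "T"), ("Dup", "C"), ("Dup", "T")]
    draws = rng.choice(4, size=(n_subjects, 2), p=h)
    order_a = {"Sin": 0, "Dup": 1}
    order_b = {"C": 0, "T": 1}
    subjects = []
    for h1, h2 in draws:
        a = tuple(sorted((haps[h1][0], haps[h2][0]), key=order_a.get))
        b = tuple(sorted((haps[h1][1], haps[h2][1]), key=order_b.get))
        subjects.append((a, b))
    return GenotypeTable(tuple(subjects))


@dataclass(frozen=True)
class FourCSimConfig:
    """Distance-decay contact model with a dosage-dependent insulator.

    Expected contact weight of a fragment end at coordinate c is
    ``(1 + |c - viewpoint|)^(-decay)``, multiplied by ``1 - s * dosage / 2``
    for ends on the far side of the insulator from the viewpoint (s is the
    per-haplotype attenuation of cross-insulator contacts; dosage counts
    Dup alleles).  Reads are a multinomial draw over ends.  Defaults mirror
    the study design: two donors per genotype, 100k reads each; about 2,000
    fragments (GATC sites of a uniform random sequence, one per ~256 bp).
    """

    n_fragments: int = 2000
    decay: float = 1.0
    insulator_offset_bp: int = 20_000
    insulator_strength: float = 0.5
    reads_per_sample: int = 100_000
    dosages: tuple[int, ...] = (0, 0, 1, 1, 2, 2)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.insulator_strength <= 1.0:
            raise ValueError("insulator strength must be in [0, 1]")
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")
        if any(dose not in (0, 1, 2) for dose in self.dosages):
            raise ValueError("dosages must be 0, 1 or 2")


@dataclass(frozen=True)
class FourCSample:
    """One simulated 4C library: genotype dosage and mapped read starts."""

    dosage: int
    read_starts: np.ndarray
    expected_downstream_fraction: float


def simulate_4c(
    cfg: FourCSimConfig,
) -> tuple[FragmentMap, FragmentMap, FourCParams, tuple[FourCSample, ...]]:
    """Simulate per-sample 4C read sets over a random restriction map.

    Returns (full fragment map, filtered valid map, processing params,
    samples).  Read starts are placed at the boundary-adjacent base of the
    drawn fragment end, so `reads_to_profile` maps them back exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    seq_len = int(cfg.n_fragments * 256)
    seq = "".join(rng.choice(list("ACGT"), size=seq_len))
    fm = digest(seq, name="sim")
    viewpoint = seq_len // 2
    params = FourCParams(viewpoint=viewpoint)
    valid = filter_fragments(fm, params)
    if not valid.fragments:
        raise ValueError("no valid fragments; increase n_fragments")

    coords = np.empty(2 * len(valid.fragments), dtype=int)
    coords[0::2] = [f.start for f in valid.fragments]
    coords[1::2] = [f.end for f in valid.fragments]
    read_pos = np.empty_like(coords)
    read_pos[0::2] = [f.start for f in valid.fragments]
    read_pos[1::2] = [f.end - 1 for f in valid.fragments]

    base = (1.0 + np.abs(coords - viewpoint).astype(float)) ** (-cfg.decay)
    insulator = viewpoint + cfg.insulator_offset_bp
    beyond = coords > insulator if cfg.insulator_offset_bp >= 0 else coords < insulator

    samples = []
    for dosage in cfg.dosages:
        w = base * np.where(beyond, 1.0 - cfg.insulator_strength * dosage / 2.0, 1.0)
        probs = w / w.sum()
        counts = rng.multinomial(cfg.reads_per_sample, probs)
        starts = np.repeat(read_pos, counts)
        down = float(probs[coords > viewpoint].sum())
        up = float(probs[coords < viewpoint].sum())
        samples.append(FourCSample(dosage, starts, down / (down + up)))
    return fm, valid, params, tuple(samples)


def simulate_ct(
    true_ratio: float,
    noise_sd_cycles: float = 0.1,
    replicates: int = 6,
    seed: int | None = None,
    baseline_ct: float = 25.0,
    sample: str = "sim",
) -> tuple[CtRecord, CtRecord]:
    """Simulate (control, sensor) Ct replicate records.

    The control amplicon has a true C/T ratio of 1; the sensor amplicon's
    C-allele Ct is shifted by log2(true_ratio), so 2^deltaCt estimates
    true_ratio.  Gaussian cycle noise (sd ``noise_sd_cycles``) is added to
    every replicate independently.
    """
    if true_ratio <= 0:
        raise ValueError("true_ratio must be positive")
    rng = np.random.default_rng(seed)

    def record(role: str, ratio: float) -> CtRecord:
        ct_t = baseline_ct + rng.normal(0.0, noise_sd_cycles, replicates)
        ct_c = ct_t + math.log2(ratio) + rng.normal(0.0, noise_sd_cycles, replicates)
        return CtRecord(sample, role, tuple(ct_c), tuple(ct_t))

    return record("control", 1.0), record("sensor", true_ratio)
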