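"""4C-seq contact-profile processing and allele-specific 3C quantification.

The 4C pipeline starts from mapped read start positions (BED) against an in
silico double digest of the region: DpnII (GATC) as the primary enzyme
defines restriction fragments, Csp6I (GTAC) as the secondary enzyme marks
which fragments are informative.  Processing follows the standard viewpoint
pipeline: drop blind fragments (no internal secondary site), fragments
shorter than 40 bp, and fragments within 10 kb of the viewpoint; count
reads per primary fragment end; smooth with a 30-fragment running mean;
normalize by the total smoothed weight within +/-2 Mb of the viewpoint.
The downstream/upstream split of normalized contact weight quantifies the
insulation asymmetry, compared across CNV genotypes by Spearman rank
correlation with Dup dosage.

The allele-specific 3C readout is a Taqman Ct difference on a ligation
amplicon: delta Ct = Ct(allele C) - Ct(allele T), and 2^deltaCt estimates
the C/T template ratio; groups are compared with the Mann-Whitney U test.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .popdata import CtRecord

__all__ = [
    "Fragment",
    "FragmentMap",
    "FourCParams",
    "ContactProfile",
    "AsymmetryResult",
    "TrendResult",
    "AlleleContactAssay",
    "digest",
    "filter_fragments",
    "reads_to_profile",
    "smooth_profile",
    "normalize_profile",
    "contact_asymmetry",
    "genotype_trend",
    "allele_ratio",
    "mann_whitney",
    "read_fasta",
    "read_bed_starts",
    "write_bedgraph",
]


@dataclass(frozen=True)
class Fragment:
    """A primary-enzyme restriction fragment [start, end)."""

    start: int
    end: int
    has_secondary_site: bool

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FragmentMap:
    """Ordered restriction fragments of one sequence.

    Fresh digests tile [0, length) without gaps; filtered maps keep only the
    valid subset (``filtered=True``).
    """

    name: str
    length: int
    fragments: tuple[Fragment, ...]
    filtered: bool = False

    def __post_init__(self) -> None:
        if not self.filtered:
            pos = 0
            for f in self.fragments:
                if f.start != pos or f.end <= f.start:
                    raise ValueError("fragments do not tile the sequence")
                pos = f.end
            if pos != self.length:
                raise ValueError("fragments do not cover the sequence")
        else:
            for f, g in zip(self.fragments, self.fragments[1:]):
                if g.start < f.end:
                    raise ValueError("filtered fragments overlap")


@dataclass(frozen=True)
class FourCParams:
    """Processing parameters of the 4C pipeline (defaults per protocol)."""

    viewpoint: int
    min_fragment_bp: int = 40
    viewpoint_exclusion_bp: int = 10_000
    smoothing_window_fragments: int = 30
    normalization_halfwidth_bp: int = 2_000_000

    def __post_init__(self) -> None:
        for name in ("min_fragment_bp", "viewpoint_exclusion_bp",
                     "smoothing_window_fragments", "normalization_halfwidth_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ContactProfile:
    """Per-fragment-end contact signal.

    Each valid fragment contributes two ends; an end's coordinate is the
    fragment boundary it sits on (left end: fragment start; right end:
    fragment end).  ``counts`` are raw reads, ``smoothed`` the running mean,
    ``weights`` the normalized profile (in-window weights sum to 1).
    """

    name: str
    coords: np.ndarray  # fragment-boundary coordinate per end, ordered
    counts: np.ndarray
    smoothed: np.ndarray | None = None
    weights: np.ndarray | None = None
    viewpoint: int | None = None
    halfwidth: int | None = None
    discarded_reads: int = 0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.counts) < 0):
            raise ValueError("negative read counts")

    def in_window(self) -> np.ndarray:
        if self.viewpoint is None or self.halfwidth is None:
            raise ValueError("profile has not been normalized")
        return np.abs(self.coords - self.viewpoint) <= self.halfwidth


def read_fasta(path, name: str | None = None) -> tuple[str, str]:
    """Read one record (by name, or the first) from a FASTA file."""
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fasta"):
        if name is None or rec.id == name:
            return rec.id, str(rec.seq).upper()
    raise ValueError(f"record {name!r} not found in {path}")


def read_bed_starts(path) -> pd.DataFrame:
    """Read mapped read start positions from a (headerless) BED file."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    return df


def write_bedgraph(profile: ContactProfile, path, which: str = "weights") -> None:
    """Export a profile track (counts/smoothed/weights) as bedGraph."""
    values = getattr(profile, which)
    if values is None:
        raise ValueError(f"profile has no {which!r} values")
    with open(path, "w") as fh:
        for c, v in zip(profile.coords, values):
            fh.write(f"{profile.name}\t{c}\t{c + 1}\t{v:.10g}\n")


def _find_all(seq: str, motif: str) -> list[int]:
    out, i = [], seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)  # step 1: overlapping occurrences count
    return out


def digest(sequence: str, primary_motif: str = "GATC",
           secondary_motif: str = "GTAC", name: str = "seq") -> FragmentMap:
    """In silico digest: cut before every primary-motif occurrence.

    Fragments are annotated with whether a full secondary-motif occurrence
    lies inside them (informative vs blind fragments).
    """
    if not sequence:
        raise ValueError("empty sequence")
    sequence = sequence.upper()
    if set(sequence) - set("ACGTN"):
        raise ValueError("sequence contains non-ACGTN characters")
    cuts = [p for p in _find_all(sequence, primary_motif) if p > 0]
    bounds = [0] + cuts + [len(sequence)]
    sec = np.array(_find_all(sequence, secondary_motif), dtype=int)
    frags = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        has = bool(np.any((sec >= s) & (sec + len(secondary_motif) <= e)))
        frags.append(Fragment(s, e, has))
    return FragmentMap(name, len(sequence), tuple(frags))


def filter_fragments(fm: FragmentMap, params: FourCParams) -> FragmentMap:
    """Keep informative fragments: internal secondary site, length >= 40 bp,
    and not overlapping [viewpoint - 10 kb, viewpoint + 10 kb]."""
    if not (0 <= params.viewpoint < fm.length):
        raise ValueError("viewpoint outside the sequence")
    lo = params.viewpoint - params.viewpoint_exclusion_bp
    hi = params.viewpoint + params.viewpoint_exclusion_bp
    kept = tuple(
        f for f in fm.fragments
        if f.has_secondary_site
        and f.length_bp >= params.min_fragment_bp
        and not (f.start <= hi and f.end > lo)  # overlap with closed window
    )
    return FragmentMap(fm.name, fm.length, kept, filtered=True)


def reads_to_profile(read_starts: Sequence[int] | pd.DataFrame,
                     fm: FragmentMap) -> ContactProfile:
    """Assign read starts to primary fragment ends of the valid fragments.

    A read belongs to the end whose half of the fragment contains its start
    (left half -> left end).  Reads falling in removed fragments are
    discarded and counted; reads outside [0, length) raise.
    """
    if isinstance(read_starts, pd.DataFrame):
        read_starts = read_starts["start"].to_numpy()
    pos = np.asarray(read_starts, dtype=int)
    if pos.size and (pos.min() < 0 or pos.max() >= fm.length):
        raise ValueError("read start beyond sequence bounds")
    starts = np.array([f.start for f in fm.fragments], dtype=int)
    ends = np.array([f.end for f in fm.fragments], dtype=int)
    coords = np.empty(2 * len(fm.fragments), dtype=int)
    coords[0::2] = starts
    coords[1::2] = ends
    counts = np.zeros(2 * len(fm.fragments), dtype=int)
    discarded = 0
    if pos.size:
        idx = np.searchsorted(starts, pos, side="right") - 1
        inside = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        discarded = int(np.sum(~inside))
        idx, p = idx[inside], pos[inside]
        mid = (starts[idx] + ends[idx]) / 2.0
        end_idx = 2 * idx + (p >= mid)
        np.add.at(counts, end_idx, 1)
    return ContactProfile(fm.name, coords, counts, discarded_reads=discarded)


def smooth_profile(profile: ContactProfile, window: int = 30) -> ContactProfile:
    """Centered running mean over fragment-end ordinates.

    The interior window covers exactly `window` ends (for even windows, one
    extra on the left); near the edges it shrinks to the symmetric window
    the data can support.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = profile.counts.astype(float)
    n = len(x)
    left = window // 2
    right = window - 1 - left
    out = np.empty(n)
    cumsum = np.concatenate([[0.0], np.cumsum(x)])
    for i in range(n):
        if i >= left and (n - 1 - i) >= right:
            lo, hi = i - left, i + right
        else:
            m = min(i, n - 1 - i, max(left, right))
            lo, hi = i - m, i + m
        out[i] = (cumsum[hi + 1] - cumsum[lo]) / (hi - lo + 1)
    return replace(profile, smoothed=out)


def normalize_profile(profile: ContactProfile, viewpoint: int,
                      halfwidth: int = 2_000_000) -> ContactProfile:
    """Divide the smoothed signal by its total within viewpoint +/- halfwidth."""
    if profile.smoothed is None:
        raise ValueError("smooth the profile before normalizing")
    mask = np.abs(profile.coords - viewpoint) <= halfwidth
    total = float(profile.smoothed[mask].sum())
    if total <= 0:
        raise ValueError("no smoothed signal within the normalization window")
    return replace(profile, weights=profile.smoothed / total,
                   viewpoint=viewpoint, halfwidth=halfwidth)


@dataclass(frozen=True)
class AsymmetryResult:
    """Up/downstream split of in-window normalized contact weight."""

    fraction_upstream: float
    fraction_downstream: float
    dosage: int | None = None  # count of Dup alleles (0/1/2)

    def __post_init__(self) -> None:
        if self.fraction_upstream < 0 or self.fraction_downstream < 0:
            raise ValueError("negative fraction")
        if abs(self.fraction_upstream + self.fraction_downstream - 1.0) > 1e-9:
            raise ValueError("fractions do not sum to 1")


def contact_asymmetry(profile: ContactProfile, viewpoint: int | None = None,
                      dosage: int | None = None) -> AsymmetryResult:
    """Fractions of in-window weight strictly down/upstream of the viewpoint."""
    if profile.weights is None:
        raise ValueError("normalize the profile first")
    vp = profile.viewpoint if viewpoint is None else viewpoint
    mask = profile.in_window()
    w = profile.weights
    down = float(w[mask & (profile.coords > vp)].sum())
    up = float(w[mask & (profile.coords < vp)].sum())
    total = down + up
    if total <= 0:
        raise ValueError("no weight on either side of the viewpoint")
    return AsymmetryResult(up / total, down / total, dosage)


@dataclass(frozen=True)
class TrendResult:
    """Spearman rank correlation of downstream fraction with Dup dosage."""

    rho: float
    pvalue: float
    n: int
    method: str  # "exact-permutation" | "t-approximation"


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def genotype_trend(results: Iterable[AsymmetryResult]) -> TrendResult:
    """Spearman correlation (mid-rank ties) between Dup dosage and the
    downstream contact fraction; exact permutation p for n <= 10, else a
    t-approximation."""
    results = list(results)
    dosages = np.array([r.dosage for r in results], dtype=float)
    fracs = np.array([r.fraction_downstream for r in results], dtype=float)
    n = len(results)
    if n < 3:
        raise ValueError("need at least 3 samples")
    if len(set(dosages)) < 2:
        raise ValueError("need at least 2 distinct dosages")
    if np.ptp(fracs) == 0:
        raise ValueError("constant fractions: correlation undefined")
    rx = stats.rankdata(dosages)
    ry = stats.rankdata(fracs)
    rho = _spearman_rho(rx, ry)
    if n <= 10:
        # permutation distribution of the rank dot product; denominators are
        # permutation-invariant so |rho| ordering equals |S - n*mx*my| ordering
        ry_c = ry - ry.mean()
        obs = abs((rx - rx.mean()) @ ry_c)
        hits = total = 0
        chunk: list[tuple] = []

        def flush(chunk):
            arr = np.asarray(chunk, dtype=float)
            s = np.abs((arr - arr.mean(axis=1, keepdims=True)) @ ry_c)
            return int(np.sum(s >= obs - 1e-9)), len(chunk)

        for perm in itertools.permutations(rx):
            chunk.append(perm)
            if len(chunk) == 100_000:
                h, t = flush(chunk)
                hits, total, chunk = hits + h, total + t, []
        if chunk:
            h, t = flush(chunk)
            hits, total = hits + h, total + t
        return TrendResult(rho, hits / total, n, "exact-permutation")
    t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return TrendResult(rho, min(1.0, p), n, "t-approximation")


@dataclass(frozen=True)
class AlleleContactAssay:
    """Allele-specific 3C readout: delta Ct and the 2^deltaCt C/T ratio."""

    sample: str
    role: str
    delta_ct: float
    ratio: float

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")


def allele_ratio(record: CtRecord) -> AlleleContactAssay:
    """delta Ct = mean Ct(C) - mean Ct(T); ratio = 2^deltaCt.

    Note the qPCR convention: a higher Ct means fewer templates, so a
    positive delta Ct (ratio > 1) means the T allele amplicon was more
    abundant.
    """
    delta = float(np.mean(record.ct_c) - np.mean(record.ct_t))
    return AlleleContactAssay(record.sample, record.role, delta, 2.0 ** delta)


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when n_A + n_B <= 12 with no ties; otherwise the
    normal approximation with tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([a, b])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (a.size + b.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
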