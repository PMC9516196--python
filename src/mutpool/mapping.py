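"""Bulked-segregant SNP-index mapping of a mutant pool.

The mapping stage starts from allele-count variant records (one per candidate
SNP in the mutant pool), applies quality filters, removes SNPs shared with
the wild type or with other mutant pools (each mutagenized line carries a
unique mutation spectrum, so a variant present in another pool is background),
computes per-site SNP indices (alt reads / total reads), smooths them in
sliding windows, and calls peak regions where the windowed index approaches 1
— the signature of a recessive causal locus under phenotype selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class IntegrityError(ValueError):
    """Inconsistent coordinates or duplicate conflicting records."""


@dataclass(frozen=True)
class VariantRecord:
    """One candidate SNP with pooled allele depths and quality metadata.

    Positions are 1-based (VCF convention).  ``true_alt_freq`` is simulation
    truth carried along for testing; it is never used by the pipeline.
    """

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    alt_depth: int
    total_depth: int
    mapping_quality: float = 60.0
    base_quality: float = 30.0
    pool_id: str = ""
    true_alt_freq: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not 0 <= self.alt_depth <= self.total_depth:
            raise ValueError(
                f"need 0 <= alt_depth <= total_depth, got {self.alt_depth}/{self.total_depth}"
            )
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base and alt_base must differ")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_base, self.alt_base)


@dataclass(frozen=True)
class FilterConfig:
    """Quality thresholds (all inclusive lower bounds)."""

    min_mapping_quality: float = 30.0
    min_base_quality: float = 20.0
    min_total_depth: int = 5

    def __post_init__(self) -> None:
        if min(self.min_mapping_quality, self.min_base_quality, self.min_total_depth) < 0:
            raise ValueError("filter thresholds must be >= 0")


def quality_filter(
    records: Iterable[VariantRecord], config: FilterConfig = FilterConfig()
) -> list[VariantRecord]:
    """Keep records meeting every threshold (inclusive); order preserved."""
    return [
        r
        for r in records
        if r.mapping_quality >= config.min_mapping_quality
        and r.base_quality >= config.min_base_quality
        and r.total_depth >= config.min_total_depth
    ]


def _presence_keys(
    record_sets: Sequence[Iterable[VariantRecord]], min_alt_reads: int
) -> set[tuple[str, int, str, str]]:
    keys: set[tuple[str, int, str, str]] = set()
    ref_at: dict[tuple[str, int], str] = {}
    for recs in record_sets:
        for r in recs:
            prev = ref_at.setdefault((r.chrom, r.pos), r.ref_base)
            if prev != r.ref_base:
                raise IntegrityError(
                    f"conflicting ref base at {r.chrom}:{r.pos}: {prev} vs {r.ref_base}"
                )
            if r.alt_depth >= min_alt_reads:
                keys.add(r.key)
    return keys


def exclude_shared(
    target: Iterable[VariantRecord],
    wild_type: Iterable[VariantRecord] = (),
    other_pools: Sequence[Iterable[VariantRecord]] = (),
    presence_min_alt_reads: int = 2,
) -> list[VariantRecord]:
    """Remove target SNPs present in the wild type or in any other pool.

    Presence in another record set means the same (chrom, pos, ref, alt) key
    is supported by at least ``presence_min_alt_reads`` alt reads there —
    read-support presence rather than a genotype call, which is robust at
    ~20x pooled coverage.  Records at the same position with a different alt
    allele are not removed (the key includes the alt base).
    """
    target = list(target)
    exclusion_sets = [list(wild_type), *[list(p) for p in other_pools]]
    shared = _presence_keys(exclusion_sets, presence_min_alt_reads)
    # ref-base consistency across all sets sharing a position
    _presence_keys([target, *exclusion_sets], presence_min_alt_reads)
    return [r for r in target if r.key not in shared]


def compute_snp_index(record: VariantRecord) -> float:
    """SNP index = alt-allele read fraction in the mutant pool."""
    if record.total_depth == 0:
        raise ValueError("SNP index undefined at zero depth")
    return record.alt_depth / record.total_depth


@dataclass
class SNPIndexTrack:
    """Per-site SNP indices, sorted by (chrom, pos).

    ``sites`` has columns chrom, pos, snp_index, total_depth.  ``excluded``
    holds records below the depth floor (flagged, not an error).
    """

    sites: pd.DataFrame
    excluded: list[VariantRecord] = field(default_factory=list)

    @classmethod
    def from_records(
        cls, records: Iterable[VariantRecord], min_total_depth: int = 5
    ) -> "SNPIndexTrack":
        kept, dropped = [], []
        for r in records:
            (kept if r.total_depth >= min_total_depth else dropped).append(r)
        frame = pd.DataFrame(
            {
                "chrom": [r.chrom for r in kept],
                "pos": [r.pos for r in kept],
                "snp_index": [compute_snp_index(r) for r in kept],
                "total_depth": [r.total_depth for r in kept],
            }
        )
        frame = frame.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        return cls(sites=frame, excluded=dropped)

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class ScanResult:
    """Per-site track plus the sliding-window mean track."""

    sites: pd.DataFrame
    windows: pd.DataFrame  # chrom, start, end (1-based incl.), mean_index, n_sites
    window_size: int
    step: int


def scan_genome(
    track: SNPIndexTrack,
    window_size: int = 1_000_000,
    step: int = 100_000,
    min_sites_per_window: int = 1,
    chrom_lengths: dict[str, int] | None = None,
) -> ScanResult:
    """Sliding-window mean of the SNP index along each chromosome.

    Windows are half-open ``[start, start + window_size)`` internally and
    reported with 1-based inclusive bounds.  Windows holding fewer than
    ``min_sites_per_window`` sites get a missing (NaN) mean.
    """
    if window_size <= 0:
        raise ValueError("window_size must be > 0")
    if step <= 0:
        raise ValueError("step must be > 0")
    rows = []
    for chrom, grp in track.sites.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        idx = grp["snp_index"].to_numpy()
        extent = chrom_lengths.get(chrom) if chrom_lengths else int(pos.max())
        start = 1
        while start <= extent:
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, start + window_size, side="left")
            n = hi - lo
            mean = float(idx[lo:hi].mean()) if n >= min_sites_per_window and n > 0 else np.nan
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": min(start + window_size - 1, extent),
                    "mean_index": mean,
                    "n_sites": int(n),
                }
            )
            start += step
    windows = pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_index", "n_sites"])
    return ScanResult(sites=track.sites, windows=windows, window_size=window_size, step=step)


@dataclass(frozen=True)
class PeakRegion:
    """A candidate causal region: a run of high-SNP-index windows."""

    chrom: str
    start: int
    end: int
    mean_index: float
    n_sites: int
    top_site: tuple[int, float]  # (pos, snp_index) of the best supporting site

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("start must be <= end")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def call_peak_regions(
    scan: ScanResult,
    index_threshold: float = 0.9,
    min_sites: int = 3,
    merge_gap: int | None = None,
) -> list[PeakRegion]:
    """Call maximal runs of windows with mean SNP index >= threshold.

    Qualifying windows on the same chromosome are merged when they overlap or
    are separated by at most ``merge_gap`` bp (default: one window size).
    Regions must be supported by at least ``min_sites`` sites.  Output is
    sorted by mean index descending, ties broken by genomic order.
    """
    if merge_gap is None:
        merge_gap = scan.window_size
    passing = scan.windows[scan.windows["mean_index"] >= index_threshold]
    regions: list[PeakRegion] = []
    for chrom, grp in passing.groupby("chrom", sort=True):
        grp = grp.sort_values("start")
        run_start = run_end = None
        spans: list[tuple[int, int]] = []
        for _, w in grp.iterrows():
            if run_start is None:
                run_start, run_end = int(w["start"]), int(w["end"])
            elif int(w["start"]) <= run_end + merge_gap + 1:
                run_end = max(run_end, int(w["end"]))
            else:
                spans.append((run_start, run_end))
                run_start, run_end = int(w["start"]), int(w["end"])
        if run_start is not None:
            spans.append((run_start, run_end))
        csites = scan.sites[scan.sites["chrom"] == chrom]
        for start, end in spans:
            sub = csites[(csites["pos"] >= start) & (csites["pos"] <= end)]
            if len(sub) < min_sites:
                continue
            best = sub.loc[sub["snp_index"].idxmax()]  # idxmax: first max, lowest pos
            regions.append(
                PeakRegion(
                    chrom=chrom,
                    start=start,
                    end=end,
                    mean_index=float(sub["snp_index"].mean()),
                    n_sites=int(len(sub)),
                    top_site=(int(best["pos"]), float(best["snp_index"])),
                )
            )
    regions.sort(key=lambda r: (-r.mean_index, r.chrom, r.start))
    return regions


def fit_index_decay(
    distance_bp: np.ndarray, snp_index: np.ndarray, initial_rate: float = 1.0
) -> float:
    """Recover the recombination rate (cM/Mb) from SNP-index decay.

    Under homozygous selection at a causal locus the expected index at map
    distance d Morgans is 1 - r(d) = 0.5 + 0.5 exp(-2 d) (Haldane), so a
    least-squares fit of index against physical distance estimates the
    cM/Mb rate of the simulated (or real) genetic map.
    """
    from scipy.optimize import curve_fit

    d = np.asarray(distance_bp, dtype=float)
    y = np.asarray(snp_index, dtype=float)

    def model(dist_bp, rate):
        return 0.5 + 0.5 * np.exp(-2.0 * rate * dist_bp / 1e6 / 100.0)

    popt, _ = curve_fit(model, d, y, p0=[initial_rate], bounds=(0.0, np.inf))
    return float(popt[0])


def map_pipeline(
    pool: Iterable[VariantRecord],
    wild_type: Iterable[VariantRecord] = (),
    other_pools: Sequence[Iterable[VariantRecord]] = (),
    filter_config: FilterConfig = FilterConfig(),
    presence_min_alt_reads: int = 2,
    window_size: int = 1_000_000,
    step: int = 100_000,
    index_threshold: float = 0.9,
    min_sites: int = 3,
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[list[PeakRegion], ScanResult]:
    """Full mapping stage: filter -> exclude shared -> index -> scan -> call."""
    filtered = quality_filter(pool, filter_config)
    private = exclude_shared(filtered, wild_type, other_pools, presence_min_alt_reads)
    track = SNPIndexTrack.from_records(private, filter_config.min_total_depth)
    scan = scan_genome(track, window_size, step, chrom_lengths=chrom_lengths)
    peaks = call_peak_regions(scan, index_threshold, min_sites)
    return peaks, scan
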