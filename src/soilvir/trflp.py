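"""T-RFLP replicate-consensus community profiling.

Each soil sample yields several replicate electropherograms, each a list of
(terminal restriction fragment size in nucleotides, peak height in
fluorescence units).  The pipeline turns these into a samples x TRF-bins
relative-abundance matrix:

1.  align replicate peaks by fragment size (greedy, running-mean anchored),
2.  drop peaks that do not occur in every replicate (reproducibility filter),
3.  reiteratively normalize replicate traces to the minimum total
    fluorescence, re-applying the minor-peak detection threshold (0.1 % of
    the trace total by default) until a fixed point,
4.  average surviving peak sizes and heights into a consensus trace,
5.  bin consensus peaks across samples within a size tolerance (0.5 nt),
6.  row-normalize to relative fluorescence and compute Shannon diversity.

Peak height (not area) is the abundance proxy throughout, and the 0.1 % rule
uses a strict inequality (a peak at exactly 0.1 % is kept).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import entropy

__all__ = [
    "PeakProfile",
    "ConsensusProfile",
    "BinTable",
    "align_replicates",
    "filter_reproducible",
    "normalize_reiterative",
    "remove_minor_peaks",
    "consensus",
    "bin_across_samples",
    "shannon_diversity",
    "trflp_pipeline",
]

DEFAULT_MINOR_FRACTION = 0.001  # "less than 0.1% of the total trace fluorescence"
DEFAULT_BIN_TOLERANCE = 0.5  # nt


@dataclass(frozen=True)
class PeakProfile:
    """One electropherogram: parallel arrays of peak sizes (nt) and heights."""

    sample_id: str
    sizes: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        sizes = np.asarray(self.sizes, dtype=float)
        heights = np.asarray(self.heights, dtype=float)
        if sizes.shape != heights.shape or sizes.ndim != 1:
            raise ValueError("sizes and heights must be 1-D arrays of equal length")
        if np.any(sizes < 0) or np.any(heights <= 0):
            raise ValueError("peak sizes must be >= 0 and heights > 0")
        order = np.argsort(sizes, kind="stable")
        object.__setattr__(self, "sizes", sizes[order])
        object.__setattr__(self, "heights", heights[order])

    @property
    def total_fluorescence(self) -> float:
        return float(self.heights.sum())

    def __len__(self) -> int:
        return self.sizes.size


@dataclass(frozen=True)
class ConsensusProfile:
    """Replicate-averaged trace: mean size, mean height, replicate support."""

    sample_id: str
    sizes: np.ndarray
    heights: np.ndarray
    support: int


@dataclass(frozen=True)
class BinTable:
    """Samples x TRF-bins relative-fluorescence matrix.

    ``bins`` holds representative sizes (mean member size per bin); rows of
    ``matrix`` sum to 1 for samples with any retained peak.
    """

    sample_ids: tuple[str, ...]
    bins: np.ndarray
    matrix: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=list(self.sample_ids), columns=[f"{b:.3f}" for b in self.bins]
        )


@dataclass
class PeakGroup:
    """Peaks matched across replicates; members are (replicate index, size, height)."""

    members: list[tuple[int, float, float]] = field(default_factory=list)

    @property
    def mean_size(self) -> float:
        return float(np.mean([m[1] for m in self.members]))

    @property
    def mean_height(self) -> float:
        return float(np.mean([m[2] for m in self.members]))

    def replicates(self) -> list[int]:
        return [m[0] for m in self.members]


def align_replicates(reps: list[PeakProfile], tol: float = DEFAULT_BIN_TOLERANCE) -> list[PeakGroup]:
    """Match peaks across replicate profiles by fragment size.

    Pools all peaks, sorts by size, and greedily grows groups left to right:
    a peak joins the current group iff it lies within `tol` of the group's
    running mean size.  Each peak belongs to at most one group.
    """
    if tol <= 0:
        raise ValueError(f"alignment tolerance must be positive, got {tol!r}")
    pooled = [
        (size, rep_idx, height)
        for rep_idx, rep in enumerate(reps)
        for size, height in zip(rep.sizes, rep.heights)
    ]
    pooled.sort()
    groups: list[PeakGroup] = []
    for size, rep_idx, height in pooled:
        if groups and abs(size - groups[-1].mean_size) <= tol:
            groups[-1].members.append((rep_idx, size, height))
        else:
            groups.append(PeakGroup(members=[(rep_idx, size, height)]))
    return groups


def filter_reproducible(groups: list[PeakGroup], n_reps: int) -> list[PeakGroup]:
    """Keep only groups with exactly one peak from every replicate."""
    return [g for g in groups if sorted(g.replicates()) == list(range(n_reps))]


def remove_minor_peaks(
    profile: PeakProfile, minor_frac: float = DEFAULT_MINOR_FRACTION
) -> PeakProfile:
    """Drop peaks strictly below `minor_frac` of the pre-removal trace total."""
    if not 0 < minor_frac < 1:
        raise ValueError(f"minor_frac must lie in (0, 1), got {minor_frac!r}")
    if len(profile) == 0:
        return profile
    keep = profile.heights >= minor_frac * profile.total_fluorescence
    return replace(profile, sizes=profile.sizes[keep], heights=profile.heights[keep])


def normalize_reiterative(
    reps: list[PeakProfile], minor_frac: float = DEFAULT_MINOR_FRACTION
) -> list[PeakProfile]:
    """Scale replicate traces to the minimum total fluorescence, reiteratively.

    Each pass scales every profile's heights by (minimum total / own total),
    deletes peaks strictly below ``minor_frac`` of the profile's new total,
    and repeats until a full pass deletes nothing.  Converged profiles all
    share the minimum total and contain no sub-threshold peak.
    """
    if not 0 < minor_frac < 1:
        raise ValueError(f"minor_frac must lie in (0, 1), got {minor_frac!r}")
    current = list(reps)
    if all(p.total_fluorescence <= 0 or len(p) == 0 for p in current):
        raise ValueError("all profiles are empty; nothing to normalize")
    while True:
        totals = [p.total_fluorescence for p in current if len(p) > 0]
        if not totals:
            raise ValueError("reiterative normalization deleted every peak")
        min_total = min(totals)
        deleted = False
        nxt = []
        for p in current:
            if len(p) == 0:
                nxt.append(p)
                continue
            scaled = p.heights * (min_total / p.total_fluorescence)
            keep = scaled >= minor_frac * scaled.sum()
            if not keep.all():
                deleted = True
            nxt.append(replace(p, sizes=p.sizes[keep], heights=scaled[keep]))
        current = nxt
        if not deleted:
            return current


def consensus(groups: list[PeakGroup], sample_id: str, n_reps: int) -> ConsensusProfile:
    """Unweighted mean of size and height per matched group."""
    sizes = np.array([g.mean_size for g in groups], dtype=float)
    heights = np.array([g.mean_height for g in groups], dtype=float)
    order = np.argsort(sizes, kind="stable")
    return ConsensusProfile(
        sample_id=sample_id, sizes=sizes[order], heights=heights[order], support=n_reps
    )


def bin_across_samples(
    profiles: list[ConsensusProfile], tol: float = DEFAULT_BIN_TOLERANCE
) -> BinTable:
    """Bin pooled consensus peaks across samples and row-normalize heights.

    Greedy left-to-right binning anchored on each bin's running mean: sort
    all peaks by size, open a new bin whenever the next peak is more than
    `tol` from the current bin's running mean.  Ties (exactly `tol` away)
    stay in the earlier bin.
    """
    if tol <= 0:
        raise ValueError(f"bin tolerance must be positive, got {tol!r}")
    pooled = [
        (size, sample_idx, height)
        for sample_idx, prof in enumerate(profiles)
        for size, height in zip(prof.sizes, prof.heights)
    ]
    pooled.sort()
    bin_sizes: list[list[float]] = []
    bin_members: list[list[tuple[int, float]]] = []
    for size, sample_idx, height in pooled:
        if bin_sizes and abs(size - float(np.mean(bin_sizes[-1]))) <= tol:
            bin_sizes[-1].append(size)
            bin_members[-1].append((sample_idx, height))
        else:
            bin_sizes.append([size])
            bin_members.append([(sample_idx, height)])
    reps = np.array([float(np.mean(sizes)) for sizes in bin_sizes])
    matrix = np.zeros((len(profiles), len(bin_sizes)))
    for j, members in enumerate(bin_members):
        for sample_idx, height in members:
            matrix[sample_idx, j] += height
    row_totals = matrix.sum(axis=1, keepdims=True)
    nonzero = row_totals[:, 0] > 0
    matrix[nonzero] /= row_totals[nonzero]
    return BinTable(
        sample_ids=tuple(p.sample_id for p in profiles), bins=reps, matrix=matrix
    )


def shannon_diversity(row: np.ndarray, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i ln p_i (natural log by default)."""
    p = np.asarray(row, dtype=float)
    if np.any(p < 0):
        raise ValueError("relative abundances must be non-negative")
    if p.sum() <= 0:
        raise ValueError("Shannon diversity undefined for an all-zero row")
    return float(entropy(p, base=base))


def trflp_pipeline(
    replicates_by_sample: dict[str, list[PeakProfile]],
    align_tol: float = DEFAULT_BIN_TOLERANCE,
    bin_tol: float = DEFAULT_BIN_TOLERANCE,
    minor_frac: float = DEFAULT_MINOR_FRACTION,
) -> tuple[BinTable, pd.DataFrame, pd.DataFrame]:
    """Full replicate-to-bin-table chain with QC accounting.

    Stage order: align -> reproducibility filter -> reiterative normalization
    -> minor-peak removal -> consensus -> cross-sample binning -> diversity.

    Returns ``(bin_table, diversity, qc)`` where `diversity` has per-sample
    Shannon H and peak counts, and `qc` counts peaks removed per rule.
    """
    consensus_profiles: list[ConsensusProfile] = []
    qc_rows = []
    for sample_id, reps in replicates_by_sample.items():
        n_reps = len(reps)
        n_input = sum(len(r) for r in reps)
        groups = align_replicates(reps, tol=align_tol)
        reproducible = filter_reproducible(groups, n_reps)
        n_irreproducible = n_input - sum(len(g.members) for g in reproducible)

        # rebuild per-replicate profiles restricted to reproducible peaks,
        # then jointly normalize; peaks lost to the threshold disqualify
        # their whole group from the consensus
        filtered = []
        for rep_idx, rep in enumerate(reps):
            member_peaks = [
                (size, height)
                for g in reproducible
                for r, size, height in g.members
                if r == rep_idx
            ]
            sizes = np.array([m[0] for m in member_peaks])
            heights = np.array([m[1] for m in member_peaks])
            filtered.append(replace(rep, sizes=sizes, heights=heights))
        if all(len(p) == 0 for p in filtered):
            # nothing reproducible (e.g. heavy dropout): empty consensus
            consensus_profiles.append(consensus([], sample_id, n_reps))
            qc_rows.append(
                {
                    "sample_id": sample_id,
                    "peaks_input": n_input,
                    "peaks_irreproducible": n_input,
                    "groups_minor_removed": 0,
                    "peaks_consensus": 0,
                }
            )
            continue
        normalized = normalize_reiterative(filtered, minor_frac=minor_frac)
        normalized = [remove_minor_peaks(p, minor_frac) for p in normalized]
        surviving_sizes = [set(np.round(p.sizes, 9)) for p in normalized]
        surviving = []
        for g in reproducible:
            if all(
                round(size, 9) in surviving_sizes[r] for r, size, height in g.members
            ):
                # carry normalized heights into the group
                members = []
                for r, size, _ in g.members:
                    prof = normalized[r]
                    idx = int(np.argmin(np.abs(prof.sizes - size)))
                    members.append((r, size, float(prof.heights[idx])))
                surviving.append(PeakGroup(members=members))
        n_minor = len(reproducible) - len(surviving)
        consensus_profiles.append(consensus(surviving, sample_id, n_reps))
        qc_rows.append(
            {
                "sample_id": sample_id,
                "peaks_input": n_input,
                "peaks_irreproducible": n_irreproducible,
                "groups_minor_removed": n_minor,
                "peaks_consensus": len(surviving),
            }
        )

    bin_table = bin_across_samples(consensus_profiles, tol=bin_tol)
    diversity = pd.DataFrame(
        {
            "sample_id": list(bin_table.sample_ids),
            "shannon_h": [
                shannon_diversity(row) if row.sum() > 0 else np.nan
                for row in bin_table.matrix
            ],
            "n_peaks": [int((row > 0).sum()) for row in bin_table.matrix],
        }
    )
    qc = pd.DataFrame(qc_rows)
    qc.attrs["unique_trfs"] = int(bin_table.bins.size)
    return bin_table, diversity, qc
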