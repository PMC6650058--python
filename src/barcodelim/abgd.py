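"""Automatic Barcode Gap Discovery (ABGD) style partitioning.

The barcode gap is the empty interval separating intraspecific from
interspecific pairwise distances. Given a prior maximum intraspecific
divergence P and a relative gap width X, the detector scans the sorted
pairwise distances for the first consecutive gap that (a) ends beyond P and
(b) is more than X times wider than the typical gap among all smaller
distances. Sequences are then partitioned by single linkage below the gap
midpoint. The recursive partition re-applies the detector inside each group
with the same prior until no group splits.

The gap-significance statistic is a deterministic dialect: the local scale
w_i is the mean consecutive-gap width among all distances up to the gap's
left endpoint (global left window), and a gap is significant iff
D[i+1] - D[i] > X * w_i. Exact parity with the original web service is not
promised; limiting behaviour (one group at large P, singletons at tiny
thresholds, group counts non-increasing in P) is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix


@dataclass
class AbgdConfig:
    """Sweep settings: priors P, relative gap widths X (K80 distances assumed)."""

    priors: tuple[float, ...] = tuple(np.geomspace(0.001, 0.1, 20).round(10))
    gap_widths: tuple[float, ...] = (1.0, 1.5, 2.0)
    max_depth: int = 10

    def __post_init__(self) -> None:
        for p in self.priors:
            if not 0.0 < p < 1.0:
                raise ValueError(f"prior {p} outside (0, 1)")
        for x in self.gap_widths:
            if x <= 0.0:
                raise ValueError(f"gap width {x} must be > 0")


@dataclass
class Partition:
    """Disjoint grouping of sequence ids; group ids contiguous from 1."""

    group_of: dict[str, int]

    def __post_init__(self) -> None:
        groups = sorted(set(self.group_of.values()))
        if groups != list(range(1, len(groups) + 1)):
            relabel = {g: k + 1 for k, g in enumerate(groups)}
            self.group_of = {s: relabel[g] for s, g in self.group_of.items()}

    @property
    def n_groups(self) -> int:
        return len(set(self.group_of.values()))

    def members(self, group: int) -> list[str]:
        return [s for s, g in self.group_of.items() if g == group]

    def groups(self) -> list[list[str]]:
        return [self.members(g) for g in range(1, self.n_groups + 1)]

    def refines(self, coarser: "Partition") -> bool:
        """True if every group here is contained in a single group of ``coarser``."""
        for grp in self.groups():
            if len({coarser.group_of[s] for s in grp}) != 1:
                return False
        return True


@dataclass
class AbgdResult:
    """One (P, X) evaluation: initial and recursive partitions."""

    prior: float
    gap_width: float
    initial: Partition
    recursive: Partition
    threshold: float | None
    converged: bool = True

    @property
    def ip_rp_difference(self) -> int:
        return abs(self.initial.n_groups - self.recursive.n_groups)


def detect_gap(
    sorted_distances: Sequence[float], prior: float, gap_width: float
) -> float | None:
    """First significant barcode gap beyond the prior; returns its midpoint.

    ``sorted_distances`` must be ascending. The gap between D[i] and D[i+1]
    is significant iff its width exceeds ``gap_width`` times the mean
    consecutive-gap width among distances up to D[i], and admissible iff its
    right endpoint exceeds ``prior``. Returns None when no admissible
    significant gap exists (including < 2 distances).
    """
    d = np.asarray(sorted_distances, dtype=float)
    if d.size < 2:
        return None
    gaps = np.diff(d)
    # leading gap: when even the smallest distance exceeds the prior, the
    # interval (P, D[0]) separates intraspecific (empty) from interspecific
    # variation; significant when wider than X times the typical spacing
    if d[0] > prior and (d[0] - prior) > gap_width * float(gaps.mean()):
        return float((prior + d[0]) / 2.0)
    cummean = np.cumsum(gaps) / np.arange(1, gaps.size + 1)
    for i in range(gaps.size):
        if d[i + 1] <= prior:
            continue
        if gaps[i] > gap_width * cummean[i] and gaps[i] > 0.0:
            return float((d[i] + d[i + 1]) / 2.0)
    return None


def partition_at_threshold(dm: DistanceMatrix, threshold: float) -> Partition:
    """Single-linkage components of the graph with edges where d < threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    adj = (dm.d < threshold) & dm.defined
    np.fill_diagonal(adj, True)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    # contiguous group ids ordered by first appearance
    order: dict[int, int] = {}
    group_of = {}
    for sid, lab in zip(dm.ids, labels):
        if lab not in order:
            order[lab] = len(order) + 1
        group_of[sid] = order[lab]
    return Partition(group_of)


def abgd_partition(
    dm: DistanceMatrix,
    prior: float,
    gap_width: float,
    max_depth: int = 10,
) -> AbgdResult:
    """Initial (global gap) and recursive (per-group fixed point) partitions."""
    if not dm.defined.all():
        raise ValueError(
            "ABGD input contains undefined (saturated) distances; "
            f"pre-filter these pairs: {dm.undefined_pairs()[:10]}"
        )
    theta = detect_gap(dm.condensed(), prior, gap_width)
    if theta is None:
        initial = Partition({s: 1 for s in dm.ids})
    else:
        initial = partition_at_threshold(dm, theta)

    current = initial
    converged = True
    for _ in range(max_depth):
        new_groups: list[list[str]] = []
        split_any = False
        for grp in current.groups():
            if len(grp) < 3:
                new_groups.append(grp)
                continue
            sub = dm.submatrix(grp)
            t = detect_gap(sub.condensed(), prior, gap_width)
            if t is None:
                new_groups.append(grp)
                continue
            sub_part = partition_at_threshold(sub, t)
            if sub_part.n_groups == 1:
                new_groups.append(grp)
            else:
                split_any = True
                new_groups.extend(sub_part.groups())
        if not split_any:
            break
        current = Partition(
            {s: g + 1 for g, grp in enumerate(new_groups) for s in grp}
        )
    else:
        converged = False

    return AbgdResult(
        prior=prior,
        gap_width=gap_width,
        initial=initial,
        recursive=current,
        threshold=theta,
        converged=converged,
    )


def abgd_sweep(dm: DistanceMatrix, config: AbgdConfig | None = None) -> list[AbgdResult]:
    cfg = config or AbgdConfig()
    return [
        abgd_partition(dm, p, x, cfg.max_depth)
        for x in cfg.gap_widths
        for p in cfg.priors
    ]


def select_partition(results: Sequence[AbgdResult]) -> AbgdResult:
    """Pick the prior minimizing |n_groups(IP) - n_groups(RP)|.

    Ties are broken toward the larger prior (then the larger gap width).
    """
    if not results:
        raise ValueError("no ABGD results to select from")
    return min(
        results,
        key=lambda r: (r.ip_rp_difference, -r.prior, -r.gap_width),
    )


def sweep_table(results: Sequence[AbgdResult]):
    """Sweep summary as a DataFrame: P, X, n_IP, n_RP (S2-style layout)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "P": [r.prior for r in results],
            "X": [r.gap_width for r in results],
            "n_IP": [r.initial.n_groups for r in results],
            "n_RP": [r.recursive.n_groups for r in results],
            "threshold": [r.threshold for r in results],
        }
    )
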