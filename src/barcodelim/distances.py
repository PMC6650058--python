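"""Kimura 2-parameter distances and divergence summaries.

The K2P (K80) distance separates transitions (A<->G, C<->T; proportion P)
from transversions (proportion Q) among the compared sites and corrects for
multiple hits:

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Only sites where both sequences carry an unambiguous base {A,C,G,T} are
compared. A pair is *undefined* (saturated) when a log argument is
non-positive or no sites are comparable; undefined pairs are flagged, never
NaN, and are excluded from all means.

Deletion modes mirror the common desktop conventions: *complete* deletion
removes every column containing any gap/ambiguity in any sequence before any
pairwise computation; *pairwise* deletion masks sites per pair.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .seqio import Alignment, _CODE


@dataclass(frozen=True)
class K2PEstimate:
    """One pairwise K2P estimate: proportions, site count, distance, flag."""

    p_transitions: float
    q_transversions: float
    n_sites_compared: int
    d: float
    defined: bool


@dataclass
class DistanceMatrix:
    """Symmetric pairwise K2P distances with undefined-entry flags."""

    ids: list[str]
    d: np.ndarray          # (n, n) float, 0 on diagonal; entries valid where defined
    defined: np.ndarray    # (n, n) bool
    deletion_mode: str = "complete"
    n_columns_used: int | None = None

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self, sid: str) -> int:
        return self.ids.index(sid)

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.index(a), self.index(b)])

    def submatrix(self, keep_ids: Sequence[str]) -> "DistanceMatrix":
        idx = np.array([self.ids.index(s) for s in keep_ids])
        return DistanceMatrix(
            ids=list(keep_ids),
            d=self.d[np.ix_(idx, idx)].copy(),
            defined=self.defined[np.ix_(idx, idx)].copy(),
            deletion_mode=self.deletion_mode,
            n_columns_used=self.n_columns_used,
        )

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if not self.defined[i, j]:
                    out.append((self.ids[i], self.ids[j]))
        return out

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances (defined entries only), ascending order."""
        iu = np.triu_indices(self.n, k=1)
        vals = self.d[iu][self.defined[iu]]
        return np.sort(vals)

    def to_phylip(self) -> str:
        buf = io.StringIO()
        buf.write(f"{self.n}\n")
        for i, sid in enumerate(self.ids):
            row = " ".join(f"{self.d[i, j]:.8f}" for j in range(self.n))
            buf.write(f"{sid}  {row}\n")
        return buf.getvalue()

    def to_tsv(self) -> str:
        buf = io.StringIO()
        buf.write("id\t" + "\t".join(self.ids) + "\n")
        for i, sid in enumerate(self.ids):
            cells = [
                f"{self.d[i, j]:.8f}" if self.defined[i, j] else "NA"
                for j in range(self.n)
            ]
            buf.write(sid + "\t" + "\t".join(cells) + "\n")
        return buf.getvalue()


_TS_PAIRS = ((0, 2), (1, 3))  # A<->G, C<->T in the uint8 encoding


def k2p(
    seq_a: str | np.ndarray,
    seq_b: str | np.ndarray,
    deletion_columns: Sequence[int] | None = None,
) -> K2PEstimate:
    """K2P estimate for one pair of equal-length aligned sequences.

    ``deletion_columns``, if given, restricts the comparison to that 0-based
    site set (the caller's deletion policy); otherwise all sites where both
    bases are unambiguous are used.
    """
    a = _encode(seq_a)
    b = _encode(seq_b)
    if a.shape != b.shape:
        raise ValueError("sequences differ in length")
    if deletion_columns is not None:
        cols = np.asarray(deletion_columns, dtype=int)
        a = a[cols]
        b = b[cols]
    both = (a < 4) & (b < 4)
    n = int(both.sum())
    if n == 0:
        return K2PEstimate(0.0, 0.0, 0, 0.0, False)
    aa, bb = a[both], b[both]
    diff = aa != bb
    ts = np.zeros_like(diff)
    for x, y in _TS_PAIRS:
        ts |= ((aa == x) & (bb == y)) | ((aa == y) & (bb == x))
    n_ts = int(ts.sum())
    n_tv = int(diff.sum()) - n_ts
    p = n_ts / n
    q = n_tv / n
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return K2PEstimate(p, q, n, 0.0, False)
    d = -0.5 * np.log(w1 * np.sqrt(w2))
    return K2PEstimate(p, q, n, float(d), True)


def _encode(seq: str | np.ndarray) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq.astype(np.uint8, copy=False)
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def complete_deletion_columns(alignment: Alignment) -> np.ndarray:
    """0-based indices of columns with an unambiguous base in every sequence."""
    codes = alignment.to_codes()
    return np.flatnonzero((codes < 4).all(axis=0))


def distance_matrix(
    alignment: Alignment,
    deletion_mode: str = "complete",
    columns: Sequence[int] | None = None,
) -> DistanceMatrix:
    """All pairwise K2P distances for an alignment.

    Under complete deletion every column containing any gap or ambiguity in
    any sequence is removed before all pairwise computations; under pairwise
    deletion sites are masked per pair. ``columns`` optionally restricts the
    computation to a site subset first (used by the column bootstrap and by
    user-supplied column masks).
    """
    if alignment.n < 2:
        raise ValueError("need >= 2 sequences for a distance matrix")
    if deletion_mode not in ("complete", "pairwise"):
        raise ValueError(f"unknown deletion mode {deletion_mode!r}")
    codes = alignment.to_codes()
    if columns is not None:
        codes = codes[:, np.asarray(columns, dtype=int)]
    if deletion_mode == "complete":
        keep = (codes < 4).all(axis=0)
        if not keep.any():
            raise ValueError(
                "complete deletion removed every column; "
                "re-run with deletion_mode='pairwise'"
            )
        codes = codes[:, keep]
    n_cols = codes.shape[1]
    d, defined = _k2p_matrix_from_codes(codes)
    return DistanceMatrix(
        ids=list(alignment.ids),
        d=d,
        defined=defined,
        deletion_mode=deletion_mode,
        n_columns_used=n_cols,
    )


def _k2p_matrix_from_codes(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized K2P over a uint8 code matrix (counts via exact matmuls)."""
    onehot = [(codes == b).astype(np.float64) for b in range(4)]
    valid = (codes < 4).astype(np.float64)
    n_comp = valid @ valid.T
    same = sum(h @ h.T for h in onehot)
    ag = onehot[0] @ onehot[2].T
    ct = onehot[1] @ onehot[3].T
    ts = ag + ag.T + ct + ct.T
    diff = n_comp - same
    tv = diff - ts
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_comp > 0, ts / np.maximum(n_comp, 1), 0.0)
        q = np.where(n_comp > 0, tv / np.maximum(n_comp, 1), 0.0)
        w1 = 1.0 - 2.0 * p - q
        w2 = 1.0 - 2.0 * q
        ok = (n_comp > 0) & (w1 > 0) & (w2 > 0)
        d = np.where(ok, -0.5 * np.log(np.where(ok, w1 * np.sqrt(np.abs(w2)), 1.0)), 0.0)
    np.fill_diagonal(d, 0.0)
    np.fill_diagonal(ok, True)
    d = (d + d.T) / 2.0  # exact symmetry against float noise
    return d, ok


@dataclass
class DivergenceSummary:
    """Within-/between-group mean K2P divergences plus an overall mean.

    Means are averages over *defined* pairs only; a single-member group has
    an undefined (None) within mean. The standard error of the overall mean
    is a site-bootstrap estimate (columns resampled with replacement).
    """

    groups: list[str]
    mean_within: dict[str, float | None]
    mean_between: dict[tuple[str, str], float | None]
    overall_mean: float
    standard_error: float | None
    n_undefined_pairs: int = 0
    group_sizes: dict[str, int] = field(default_factory=dict)

    def max_between(self) -> tuple[tuple[str, str], float] | None:
        items = [(k, v) for k, v in self.mean_between.items() if v is not None]
        if not items:
            return None
        return max(items, key=lambda kv: kv[1])


def divergence_summary(
    dm: DistanceMatrix,
    grouping: Mapping[str, str],
    n_boot: int = 1000,
    seed: int = 0,
    alignment: Alignment | None = None,
) -> DivergenceSummary:
    """Group-wise divergence summary from a distance matrix.

    ``grouping`` maps sequence id -> group label; ids not in the map are
    excluded from group means but included in the overall mean. The bootstrap
    SE requires the source ``alignment`` (columns are resampled and the whole
    matrix recomputed); without it the SE is None.
    """
    ids = dm.ids
    labels = sorted({grouping[i] for i in ids if i in grouping})
    members = {g: [i for i in ids if grouping.get(i) == g] for g in labels}

    mean_within = {
        g: _mean_pairs(dm, members[g], members[g], within=True) for g in labels
    }
    mean_between = {}
    for a_idx in range(len(labels)):
        for b_idx in range(a_idx + 1, len(labels)):
            ga, gb = labels[a_idx], labels[b_idx]
            mean_between[(ga, gb)] = _mean_pairs(dm, members[ga], members[gb])

    overall = _mean_pairs(dm, ids, ids, within=True)
    se = None
    if alignment is not None and n_boot > 0:
        rng = np.random.default_rng(seed)
        codes = alignment.to_codes()
        if dm.deletion_mode == "complete":
            codes = codes[:, (codes < 4).all(axis=0)]
        n_cols = codes.shape[1]
        boots = np.empty(n_boot)
        for r in range(n_boot):
            cols = rng.integers(0, n_cols, size=n_cols)
            d_b, ok_b = _k2p_matrix_from_codes(codes[:, cols])
            iu = np.triu_indices(len(ids), k=1)
            vals = d_b[iu][ok_b[iu]]
            boots[r] = vals.mean() if vals.size else np.nan
        se = float(np.nanstd(boots, ddof=1))

    iu = np.triu_indices(dm.n, k=1)
    n_undef = int((~dm.defined[iu]).sum())
    return DivergenceSummary(
        groups=labels,
        mean_within=mean_within,
        mean_between=mean_between,
        overall_mean=overall if overall is not None else float("nan"),
        standard_error=se,
        n_undefined_pairs=n_undef,
        group_sizes={g: len(members[g]) for g in labels},
    )


def _mean_pairs(
    dm: DistanceMatrix,
    ids_a: Sequence[str],
    ids_b: Sequence[str],
    within: bool = False,
) -> float | None:
    idx = {s: k for k, s in enumerate(dm.ids)}
    vals = []
    if within:
        for i in range(len(ids_a)):
            for j in range(i + 1, len(ids_a)):
                a, b = idx[ids_a[i]], idx[ids_a[j]]
                if dm.defined[a, b]:
                    vals.append(dm.d[a, b])
    else:
        for sa in ids_a:
            for sb in ids_b:
                a, b = idx[sa], idx[sb]
                if dm.defined[a, b]:
                    vals.append(dm.d[a, b])
    if not vals:
        return None
    return float(np.mean(vals))
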