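"""Statistics on binary AFLP marker matrices.

Peak lists are binned into markers, each marker is tested for association
with a two-level trait (patient vs donor, treatment-sensitive vs
resistant) by Fisher's exact test on the present/absent x group 2x2
table, and samples are clustered from pairwise dissimilarities of their
0/1 profiles (Dice by default, the usual choice for dominant AFLP
markers).

The two-tailed Fisher p-value uses the point-probability ("small p")
convention: the sum of the probabilities of all tables, with the margins
fixed, whose point probability does not exceed the observed table's.
This matches the common online calculators; the alternative "doubling"
convention differs and is not used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .amplify import FingerprintMatrix, bin_sizes

__all__ = [
    "AssociationResult",
    "DistanceMatrix",
    "score_binary",
    "fisher_exact",
    "associate",
    "presence_frequency",
    "dissimilarity",
    "matrix_from_counts",
]

TableLike = Sequence[Sequence[int]]


@dataclass(frozen=True)
class AssociationResult:
    """Fisher's exact test of one marker against a two-group labeling.

    ``table`` is ((present_g1, present_g2), (absent_g1, absent_g2));
    ``odds_ratio`` is the unconditional cross-product ratio (may be
    ``inf`` when a discordant cell is empty, ``nan`` for 0/0)."""

    marker_id: str
    table: tuple[tuple[int, int], tuple[int, int]]
    p_one: float
    p_two: float
    odds_ratio: float
    adjusted_p: float | None = None
    significant: bool = False


@dataclass(frozen=True)
class DistanceMatrix:
    """A symmetric, nonnegative sample dissimilarity matrix."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape must match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if (v < 0).any():
            raise ValueError("distances must be nonnegative")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        object.__setattr__(self, "values", v)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def _validate_table(table: TableLike) -> np.ndarray:
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.all(np.mod(t, 1) == 0):
            raise ValueError("table counts must be integers")
        t = t.astype(int)
    if (t < 0).any():
        raise ValueError("table counts must be nonnegative")
    if t.sum() == 0:
        raise ValueError("table total must be positive")
    return t


def fisher_exact(table: TableLike) -> tuple[float, float]:
    """One- and two-tailed Fisher exact probabilities of a 2x2 table.

    ``p_one`` is the hypergeometric tail containing the observed table in
    the direction of its deviation from independence; ``p_two`` is the
    small-p two-tailed probability.  Both lie in (0, 1] and
    ``p_one <= p_two``.
    """
    t = _validate_table(table)
    p_two = float(scipy.stats.fisher_exact(t, alternative="two-sided")[1])
    p_greater = float(scipy.stats.fisher_exact(t, alternative="greater")[1])
    p_less = float(scipy.stats.fisher_exact(t, alternative="less")[1])
    p_one = min(p_greater, p_less)
    return p_one, min(p_two, 1.0)


def _odds_ratio(t: np.ndarray) -> float:
    num = t[0, 0] * t[1, 1]
    den = t[0, 1] * t[1, 0]
    if den == 0:
        return float("nan") if num == 0 else float("inf")
    return num / den


def associate(
    matrix: FingerprintMatrix,
    groups: Mapping[str, str] | pd.Series | None = None,
    alpha: float = 0.05,
    correction: str | None = None,
) -> list[AssociationResult]:
    """Fisher's exact test of every marker against a two-group labeling.

    Builds one present/absent x group 2x2 table per marker (group columns
    in sorted label order), flags markers with raw ``p_two < alpha`` as
    significant, and optionally reports Bonferroni- or Benjamini-Hochberg-
    adjusted p-values (``correction`` in {"bonferroni", "bh"}).  Results
    are sorted by ``p_two`` then marker id.
    """
    if groups is None:
        groups = matrix.groups
    if groups is None:
        raise ValueError("group labels are required")
    labels = {s: groups[s] for s in matrix.sample_ids}
    levels = sorted(set(labels.values()))
    if len(levels) != 2:
        raise ValueError(
            f"exactly two groups required, got {len(levels)}: run pairwise "
            "comparisons for multi-level traits"
        )
    g1 = [s for s in matrix.sample_ids if labels[s] == levels[0]]
    g2 = [s for s in matrix.sample_ids if labels[s] == levels[1]]
    if not g1 or not g2:
        raise ValueError("both groups must be nonempty")

    n_markers = len(matrix.marker_ids)
    if correction is None and n_markers > 100:
        warnings.warn(
            f"testing {n_markers} markers without multiple-testing "
            "correction; significance flags use raw p-values",
            stacklevel=2,
        )

    results = []
    for marker in matrix.marker_ids:
        col = matrix.calls[marker]
        n11 = int(col[g1].sum())
        n12 = int(col[g2].sum())
        t = np.array([[n11, n12], [len(g1) - n11, len(g2) - n12]])
        p_one, p_two = fisher_exact(t)
        results.append(
            AssociationResult(
                marker_id=marker,
                table=(
                    (int(t[0, 0]), int(t[0, 1])),
                    (int(t[1, 0]), int(t[1, 1])),
                ),
                p_one=p_one,
                p_two=p_two,
                odds_ratio=_odds_ratio(t),
                significant=p_two < alpha,
            )
        )

    if correction is not None:
        from statsmodels.stats.multitest import multipletests

        method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(correction)
        if method is None:
            raise ValueError("correction must be 'bonferroni' or 'bh'")
        adj = multipletests([r.p_two for r in results], method=method)[1]
        results = [
            AssociationResult(
                r.marker_id, r.table, r.p_one, r.p_two, r.odds_ratio,
                adjusted_p=float(a), significant=r.significant,
            )
            for r, a in zip(results, adj)
        ]

    return sorted(results, key=lambda r: (r.p_two, r.marker_id))


def presence_frequency(
    matrix: FingerprintMatrix,
    group: str,
    marker: str,
    groups: Mapping[str, str] | None = None,
) -> float:
    """Fraction of the group's samples in which *marker* is called present."""
    if groups is None:
        groups = matrix.groups
    if groups is None:
        raise ValueError("group labels are required")
    if marker not in matrix.calls.columns:
        raise ValueError(f"unknown marker {marker!r}")
    members = [s for s in matrix.sample_ids if groups.get(s) == group]
    if not members:
        raise ValueError(f"unknown or empty group {group!r}")
    return float(matrix.calls.loc[members, marker].mean())


def matrix_from_counts(
    marker_counts: Mapping[str, Mapping[str, tuple[int, int]]],
) -> FingerprintMatrix:
    """Build a fingerprint matrix from printed per-group present/absent
    counts, e.g. ``{"CAG_AGG_56": {"sensitive": (14, 21), ...}}``.

    Sample ids are synthesized per group.  Useful for re-deriving
    published frequencies and exact tests from tabulated counts.
    """
    group_sizes: dict[str, int] = {}
    for per_group in marker_counts.values():
        for g, (present, absent) in per_group.items():
            group_sizes[g] = max(group_sizes.get(g, 0), present + absent)
    sample_ids = []
    groups = {}
    for g in group_sizes:
        for i in range(group_sizes[g]):
            sid = f"{g}_{i:03d}"
            sample_ids.append(sid)
            groups[sid] = g
    calls = pd.DataFrame(0, index=sample_ids, columns=list(marker_counts), dtype=int)
    for marker, per_group in marker_counts.items():
        for g, (present, absent) in per_group.items():
            members = [s for s in sample_ids if groups[s] == g]
            if present + absent > len(members):
                raise ValueError("counts exceed group size")
            calls.loc[members[:present], marker] = 1
    return FingerprintMatrix(calls=calls, groups=groups)


PeakLists = Mapping[str, Iterable[tuple[str, float]]]


def score_binary(peaks: PeakLists | pd.DataFrame, tol: float = 1.0) -> FingerprintMatrix:
    """Transform per-sample peak/size lists into a binary marker matrix.

    ``peaks`` maps sample id to (combo label, size) records, or is a
    DataFrame with columns ``sample_id``, ``combo``, ``size``.  Sizes of
    each combo are clustered across samples into single-linkage bins
    (consecutive gap <= *tol*, bin width <= 2 * tol); each (combo, bin)
    becomes a marker, called 1 for every sample with a peak in the bin.
    """
    if isinstance(peaks, pd.DataFrame):
        records = [
            (str(r.sample_id), str(r.combo), float(r.size))
            for r in peaks.itertuples(index=False)
        ]
        sample_ids = list(dict.fromkeys(r[0] for r in records))
    else:
        records = [
            (sample, str(combo), float(size))
            for sample, lst in peaks.items()
            for combo, size in lst
        ]
        sample_ids = list(peaks)
    for _, _, size in records:
        if size < 0:
            raise ValueError("peak sizes must be nonnegative")

    by_combo: dict[str, list[tuple[str, float]]] = {}
    for sample, combo, size in records:
        by_combo.setdefault(combo, []).append((sample, size))

    cols: dict[str, pd.Series] = {}
    for combo in sorted(by_combo):
        entries = by_combo[combo]
        for bin_ in bin_sizes([s for (_, s) in entries], tol):
            lo, hi = bin_[0], bin_[-1]
            center = int(round((lo + hi) / 2))
            marker = f"{combo}_{center}"
            col = pd.Series(0, index=sample_ids, dtype=int)
            for sample, size in entries:
                if lo <= size <= hi:
                    col[sample] = 1
            cols[marker] = col
    calls = pd.DataFrame(cols, index=sample_ids, dtype=int)
    return FingerprintMatrix(calls=calls)


_METRICS = ("dice", "jaccard", "simple_matching")


def dissimilarity(matrix: FingerprintMatrix, metric: str = "dice") -> DistanceMatrix:
    """Pairwise dissimilarity of 0/1 fingerprint profiles.

    dice: ``1 - 2a / (2a + b + c)``; jaccard: ``1 - a / (a + b + c)``;
    simple_matching: fraction of discordant markers — with ``a`` shared
    presences and ``b``, ``c`` the one-sided presences of each pair.
    A pair of identical all-absent profiles has no presences on either
    side; consistent with "identical profiles have distance 0", the 0/0
    ratio is taken as 0.  Profiles with missing (NaN) calls are an error.
    """
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    X = matrix.calls.to_numpy(dtype=float)
    n, m = X.shape
    if n < 2:
        raise ValueError("at least two samples are required")
    if np.isnan(X).any():
        bad = [s for s, row in zip(matrix.sample_ids, np.isnan(X).any(axis=1)) if row]
        raise ValueError(f"samples with missing calls: {bad}")
    a = X @ X.T
    s = X.sum(axis=1)
    b = s[:, None] - a
    c = s[None, :] - a
    with np.errstate(invalid="ignore"):
        if metric == "dice":
            d = 1.0 - 2.0 * a / (2.0 * a + b + c)
        elif metric == "jaccard":
            d = 1.0 - a / (a + b + c)
        else:
            d = (b + c) / m
    d = np.nan_to_num(d, nan=0.0)  # 0/0: two all-absent, hence identical, profiles
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=tuple(matrix.sample_ids), values=d)
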