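"""Group separation in topospace: PERMANOVA, pairwise PERMANOVA, size classes.

PERMANOVA (Anderson's permutational MANOVA) tests whether labelled groups
occupy distinct regions of topospace. From the Euclidean distance matrix of
the score rows,

    SS_total  = sum_{i<j} d_ij^2 / n
    SS_within = sum_g sum_{i<j in g} d_ij^2 / n_g
    F = (SS_between / (a - 1)) / (SS_within / (n - a))

and the p-value is the fraction of free label permutations with F at least as
large, with the conventional (count + 1)/(n_perm + 1) correction. Size classes
are assigned from snout-occiput skull length against a break in the empirical
length distribution (the squamate study used <= 11.74 mm for 'miniaturized'
and >= 14.05 mm for 'non-miniaturized').
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "PermanovaResult",
    "SizeClassification",
    "permanova",
    "pairwise_permanova",
    "classify_size",
    "find_distribution_break",
    "MINIATURIZED_MAX_MM",
    "NON_MINIATURIZED_MIN_MM",
]

# Snout-occiput skull length thresholds (mm) from the break in the observed
# squamate length distribution.
MINIATURIZED_MAX_MM = 11.74
NON_MINIATURIZED_MIN_MM = 14.05


@dataclasses.dataclass(frozen=True)
class PermanovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    n_permutations: int
    groups: tuple[str, ...]
    seed: int | None = None

    def as_dict(self) -> dict:
        return {
            "F": self.f_statistic,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "p": self.p_value,
            "n_permutations": self.n_permutations,
            "groups": list(self.groups),
            "seed": self.seed,
        }


@dataclasses.dataclass(frozen=True)
class SizeClassification:
    taxon: str
    skull_length: float
    size_class: str  # miniaturized | non-miniaturized | ambiguous


def _as_matrix_and_labels(scores, labels):
    if isinstance(scores, pd.DataFrame):
        x = scores.to_numpy(dtype=float)
        if isinstance(labels, (pd.Series, dict)):
            labels = pd.Series(labels).reindex(scores.index)
            if labels.isna().any():
                raise ValueError("labels missing for some rows")
            labels = labels.to_numpy()
    else:
        x = np.asarray(scores, dtype=float)
        labels = np.asarray(labels)
    if len(labels) != x.shape[0]:
        raise ValueError("labels length does not match score rows")
    return x, np.asarray(labels)


def _f_from_within(ss_total, ss_within, a, n):
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(scores, labels, n_permutations: int = 10_000, seed: int | None = None) -> PermanovaResult:
    """One-way PERMANOVA on Euclidean distances of score rows.

    Labels are permuted freely (unrestricted shuffles) with a seeded
    generator; the observed F is permutation-invariant, only p varies within
    Monte-Carlo error.
    """
    x, lab = _as_matrix_and_labels(scores, labels)
    n = x.shape[0]
    groups = sorted(map(str, set(lab.tolist())))
    a = len(groups)
    if a < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    sizes = {g: int((lab.astype(str) == g).sum()) for g in groups}
    small = [g for g, s in sizes.items() if s < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 members: {small}")
    d2 = squareform(pdist(x, metric="euclidean") ** 2)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    if ss_total <= 0:
        raise ValueError("degenerate data: all points identical")
    lab_codes = np.searchsorted(np.array(groups), lab.astype(str))

    def ss_within_for(codes_matrix: np.ndarray) -> np.ndarray:
        # codes_matrix: (m, n) label codes; returns (m,) within sums of squares
        ssw = np.zeros(codes_matrix.shape[0])
        for gi, g in enumerate(groups):
            mask = (codes_matrix == gi).astype(float)
            ssw += np.einsum("pi,ij,pj->p", mask, d2, mask) / (2.0 * sizes[g])
        return ssw

    obs_ssw = float(ss_within_for(lab_codes[None, :])[0])
    f_obs = _f_from_within(ss_total, obs_ssw, a, n)
    rng = np.random.default_rng(seed)
    perms = np.empty((n_permutations, n), dtype=lab_codes.dtype)
    for i in range(n_permutations):
        perms[i] = lab_codes[rng.permutation(n)]
    f_perm = _f_from_within(ss_total, ss_within_for(perms), a, n)
    count = int(np.sum(f_perm >= f_obs - 1e-12))
    p = (count + 1) / (n_permutations + 1)
    return PermanovaResult(
        f_statistic=float(f_obs),
        df_between=a - 1,
        df_within=n - a,
        p_value=float(p),
        n_permutations=n_permutations,
        groups=tuple(groups),
        seed=seed,
    )


def pairwise_permanova(scores, labels, n_permutations: int = 10_000, seed: int | None = None) -> list[PermanovaResult]:
    """One PERMANOVA per unordered category pair, on that pair's rows only."""
    x, lab = _as_matrix_and_labels(scores, labels)
    lab = lab.astype(str)
    groups = sorted(set(lab.tolist()))
    if len(groups) < 3:
        raise ValueError("pairwise PERMANOVA expects more than 2 categories")
    results = []
    for g1, g2 in itertools.combinations(groups, 2):
        mask = np.isin(lab, (g1, g2))
        results.append(
            permanova(x[mask], lab[mask], n_permutations=n_permutations, seed=seed)
        )
    return results


def classify_size(
    lengths: pd.Series | dict,
    lower: float = MINIATURIZED_MAX_MM,
    upper: float = NON_MINIATURIZED_MIN_MM,
) -> list[SizeClassification]:
    """Assign size classes from skull lengths against the distribution break.

    length <= lower -> miniaturized; length >= upper -> non-miniaturized;
    values strictly inside the gap are flagged ambiguous.
    """
    if lower > upper:
        raise ValueError("lower threshold exceeds upper threshold")
    lengths = pd.Series(lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("skull lengths must be positive")
    out = []
    for taxon, length in lengths.items():
        if length <= lower:
            cls = "miniaturized"
        elif length >= upper:
            cls = "non-miniaturized"
        else:
            cls = "ambiguous"
        out.append(SizeClassification(str(taxon), float(length), cls))
    return out


def find_distribution_break(lengths, min_gap: float = 1.0) -> tuple[float, float] | None:
    """Largest gap in the sorted length distribution, if it exceeds min_gap.

    Returns the (lower, upper) endpoints of the widest inter-value gap wider
    than ``min_gap``, or None when every consecutive gap is at most min_gap.
    This mirrors the miniaturization-threshold procedure: lengths creep up in
    steps of about a millimetre and then jump, and the jump's endpoints become
    the class thresholds.
    """
    values = np.sort(np.asarray(pd.Series(lengths), dtype=float))
    if values.size < 3:
        raise ValueError("need at least 3 lengths to look for a break")
    gaps = np.diff(values)
    best = int(np.argmax(gaps))
    if gaps[best] <= min_gap:
        return None
    return float(values[best]), float(values[best + 1])
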