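"""Differential expression over staged tag libraries.

The per-gene statistic is the exact test of Audic & Claverie for comparing a
tag count between two libraries of known sizes.  Conditional on a count of
``x`` in a library of ``N1`` tags, the count ``y`` in a second library of
``N2`` tags follows

    p(y | x) = (N2/N1)^y * (x+y)! / ( x! * y! * (1 + N2/N1)^(x+y+1) )

which is a negative binomial law with ``x+1`` successes and success
probability ``N1/(N1+N2)``.  The two-sided p-value is twice the smaller tail,
capped at 1.  Both tails are accumulated in log space (log-sum-exp over the
log pmf), which keeps full relative precision for counts up to ~10^6 in
either tail — the naive ``1 - lower`` complement loses the upper tail to
cancellation whenever it is small.

Significance follows the conventional thresholds: Benjamini-Hochberg FDR < 0.001 and
|log2 ratio| > 1, the ratio taken on tags-per-million with a 0.5 pseudocount
(the p-value always uses raw counts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .refmap import ExpressionMatrix
from .simdata import comparison_label, default_comparisons


# ---------------------------------------------------------------------------
# normalisation

def normalize_tpm(count, total):
    """Tags per million: count / total x 10^6."""
    if np.any(np.asarray(total) <= 0):
        raise ValueError("library total must be positive")
    return np.multiply(count, 1e6) / total


def normalize_rpkm(count, length_bp, total_mapped):
    """Reads per kb of gene length per million mapped reads."""
    if np.any(np.asarray(length_bp) <= 0):
        raise ValueError("gene length must be positive")
    if np.any(np.asarray(total_mapped) <= 0):
        raise ValueError("mapped total must be positive")
    return np.asarray(count, dtype=float) / (np.asarray(length_bp) / 1e3) \
        / (total_mapped / 1e6)


# ---------------------------------------------------------------------------
# the exact test

def _log_pmf(k: np.ndarray, x: int, log_r: float, log_1pr: float) -> np.ndarray:
    return (k * log_r + gammaln(x + k + 1) - gammaln(x + 1) - gammaln(k + 1)
            - (x + k + 1) * log_1pr)


def audic_claverie_p(x: int, n1: float, y: int, n2: float) -> float:
    """Two-sided Audic-Claverie p-value for count ``x`` of ``n1`` total tags
    versus count ``y`` of ``n2``.

    Symmetric under (x, n1) <-> (y, n2); returns 1.0 for perfectly balanced
    observations.
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    x, y = int(x), int(y)
    r = n2 / n1
    log_r = math.log(r)
    log_1pr = math.log1p(r)

    # lower tail: sum_{k=0..y} p(k|x)
    lower = float(np.exp(logsumexp(_log_pmf(np.arange(y + 1), x, log_r, log_1pr))))

    # upper tail: sum_{k=y..inf} p(k|x), truncated where terms are negligible.
    q = r / (1.0 + r)                       # asymptotic term ratio < 1
    mean = (x + 1) * r
    sd = math.sqrt((x + 1) * r * (1.0 + r))
    tail = int(-50.0 / math.log(q)) + 50 if q < 1 else 10 ** 7
    hi = int(max(y, mean) + 12 * sd) + tail
    upper = float(np.exp(logsumexp(_log_pmf(np.arange(y, hi + 1), x, log_r, log_1pr))))

    p = 2.0 * min(lower, upper)
    # extreme discrepancies underflow double precision; keep p in (0, 1]
    return min(1.0, max(p, float(np.finfo(float).tiny)))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# staged comparisons

@dataclass(frozen=True)
class Comparison:
    control: str
    case: str

    @property
    def label(self) -> str:
        return comparison_label(self.control, self.case)


@dataclass(frozen=True)
class ComparisonDesign:
    """Ordered (control, case) pairs; default: stages 2-4 of the swelling
    strain against the mutant baseline and against stage 1 (six pairs)."""

    comparisons: tuple[Comparison, ...]

    @classmethod
    def default(cls, libraries: Sequence[str]) -> "ComparisonDesign":
        return cls(tuple(Comparison(c, s) for c, s in default_comparisons(libraries)))

    @classmethod
    def from_pairs(cls, pairs: Iterable[Sequence[str]]) -> "ComparisonDesign":
        return cls(tuple(Comparison(p[0], p[1]) for p in pairs))

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.comparisons]

    def validate_against(self, libraries: Sequence[str]) -> None:
        libs = set(libraries)
        for c in self.comparisons:
            for lib in (c.control, c.case):
                if lib not in libs:
                    raise ValueError(f"comparison references unknown library {lib!r}")
            if c.control == c.case:
                raise ValueError(f"comparison {c.label} pairs a library with itself")


def call_de(matrix: ExpressionMatrix,
            design: ComparisonDesign,
            fdr_threshold: float = 0.001,
            log2_threshold: float = 1.0,
            pseudocount: float = 0.5) -> dict[str, pd.DataFrame]:
    """Run the exact test for every comparison of the design.

    Genes with zero counts in both libraries of a comparison are excluded from
    the test and from the BH family.  Returns one table per comparison with
    columns gene, x, y, N1, N2, log2_ratio, p_value, fdr, significant, where
    the log2 ratio is case-over-control TPM with the pseudocount applied.
    """
    design.validate_against(matrix.libraries)
    out: dict[str, pd.DataFrame] = {}
    for comp in design.comparisons:
        n1 = matrix.lib_totals[comp.control]
        n2 = matrix.lib_totals[comp.case]
        x = matrix.counts[comp.control]
        y = matrix.counts[comp.case]
        tested = (x > 0) | (y > 0)
        xt = x[tested].to_numpy()
        yt = y[tested].to_numpy()
        log2_ratio = np.log2(((yt + pseudocount) / n2) / ((xt + pseudocount) / n1))
        pvals = np.array([audic_claverie_p(xi, n1, yi, n2)
                          for xi, yi in zip(xt, yt)])
        fdr = bh_fdr(pvals) if pvals.size else pvals
        sig = (fdr < fdr_threshold) & (np.abs(log2_ratio) > log2_threshold)
        out[comp.label] = pd.DataFrame({
            "gene": x.index[tested],
            "x": xt, "y": yt, "N1": n1, "N2": n2,
            "log2_ratio": log2_ratio,
            "p_value": pvals, "fdr": fdr,
            "significant": sig,
        }).set_index("gene")
    return out


def up_down_summary(results: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Counts of up-/down-regulated significant genes per comparison."""
    rows = []
    for label, df in results.items():
        sig = df[df["significant"]]
        rows.append({"comparison": label,
                     "up": int((sig["log2_ratio"] > 0).sum()),
                     "down": int((sig["log2_ratio"] < 0).sum()),
                     "significant": int(len(sig))})
    return pd.DataFrame(rows).set_index("comparison")


def significant_sets(results: Mapping[str, pd.DataFrame]) -> dict[str, set[str]]:
    return {label: set(df.index[df["significant"]])
            for label, df in results.items()}


def intersect_comparisons(sets: "Mapping[str, set[str]] | Sequence[set[str]]") -> set[str]:
    """Genes significant in every comparison (exact set intersection)."""
    members = list(sets.values()) if isinstance(sets, Mapping) else list(sets)
    if not members:
        raise ValueError("need at least one comparison")
    out = set(members[0])
    for s in members[1:]:
        out &= s
    return out


def trend_profiles(results: Mapping[str, pd.DataFrame],
                   genes: Iterable[str]) -> pd.DataFrame:
    """log2-ratio vectors (one column per comparison, in design order) for the
    given genes; genes untested in any comparison are dropped."""
    genes = list(genes)
    prof = pd.DataFrame(index=pd.Index(sorted(genes), name="gene"))
    for label, df in results.items():
        prof[label] = df["log2_ratio"].reindex(prof.index)
    return prof.dropna()


def screen_extremes(profiles: pd.DataFrame,
                    threshold: float = 10.0) -> tuple[set[str], set[str]]:
    """Genes with |log2 ratio| > threshold in ALL comparisons and a consistent
    sign; mixed-sign profiles are excluded.  Returns (up_set, down_set)."""
    vals = profiles.to_numpy()
    big = np.abs(vals) > threshold
    all_big = big.all(axis=1)
    up = all_big & (vals > 0).all(axis=1)
    down = all_big & (vals < 0).all(axis=1)
    return set(profiles.index[up]), set(profiles.index[down])


def cluster_trends(profiles: pd.DataFrame, k: int = 4
                   ) -> tuple[pd.Series, np.ndarray]:
    """Hierarchical clustering of log2-ratio profiles.

    Euclidean distance, average linkage, tree cut into ``k`` groups.  Rows are
    sorted by gene id before linkage so the partition is independent of input
    order.  Returns (labels, linkage matrix).
    """
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds number of profiles ({len(profiles)})")
    if k < 1:
        raise ValueError("k must be >= 1")
    prof = profiles.sort_index()
    if len(prof) == 1:
        return pd.Series([1], index=prof.index, name="cluster"), np.empty((0, 4))
    Z = linkage(prof.to_numpy(), method="average", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=prof.index, name="cluster"), Z
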