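"""Kimura 2-parameter distances and barcode-gap analysis.

The K2P model distinguishes transitions (A<->G, C<->T, proportion P of
compared sites) from transversions (proportion Q) and corrects observed
differences for multiple hits:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Distances are computed after *complete deletion*: every alignment column
containing a gap or ambiguity code in any sequence is removed before any
pair is compared, so all pairs see the same sites.  On top of the pairwise
matrix this module partitions divergence into intra- and interspecific
components, evaluates the per-species discrimination criterion (minimum
interspecific distance strictly larger than maximum intraspecific distance),
tests for a barcoding gap by paired t-test, and compares loci by one-way
ANOVA with Bonferroni-corrected pairwise contrasts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .seqdata import AlignmentError, LocusAlignment, SpeciesMap

__all__ = [
    "DistanceMatrix",
    "PairComposition",
    "DivergenceSummary",
    "SpeciesGapStats",
    "complete_deletion",
    "k2p_distance",
    "pairwise_matrix",
    "partition_divergence",
    "species_gap_stats",
    "barcode_gap_test",
    "anova_bonferroni",
]

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}
_GOOD = frozenset("ACGT")


@dataclass(frozen=True)
class PairComposition:
    """Site composition of one sequence pair: transition proportion P,
    transversion proportion Q, over ``n_sites`` compared sites."""

    P: float
    Q: float
    n_sites: int


class DistanceMatrix:
    """Labelled symmetric pairwise distance matrix (substitutions/site).

    Entries where the K2P estimator is undefined (log-domain violation at
    extreme divergence) are flagged in ``undefined`` and excluded from all
    summaries rather than silently propagated as NaN.
    """

    def __init__(
        self,
        labels: Sequence[str],
        values: np.ndarray,
        undefined: np.ndarray | None = None,
    ):
        labels = list(labels)
        values = np.asarray(values, dtype=float)
        n = len(labels)
        if values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if undefined is None:
            undefined = np.zeros((n, n), dtype=bool)
        undefined = np.asarray(undefined, dtype=bool)
        defined = ~undefined
        if not np.allclose(values[defined & defined.T], values.T[defined & defined.T]):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(values) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(values[defined] < 0):
            raise ValueError("negative distances")
        self.labels = labels
        self.values = values
        self.undefined = undefined

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def n_undefined_pairs(self) -> int:
        iu = np.triu_indices(self.n, 1)
        return int(self.undefined[iu].sum())

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.labels.index(pair[0]), self.labels.index(pair[1])
        if self.undefined[i, j]:
            raise ValueError(f"distance undefined for pair {pair}")
        return float(self.values[i, j])

    def is_defined(self, a: str, b: str) -> bool:
        return not self.undefined[self.labels.index(a), self.labels.index(b)]

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(
            list(labels), self.values[np.ix_(idx, idx)], self.undefined[np.ix_(idx, idx)]
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.labels, columns=self.labels)
        return df.mask(pd.DataFrame(self.undefined, index=self.labels, columns=self.labels))

    def write_csv(self, path: str | Path) -> None:
        """Square CSV; undefined entries written empty."""
        self.to_dataframe().to_csv(path)

    def write_phylip_lower(self, path: str | Path) -> None:
        """PHYLIP-style lower-triangle format (undefined entries as NA)."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, lab in enumerate(self.labels):
                cells = [
                    "NA" if self.undefined[i, j] else f"{self.values[i, j]:.6f}"
                    for j in range(i)
                ]
                fh.write("\t".join([lab] + cells) + "\n")

    @classmethod
    def read_csv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        values = df.to_numpy(dtype=float)
        undefined = np.isnan(values)
        values = np.nan_to_num(values)
        return cls([str(c) for c in df.columns], values, undefined)


@dataclass(frozen=True)
class DivergenceSummary:
    """Intra- vs interspecific partition of all defined pairwise distances."""

    intra: dict[str, list[float]]          # species -> within-species distances
    inter: dict[tuple[str, str], list[float]]  # species pair -> between distances
    mean_intra: float | None
    sd_intra: float | None
    mean_inter: float | None
    sd_inter: float | None
    n_undefined: int

    @property
    def intra_values(self) -> list[float]:
        return [d for v in self.intra.values() for d in v]

    @property
    def inter_values(self) -> list[float]:
        return [d for v in self.inter.values() for d in v]


@dataclass(frozen=True)
class SpeciesGapStats:
    """Per-species barcode-gap quantities.

    ``discriminated`` follows the CBOL criterion: the minimum interspecific
    distance involving the species is *strictly* larger than its maximum
    intraspecific distance; a tie fails.  ``evaluable`` is False when the
    species lacks intraspecific pairs (single accession) or heterospecific
    pairs.
    """

    species: str
    max_intra: float | None
    min_inter: float | None
    mean_intra: float | None
    mean_inter: float | None
    ratio_mean_inter_over_intra: float | None
    discriminated: bool | None

    @property
    def evaluable(self) -> bool:
        return self.max_intra is not None and self.min_inter is not None


def complete_deletion(aln: LocusAlignment) -> LocusAlignment:
    """Remove every column containing a gap or ambiguity in any sequence.

    MEGA-style "complete deletion": applied alignment-wide, not pairwise,
    so all pairwise comparisons use an identical site set.  Original column
    indices are retained in ``column_origin``.
    """
    if aln.n < 2:
        raise AlignmentError("complete deletion needs at least 2 sequences")
    arr = aln.to_array()
    keep = [
        j for j in range(aln.length) if all(c in _GOOD for c in arr[:, j])
    ]
    if not keep:
        raise AlignmentError("no columns remain after complete deletion")
    return aln.select_columns(keep)


def k2p_distance(a: str, b: str) -> tuple[float | None, PairComposition]:
    """K2P distance between two gap-free equal-length sequences.

    Returns ``(d, composition)``; ``d`` is ``None`` when the estimator is
    undefined, i.e. ``1 - 2P - Q <= 0`` or ``1 - 2Q <= 0`` (saturation).
    """
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    n = len(a)
    if n == 0:
        raise ValueError("zero compared sites")
    a = a.upper()
    b = b.upper()
    ts = tv = 0
    for x, y in zip(a, b):
        if x == y:
            continue
        if frozenset((x, y)) in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    P = ts / n
    Q = tv / n
    comp = PairComposition(P, Q, n)
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return None, comp
    return -0.5 * math.log(w1) - 0.25 * math.log(w2), comp


def _encode(aln: LocusAlignment) -> np.ndarray:
    arr = aln.to_array()
    code = np.zeros(arr.shape, dtype=np.int8)
    for k, base in enumerate("ACGT"):
        code[arr == base] = k
    return code


def pairwise_matrix(aln: LocusAlignment, deletion: str = "complete") -> DistanceMatrix:
    """All-pairs K2P distance matrix.

    ``deletion="complete"`` (default) first strips every column with a gap
    or ambiguity anywhere; ``deletion="none"`` assumes the alignment is
    already gap-free.  Undefined pairs are flagged, not raised.
    """
    if aln.n < 2:
        raise AlignmentError("need at least 2 sequences")
    if deletion == "complete":
        aln = complete_deletion(aln)
    elif deletion != "none":
        raise ValueError(f"unknown deletion mode {deletion!r}")

    # A<->G and C<->T transitions pair codes {0,2} and {1,3}: differing
    # codes with equal parity are transitions, unequal parity transversions.
    code = _encode(aln)
    n, L = code.shape
    values = np.zeros((n, n))
    undefined = np.zeros((n, n), dtype=bool)
    parity = code % 2
    for i in range(n):
        diff = code[i] != code[i + 1 :]
        same_parity = parity[i] == parity[i + 1 :]
        ts = (diff & same_parity).sum(axis=1)
        tv = (diff & ~same_parity).sum(axis=1)
        P = ts / L
        Q = tv / L
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        bad = (w1 <= 0) | (w2 <= 0)
        d = np.where(bad, 0.0, -0.5 * np.log(np.where(bad, 1.0, w1))
                     - 0.25 * np.log(np.where(bad, 1.0, w2))) + 0.0
        values[i, i + 1 :] = d
        values[i + 1 :, i] = d
        undefined[i, i + 1 :] = bad
        undefined[i + 1 :, i] = bad
    return DistanceMatrix(list(aln.ids), values, undefined)


def partition_divergence(dm: DistanceMatrix, species: SpeciesMap) -> DivergenceSummary:
    """Split all defined pairwise distances into intra- and interspecific sets.

    Means and standard deviations (sample SD, ddof=1; None for <2 values)
    are taken over defined pairs only; undefined pairs are counted.
    """
    intra: dict[str, list[float]] = {}
    inter: dict[tuple[str, str], list[float]] = {}
    n_undef = 0
    for i, j in itertools.combinations(range(dm.n), 2):
        if dm.undefined[i, j]:
            n_undef += 1
            continue
        a, b = dm.labels[i], dm.labels[j]
        sa, sb = species.species_of(a), species.species_of(b)
        d = float(dm.values[i, j])
        if sa == sb:
            intra.setdefault(sa, []).append(d)
        else:
            inter.setdefault(tuple(sorted((sa, sb))), []).append(d)

    def _mean(vals: list[float]) -> float | None:
        return float(np.mean(vals)) if vals else None

    def _sd(vals: list[float]) -> float | None:
        return float(np.std(vals, ddof=1)) if len(vals) >= 2 else None

    intra_all = [d for v in intra.values() for d in v]
    inter_all = [d for v in inter.values() for d in v]
    return DivergenceSummary(
        intra=intra,
        inter=inter,
        mean_intra=_mean(intra_all),
        sd_intra=_sd(intra_all),
        mean_inter=_mean(inter_all),
        sd_inter=_sd(inter_all),
        n_undefined=n_undef,
    )


def species_gap_stats(dm: DistanceMatrix, species: SpeciesMap) -> list[SpeciesGapStats]:
    """Per-species discrimination statistics.

    For each species: maximum intraspecific distance, minimum interspecific
    distance over pairs *involving that species*, ratio of the species' mean
    inter to mean intra distance, and the strict-inequality discrimination
    flag.  Species with no intraspecific pairs (or no defined heterospecific
    pairs) are returned with ``discriminated=None`` (not evaluable).
    """
    by_species: dict[str, dict[str, list[float]]] = {}
    for i, j in itertools.combinations(range(dm.n), 2):
        if dm.undefined[i, j]:
            continue
        a, b = dm.labels[i], dm.labels[j]
        sa, sb = species.species_of(a), species.species_of(b)
        d = float(dm.values[i, j])
        if sa == sb:
            by_species.setdefault(sa, {"intra": [], "inter": []})["intra"].append(d)
        else:
            by_species.setdefault(sa, {"intra": [], "inter": []})["inter"].append(d)
            by_species.setdefault(sb, {"intra": [], "inter": []})["inter"].append(d)

    out = []
    for sp in species.species_names(dm.labels):
        vals = by_species.get(sp, {"intra": [], "inter": []})
        max_intra = max(vals["intra"]) if vals["intra"] else None
        min_inter = min(vals["inter"]) if vals["inter"] else None
        mean_intra = float(np.mean(vals["intra"])) if vals["intra"] else None
        mean_inter = float(np.mean(vals["inter"])) if vals["inter"] else None
        if mean_intra is not None and mean_inter is not None and mean_intra > 0:
            ratio = mean_inter / mean_intra
        else:
            ratio = None
        discriminated = (
            min_inter > max_intra
            if max_intra is not None and min_inter is not None
            else None
        )
        out.append(
            SpeciesGapStats(
                species=sp,
                max_intra=max_intra,
                min_inter=min_inter,
                mean_intra=mean_intra,
                mean_inter=mean_inter,
                ratio_mean_inter_over_intra=ratio,
                discriminated=discriminated,
            )
        )
    return out


def gap_stats_frame(stats: Iterable[SpeciesGapStats], locus: str = "") -> pd.DataFrame:
    """Tidy per-species gap-statistics table (one row per species)."""
    rows = []
    for s in stats:
        rows.append(
            {
                "locus": locus,
                "species": s.species,
                "max_intra": s.max_intra,
                "min_inter": s.min_inter,
                "ratio": s.ratio_mean_inter_over_intra,
                "discriminated": s.discriminated,
            }
        )
    return pd.DataFrame(rows)


def barcode_gap_test(stats: Sequence[SpeciesGapStats]) -> tuple[float, float, int]:
    """Paired t-test of minimum interspecific vs maximum intraspecific
    distance across evaluable species.

    A significant positive difference indicates a barcoding gap.  Returns
    ``(t, two-sided p, n species used)``.
    """
    pairs = [(s.min_inter, s.max_intra) for s in stats if s.evaluable]
    if len(pairs) < 2:
        raise ValueError("barcode gap test needs >= 2 evaluable species")
    inter = np.array([p[0] for p in pairs])
    intra = np.array([p[1] for p in pairs])
    if np.array_equal(inter, intra):
        return 0.0, 1.0, len(pairs)
    t, p = stats_ttest_rel(inter, intra)
    return float(t), float(p), len(pairs)


def stats_ttest_rel(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    res = stats.ttest_rel(x, y)
    return res.statistic, res.pvalue


def anova_bonferroni(
    groups: dict[str, Sequence[float]], log_transform: bool = False
) -> tuple[float, float, list[tuple[tuple[str, str], float]]]:
    """One-way ANOVA across named groups plus Bonferroni pairwise contrasts.

    Used to compare per-locus divergence distributions.  Each pairwise
    contrast is a two-sample t-test whose p-value is multiplied by the
    number of comparisons (capped at 1).  ``log_transform`` applies
    ``log(x + 1e-6)`` to stabilise variances of near-zero distances.

    Returns ``(F, p, [((group_a, group_b), adjusted_p), ...])``.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    data = {}
    for name in names:
        vals = np.asarray(groups[name], dtype=float)
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
        data[name] = np.log(vals + 1e-6) if log_transform else vals
    F, p = stats.f_oneway(*data.values())
    if not np.isfinite(F):  # all groups constant and equal
        F, p = 0.0, 1.0
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    pairwise = []
    for a, b in pairs:
        res = stats.ttest_ind(data[a], data[b])
        praw = 1.0 if not np.isfinite(res.pvalue) else float(res.pvalue)
        pairwise.append(((a, b), min(1.0, praw * m)))
    return float(F), float(p), pairwise
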