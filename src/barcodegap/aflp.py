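"""AFLP binary-marker diversity analysis.

AFLP fingerprinting yields a binary accessions × bands matrix (band
presence/absence per primer-pair combination).  This module summarises
polymorphism and species-unique bands, computes Jaccard similarities
(shared-band proportion ignoring joint absences), clusters accessions by
UPGMA with a cophenetic-correlation check, embeds the distance matrix by
principal coordinates analysis (Gower double-centering + eigendecomposition,
no negative-eigenvalue correction), and tests the association between
genetic and WGS84 geographic distances with a seeded one-sided Mantel
permutation test.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode

from .distances import DistanceMatrix
from .seqdata import SpeciesMap

__all__ = [
    "BandMatrix",
    "PairCounts",
    "PolymorphismSummary",
    "PCoAResult",
    "MantelResult",
    "polymorphism_summary",
    "unique_bands",
    "species_band_distribution",
    "pair_counts",
    "jaccard_similarity",
    "jaccard_distance_matrix",
    "cophenetic_correlation",
    "pcoa",
    "mantel_test",
    "geo_distance_matrix",
]


class BandMatrix:
    """Binary accessions × bands table with primer-pair annotation.

    Band identifiers follow the ``"primer:size"`` convention (e.g.
    ``"P3:142"``); the primer name is everything before the first colon,
    or the whole id if no colon is present.
    """

    def __init__(self, frame: pd.DataFrame):
        values = frame.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("band matrix entries must be 0 or 1")
        if frame.columns.duplicated().any():
            raise ValueError("duplicate band ids")
        if frame.index.duplicated().any():
            raise ValueError("duplicate accession ids")
        self.frame = frame.astype(np.int8)

    @property
    def accessions(self) -> list[str]:
        return [str(a) for a in self.frame.index]

    @property
    def bands(self) -> list[str]:
        return [str(b) for b in self.frame.columns]

    @property
    def n_bands(self) -> int:
        return self.frame.shape[1]

    def primer_of(self, band: str) -> str:
        return band.split(":", 1)[0]

    def primers(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.bands:
            seen.setdefault(self.primer_of(b), None)
        return list(seen)

    def profile(self, accession: str) -> np.ndarray:
        return self.frame.loc[accession].to_numpy()

    @classmethod
    def read_csv(cls, path: str | Path) -> "BandMatrix":
        return cls(pd.read_csv(path, index_col=0))

    def write_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path)


@dataclass(frozen=True)
class PairCounts:
    """2×2 band-sharing counts for one accession pair."""

    a11: int
    a10: int
    a01: int
    a00: int

    @property
    def total(self) -> int:
        return self.a11 + self.a10 + self.a01 + self.a00


@dataclass(frozen=True)
class PolymorphismSummary:
    """Band counts per primer pair and overall.

    A band is polymorphic iff it is neither present in all accessions nor
    absent from all.  Percentages are rounded to one decimal.
    """

    per_primer: pd.DataFrame  # index primer; columns n_bands, n_polymorphic, pct_polymorphic
    n_bands: int
    n_polymorphic: int
    pct_polymorphic: float


def polymorphism_summary(bm: BandMatrix) -> PolymorphismSummary:
    if bm.n_bands == 0:
        raise ValueError("empty band matrix")
    presence = bm.frame.sum(axis=0)
    n_acc = len(bm.accessions)
    poly = (presence > 0) & (presence < n_acc)
    rows = []
    for primer in bm.primers():
        cols = [b for b in bm.bands if bm.primer_of(b) == primer]
        n = len(cols)
        npoly = int(poly[cols].sum())
        rows.append(
            {
                "primer": primer,
                "n_bands": n,
                "n_polymorphic": npoly,
                "pct_polymorphic": round(100.0 * npoly / n, 1),
            }
        )
    per_primer = pd.DataFrame(rows).set_index("primer")
    n_total = bm.n_bands
    n_poly = int(poly.sum())
    return PolymorphismSummary(
        per_primer=per_primer,
        n_bands=n_total,
        n_polymorphic=n_poly,
        pct_polymorphic=round(100.0 * n_poly / n_total, 1),
    )


def unique_bands(bm: BandMatrix, species: SpeciesMap) -> list[tuple[str, str]]:
    """Bands present in at least one accession of exactly one species.

    Returns ``(band_id, species)`` pairs; such private bands are the only
    strictly species-diagnostic AFLP signal.
    """
    out = []
    sp_of = {a: species.species_of(a) for a in bm.accessions}
    for band in bm.bands:
        col = bm.frame[band]
        carriers = {sp_of[a] for a in bm.accessions if col[a] == 1}
        if len(carriers) == 1:
            out.append((band, next(iter(carriers))))
    return out


def species_band_distribution(bm: BandMatrix, species: SpeciesMap) -> pd.DataFrame:
    """Species × primer table of band counts.

    A species' count for a primer is the number of that primer's bands
    present in at least one of its accessions.
    """
    primers = bm.primers()
    rows = {}
    for sp in species.species_names(bm.accessions):
        members = species.members(sp, bm.accessions)
        present = bm.frame.loc[members].max(axis=0)
        rows[sp] = {
            p: int(sum(present[b] for b in bm.bands if bm.primer_of(b) == p))
            for p in primers
        }
    return pd.DataFrame.from_dict(rows, orient="index", columns=primers)


def pair_counts(x: np.ndarray, y: np.ndarray) -> PairCounts:
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    return PairCounts(
        a11=int(((x == 1) & (y == 1)).sum()),
        a10=int(((x == 1) & (y == 0)).sum()),
        a01=int(((x == 0) & (y == 1)).sum()),
        a00=int(((x == 0) & (y == 0)).sum()),
    )


def jaccard_similarity(x: np.ndarray, y: np.ndarray) -> float | None:
    """Jaccard coefficient S = a11 / (a11 + a10 + a01).

    Joint absences are ignored; ``None`` when both profiles are all-zero
    (undefined).  The distance used downstream is 1 − S.
    """
    c = pair_counts(x, y)
    denom = c.a11 + c.a10 + c.a01
    if denom == 0:
        return None
    return c.a11 / denom


def jaccard_distance_matrix(bm: BandMatrix) -> DistanceMatrix:
    """1 − Jaccard similarity over all accession pairs, bands from all
    primer pairs concatenated into one profile."""
    accs = bm.accessions
    n = len(accs)
    values = np.zeros((n, n))
    undefined = np.zeros((n, n), dtype=bool)
    profiles = [bm.profile(a) for a in accs]
    for i, j in itertools.combinations(range(n), 2):
        s = jaccard_similarity(profiles[i], profiles[j])
        if s is None:
            undefined[i, j] = undefined[j, i] = True
        else:
            values[i, j] = values[j, i] = 1.0 - s
    return DistanceMatrix(accs, values, undefined)


def cophenetic_correlation(tree: TreeNode, dm: DistanceMatrix) -> float:
    """Pearson correlation between tree-implied (cophenetic) and original
    distances over all off-diagonal pairs.  Values near 1 mean the
    dendrogram faithfully represents the distance matrix."""
    tip_names = sorted(t.name for t in tree.tips())
    if set(tip_names) != set(dm.labels):
        raise ValueError("tree leaves do not match matrix labels")
    coph = tree.tip_tip_distances()
    x, y = [], []
    for a, b in itertools.combinations(dm.labels, 2):
        x.append(float(coph[a, b]))
        y.append(dm[a, b])
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance distance vector")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass(frozen=True)
class PCoAResult:
    """Principal coordinates of a distance matrix.

    ``eigenvalues`` are in descending order (negative ones, arising from
    non-Euclidean distances like Jaccard, are reported uncorrected);
    ``pct_variance`` is each positive eigenvalue as a percentage of the sum
    of positive eigenvalues, 0 for the rest.  ``coordinates`` has one row
    per accession and one column per positive axis.
    """

    labels: list[str]
    eigenvalues: np.ndarray
    coordinates: np.ndarray
    pct_variance: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis{i+1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.labels, columns=cols)


def pcoa(dm: DistanceMatrix) -> PCoAResult:
    """Classical scaling: Gower double-centering of −½D², eigendecomposition.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue), restricted to
    positive eigenvalues; axes ordered by decreasing eigenvalue.
    """
    if dm.n_undefined_pairs:
        raise ValueError("cannot ordinate a matrix with undefined entries")
    D = dm.values
    n = dm.n
    if np.all(D == 0):
        warnings.warn("all-zero distance matrix: degenerate ordination")
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    pos = eigval > 1e-10 * max(1.0, abs(eigval[0]))
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    total_pos = eigval[pos].sum()
    pct = np.where(pos, 100.0 * eigval / total_pos, 0.0) if total_pos > 0 else np.zeros(n)
    return PCoAResult(
        labels=list(dm.labels),
        eigenvalues=eigval,
        coordinates=coords,
        pct_variance=pct,
    )


@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_permutations: int
    seed: int | None


def _offdiag(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], 1)
    return values[iu]


def mantel_test(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    n_permutations: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """One-sided (positive association) Mantel permutation test.

    ``r`` is the Pearson correlation of the upper-triangle entries; the null
    distribution permutes rows and columns of the second matrix jointly.
    ``p = (#{r_perm >= r_obs} + 1) / (n_permutations + 1)``.  Labels must
    match; ``dm2`` is reordered to ``dm1``'s label order first.
    """
    if set(dm1.labels) != set(dm2.labels):
        raise ValueError("matrices have different labels")
    dm2 = dm2.submatrix(dm1.labels)
    if dm1.n_undefined_pairs or dm2.n_undefined_pairs:
        raise ValueError("undefined entries in Mantel input")
    x = _offdiag(dm1.values)
    v2 = dm2.values
    y = _offdiag(v2)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance distance vector")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    n = dm1.n
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        r_perm = np.corrcoef(x, _offdiag(v2[np.ix_(perm, perm)]))[0, 1]
        if r_perm >= r_obs:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return MantelResult(r=r_obs, p=p, n_permutations=n_permutations, seed=seed)


# WGS84 ellipsoid
_WGS84_A = 6378137.0
_WGS84_F = 1.0 / 298.257223563
_WGS84_B = _WGS84_A * (1.0 - _WGS84_F)


def _vincenty_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Vincenty inverse geodesic on the WGS84 ellipsoid, in kilometres.

    Falls back to the spherical haversine formula for the rare
    nearly-antipodal pairs where the iteration fails to converge (both are
    far beyond the precision geographic sampling requires).
    """
    if (lat1, lon1) == (lat2, lon2):
        return 0.0
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    L = math.radians(lon2 - lon1)
    U1 = math.atan((1 - _WGS84_F) * math.tan(phi1))
    U2 = math.atan((1 - _WGS84_F) * math.tan(phi2))
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sinU2, cosU2 = math.sin(U2), math.cos(U2)
    lam = L
    for _ in range(200):
        sinl, cosl = math.sin(lam), math.cos(lam)
        sin_sigma = math.hypot(cosU2 * sinl, cosU1 * sinU2 - sinU1 * cosU2 * cosl)
        if sin_sigma == 0:
            return 0.0
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cosl
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sinl / sin_sigma
        cos2_alpha = 1.0 - sin_alpha**2
        cos_2sm = cos_sigma - 2 * sinU1 * sinU2 / cos2_alpha if cos2_alpha else 0.0
        C = _WGS84_F / 16 * cos2_alpha * (4 + _WGS84_F * (4 - 3 * cos2_alpha))
        lam_prev = lam
        lam = L + (1 - C) * _WGS84_F * sin_alpha * (
            sigma + C * sin_sigma * (cos_2sm + C * cos_sigma * (-1 + 2 * cos_2sm**2))
        )
        if abs(lam - lam_prev) < 1e-12:
            break
    else:  # no convergence: haversine fallback (~0.5% worst case)
        R = (2 * _WGS84_A + _WGS84_B) / 3
        h = (
            math.sin((phi2 - phi1) / 2) ** 2
            + math.cos(phi1) * math.cos(phi2) * math.sin(L / 2) ** 2
        )
        return 2 * R * math.asin(math.sqrt(h)) / 1000.0
    u2 = cos2_alpha * (_WGS84_A**2 - _WGS84_B**2) / _WGS84_B**2
    A = 1 + u2 / 16384 * (4096 + u2 * (-768 + u2 * (320 - 175 * u2)))
    Bc = u2 / 1024 * (256 + u2 * (-128 + u2 * (74 - 47 * u2)))
    delta = Bc * sin_sigma * (
        cos_2sm
        + Bc
        / 4
        * (
            cos_sigma * (-1 + 2 * cos_2sm**2)
            - Bc / 6 * cos_2sm * (-3 + 4 * sin_sigma**2) * (-3 + 4 * cos_2sm**2)
        )
    )
    return _WGS84_B * A * (sigma - delta) / 1000.0


def geo_distance_matrix(
    species: SpeciesMap, accessions: Sequence[str] | None = None
) -> DistanceMatrix:
    """Pairwise WGS84 geodesic distances (km) from accession GPS records.

    Accessions without coordinates are excluded with a warning.
    """
    accs = list(accessions) if accessions is not None else species.accessions()
    usable = []
    for a in accs:
        rec = species[a]
        if rec.latitude is None or rec.longitude is None:
            warnings.warn(f"accession {a} has no GPS coordinates; excluded")
            continue
        if not (-90 <= rec.latitude <= 90 and -180 <= rec.longitude <= 180):
            raise ValueError(f"coordinates out of range for {a}")
        usable.append(a)
    n = len(usable)
    values = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        ra, rb = species[usable[i]], species[usable[j]]
        d = _vincenty_km(ra.latitude, ra.longitude, rb.latitude, rb.longitude)
        values[i, j] = values[j, i] = d
    return DistanceMatrix(usable, values)
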