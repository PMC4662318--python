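"""Biome-structured diversity and spatial statistics.

Rarefaction allelic richness (multiple random reductions of N), private
alleles, allele-frequency summaries, microsatellite summary statistics
(Na, private alleles, Ho/He), pairwise geographic and genetic distance
matrices, Mantel and partial Mantel permutation tests, and the paired
t-test used to compare genotyping methods on the same individuals.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RarefactionResult",
    "MantelResult",
    "PairedTestResult",
    "allelic_richness",
    "private_alleles",
    "allele_frequency_summary",
    "microsat_summary",
    "geo_distance_matrix",
    "genetic_distance_individuals",
    "mantel",
    "partial_mantel",
    "paired_t_test",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass
class RarefactionResult:
    group: str
    g: int
    mean_richness: float
    sd_richness: float
    n_replicates: int


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    partial: bool = False
    conditioning: str | None = None


@dataclass
class PairedTestResult:
    t: float
    df: int
    p_value: float


# ---------------------------------------------------------------------------
# allelic richness (rarefaction by repeated random reduction)


def allelic_richness(
    genotypes: dict[str, set[str]],
    groups: dict[str, str],
    g: int | None = None,
    n_reps: int = 10_000,
    seed: int | None = None,
    exact: bool = False,
) -> list[RarefactionResult]:
    """Rarefaction allelic richness per group at standardized sample size g.

    ``genotypes`` maps individual -> set of allele names (a diploid
    microsatellite locus can be passed as 1- or 2-element sets). ``groups``
    maps individual -> group label. Each replicate draws ``g`` individuals
    without replacement from the group and counts distinct alleles; the
    default ``g`` is the minimum group size. With ``exact=True`` the mean and
    SD are computed by exhaustive enumeration of all C(n, g) subsets instead
    of resampling (intended for small groups).
    """
    members: dict[str, list[str]] = {}
    for ind, grp in groups.items():
        if ind in genotypes:
            members.setdefault(grp, []).append(ind)
    if not members:
        raise ValueError("no genotyped individuals in any group")
    if g is None:
        g = min(len(v) for v in members.values())
    rng = np.random.default_rng(seed)
    results = []
    for grp in sorted(members):
        inds = sorted(members[grp])
        if g > len(inds):
            raise ValueError(f"g={g} exceeds group size {len(inds)} for {grp}")
        if exact:
            vals = [
                float(len(set().union(*(genotypes[i] for i in sub))))
                for sub in itertools.combinations(inds, g)
            ]
            results.append(
                RarefactionResult(grp, g, float(np.mean(vals)),
                                  float(np.std(vals)), len(vals))
            )
            continue
        vals = np.empty(n_reps)
        for r in range(n_reps):
            sub = rng.choice(len(inds), size=g, replace=False)
            vals[r] = len(set().union(*(genotypes[inds[k]] for k in sub)))
        results.append(
            RarefactionResult(grp, g, float(vals.mean()), float(vals.std()), n_reps)
        )
    return results


# ---------------------------------------------------------------------------
# private alleles / frequency summaries


def private_alleles(
    genotypes: dict[str, set[str]], groups: dict[str, str]
) -> dict[str, set[str]]:
    """Alleles whose carriers all belong to a single group.

    Returns group -> set of private alleles (groups with none map to an
    empty set).
    """
    carriers: dict[str, set[str]] = {}
    for ind, alleles in genotypes.items():
        for a in alleles:
            carriers.setdefault(a, set()).add(groups[ind])
    out: dict[str, set[str]] = {grp: set() for grp in set(groups.values())}
    for allele, grps in carriers.items():
        if len(grps) == 1:
            out[next(iter(grps))].add(allele)
    return out


def allele_frequency_summary(
    genotypes: dict[str, set[str]],
    groups: dict[str, str] | None = None,
    coverage: dict[str, int] | None = None,
    frequent_threshold: float = 0.10,
    rare_max_carriers: int = 2,
) -> pd.DataFrame:
    """Per-allele carrier counts, relative frequencies and rarity classes.

    Relative frequency = carriers / genotyped individuals. ``frequent`` is
    strict (> threshold); ``rare`` means carried by at most
    ``rare_max_carriers`` individuals. When ``groups`` is given the biome
    span (number of groups of occurrence) is reported, and when ``coverage``
    is given the per-allele read coverage is carried through.
    """
    n_ind = len(genotypes)
    if n_ind == 0:
        raise ValueError("no genotyped individuals")
    carriers: dict[str, set[str]] = {}
    for ind, alleles in genotypes.items():
        for a in alleles:
            carriers.setdefault(a, set()).add(ind)
    rows = []
    for allele in sorted(carriers):
        n = len(carriers[allele])
        freq = n / n_ind
        row = {
            "allele": allele,
            "n_individuals": n,
            "frequency": freq,
            "frequent": freq > frequent_threshold,
            "rare": n <= rare_max_carriers,
        }
        if groups is not None:
            row["n_biomes"] = len({groups[i] for i in carriers[allele]})
        if coverage is not None:
            row["coverage"] = coverage.get(allele, 0)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# microsatellites


def microsat_summary(
    genotable: pd.DataFrame, groups: dict[str, str], unbiased: bool = False
) -> pd.DataFrame:
    """Per-locus, per-group Na, private alleles, Ho and He.

    ``genotable`` is indexed by individual with two columns per locus named
    ``<locus>_1`` / ``<locus>_2``; missing calls are NaN/None. He is
    1 - sum(p_i^2) by default; ``unbiased=True`` applies the 2n/(2n-1)
    small-sample correction.
    """
    loci = sorted({c.rsplit("_", 1)[0] for c in genotable.columns})
    grp_labels = sorted(set(groups.values()))
    # which alleles occur in which groups, per locus (for private counts)
    rows = []
    for locus in loci:
        cols = [f"{locus}_1", f"{locus}_2"]
        occurrence: dict[object, set[str]] = {}
        for ind, row in genotable[cols].iterrows():
            grp = groups[ind]
            for a in row:
                if pd.notna(a):
                    occurrence.setdefault(a, set()).add(grp)
        for grp in grp_labels:
            inds = [i for i in genotable.index if groups[i] == grp]
            calls = genotable.loc[inds, cols].dropna()
            if calls.empty:
                rows.append({"locus": locus, "group": grp, "n": 0, "Na": 0,
                             "private": 0, "Ho": np.nan, "He": np.nan})
                continue
            a1, a2 = calls[cols[0]], calls[cols[1]]
            pooled = pd.concat([a1, a2])
            freqs = pooled.value_counts(normalize=True)
            he = 1.0 - float((freqs**2).sum())
            if unbiased:
                n2 = len(pooled)
                he *= n2 / (n2 - 1) if n2 > 1 else np.nan
            ho = float((a1.values != a2.values).mean())
            private = sum(
                1 for a in freqs.index if occurrence[a] == {grp}
            )
            rows.append({
                "locus": locus, "group": grp, "n": len(calls),
                "Na": int(freqs.size), "private": private, "Ho": ho, "He": he,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# distance matrices


def _haversine_km(lat1, lon1, lat2, lon2) -> float:
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def geo_distance_matrix(
    coords: dict[str, tuple[float, float]],
    mode: str = "haversine",
    log10: bool = True,
    floor_km: float = 0.1,
) -> pd.DataFrame:
    """Pairwise geographic distances in (log10) km.

    ``coords`` maps individual -> (latitude, longitude) in decimal degrees.
    ``mode`` is 'haversine' (great-circle) or 'planar' (Euclidean on degrees
    scaled by 111.32 km/deg with latitude-corrected longitude). Off-diagonal
    distances are floored at ``floor_km`` before taking log10; the diagonal
    stays 0.
    """
    ids = sorted(coords)
    for ind, (lat, lon) in coords.items():
        if not (-90 <= lat <= 90 and -180 <= lon <= 180):
            raise ValueError(f"invalid coordinates for {ind}: ({lat}, {lon})")
    n = len(ids)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        lat1, lon1 = coords[ids[i]]
        lat2, lon2 = coords[ids[j]]
        if mode == "haversine":
            d = _haversine_km(lat1, lon1, lat2, lon2)
        elif mode == "planar":
            mean_lat = math.radians((lat1 + lat2) / 2)
            dx = (lon2 - lon1) * 111.32 * math.cos(mean_lat)
            dy = (lat2 - lat1) * 111.32
            d = math.hypot(dx, dy)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if log10:
            d = math.log10(max(d, floor_km))
        mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=ids, columns=ids)


def genetic_distance_individuals(
    data: dict[str, set[str]] | pd.DataFrame, kind: str = "presence_mismatch"
) -> pd.DataFrame:
    """Pairwise individual genetic distances.

    ``presence_mismatch`` (for presence/absence allele sets): 1 - 2*|shared|
    / (|A| + |B|). ``microsat_allele_sharing`` (for a diploid table as in
    :func:`microsat_summary`): mean over loci of the proportion of
    non-shared alleles, missing loci pairwise-deleted.
    """
    if kind == "presence_mismatch":
        assert isinstance(data, dict)
        ids = sorted(k for k, v in data.items() if v)
        n = len(ids)
        mat = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            a, b = data[ids[i]], data[ids[j]]
            d = 1.0 - 2.0 * len(a & b) / (len(a) + len(b))
            mat[i, j] = mat[j, i] = d
        return pd.DataFrame(mat, index=ids, columns=ids)
    if kind == "microsat_allele_sharing":
        assert isinstance(data, pd.DataFrame)
        loci = sorted({c.rsplit("_", 1)[0] for c in data.columns})
        ids = sorted(data.index)
        n = len(ids)
        mat = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            shares = []
            for locus in loci:
                cols = [f"{locus}_1", f"{locus}_2"]
                gi = [data.at[ids[i], c] for c in cols]
                gj = [data.at[ids[j], c] for c in cols]
                if any(pd.isna(x) for x in gi + gj):
                    continue
                # shared allele count between two diploid genotypes (0..2)
                shared = 0
                pool = list(gj)
                for a in gi:
                    if a in pool:
                        shared += 1
                        pool.remove(a)
                shares.append(1.0 - shared / 2.0)
            d = float(np.mean(shares)) if shares else np.nan
            mat[i, j] = mat[j, i] = d
        return pd.DataFrame(mat, index=ids, columns=ids)
    raise ValueError(f"unknown kind {kind!r}")


# ---------------------------------------------------------------------------
# Mantel tests


def _check_square(mat: np.ndarray, name: str) -> None:
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} is not square")
    if not np.allclose(mat, mat.T):
        raise ValueError(f"{name} is not symmetric")
    if not np.allclose(np.diag(mat), 0):
        raise ValueError(f"{name} has a nonzero diagonal")


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def mantel(
    A: pd.DataFrame | np.ndarray,
    B: pd.DataFrame | np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    exact: bool = False,
) -> MantelResult:
    """Mantel matrix-correlation permutation test (two-tailed).

    r is the Pearson correlation of off-diagonal upper-triangle entries; the
    p-value counts simultaneous row/column permutations of B with
    ``|r*| >= |r|`` under the add-one rule. ``exact=True`` enumerates all
    n! permutations (identity included, no add-one needed) — small n only.
    """
    a = np.asarray(A, dtype=float)
    b = np.asarray(B, dtype=float)
    _check_square(a, "A")
    _check_square(b, "B")
    if a.shape != b.shape:
        raise ValueError("matrix dimensions differ")
    n = a.shape[0]
    va = _upper(a)
    if np.std(va) == 0 or np.std(_upper(b)) == 0:
        return MantelResult(np.nan, np.nan, 0)
    r_obs = float(np.corrcoef(va, _upper(b))[0, 1])
    if exact:
        hits = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            p = np.array(perm)
            r_star = np.corrcoef(va, _upper(b[np.ix_(p, p)]))[0, 1]
            total += 1
            if abs(r_star) >= abs(r_obs) - 1e-12:
                hits += 1
        return MantelResult(r_obs, hits / total, total)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        r_star = np.corrcoef(va, _upper(b[np.ix_(p, p)]))[0, 1]
        if abs(r_star) >= abs(r_obs) - 1e-12:
            hits += 1
    return MantelResult(r_obs, (hits + 1) / (n_perm + 1), n_perm)


def partial_mantel(
    A: pd.DataFrame | np.ndarray,
    B: pd.DataFrame | np.ndarray,
    C: pd.DataFrame | np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
) -> MantelResult:
    """Partial Mantel test of A ~ B conditioned on C.

    Upper-triangle vectors of A and B are each regressed on C; r is the
    Pearson correlation of the residuals, and the permutation p-value is
    obtained by permuting the residuals of A (two-tailed, add-one rule).
    """
    a = np.asarray(A, dtype=float)
    b = np.asarray(B, dtype=float)
    c = np.asarray(C, dtype=float)
    for m, nm in ((a, "A"), (b, "B"), (c, "C")):
        _check_square(m, nm)
    va, vb, vc = _upper(a), _upper(b), _upper(c)

    def _residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
        if np.std(x) == 0:
            return y - y.mean()
        X = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return y - X @ beta

    ra, rb = _residuals(va, vc), _residuals(vb, vc)
    if np.std(ra) == 0 or np.std(rb) == 0:
        return MantelResult(np.nan, np.nan, 0, partial=True, conditioning="C")
    r_obs = float(np.corrcoef(ra, rb)[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        r_star = np.corrcoef(rng.permutation(ra), rb)[0, 1]
        if abs(r_star) >= abs(r_obs) - 1e-12:
            hits += 1
    return MantelResult(r_obs, (hits + 1) / (n_perm + 1), n_perm,
                        partial=True, conditioning="C")


# ---------------------------------------------------------------------------
# paired comparison of genotyping methods


def paired_t_test(x: list[float], y: list[float]) -> PairedTestResult:
    """Two-tailed Student's t-test for paired per-subject counts (d = y - x)."""
    if len(x) != len(y):
        raise ValueError("paired samples differ in length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least two pairs")
    d = np.asarray(y, dtype=float) - np.asarray(x, dtype=float)
    if np.allclose(d.std(ddof=1), 0):
        return PairedTestResult(t=0.0 if d.mean() == 0 else np.inf, df=n - 1,
                                p_value=1.0 if d.mean() == 0 else 0.0)
    res = stats.ttest_rel(y, x)
    return PairedTestResult(t=float(res.statistic), df=n - 1, p_value=float(res.pvalue))
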