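"""Two-point linkage analysis: recombination-fraction likelihoods, LOD
clustering into linkage groups, marker ordering and sex-specific maps.

The two-point likelihood treats parental phase as unknown: for each
nuclear family it sums, with equal priors, over the phase configurations
of each doubly-heterozygous parent, with offspring meioses conditionally
independent given phase.  Sex-specific recombination fractions are
informed only by meioses from parents of that sex that are heterozygous
at both markers; the male and female fractions are maximised jointly
(coordinate ascent), because in both-doubly-het families the two
transmissions are entangled.

An optional genotype-emission error rate makes the likelihood robust to
mistyped calls: each observed genotype is a mixture of the true genotype
(prob 1-e) and the two other states (e/2 each); adjacent-pair estimation
additionally marginalises over single parent-call mistypes.  This is
two-point robustness — there is no multipoint error correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import logsumexp

from .genotypes import GenotypeMatrix

LN10 = np.log(10.0)
_FLOOR = 1e-300

#: theta grid used for batch LOD screening (dense near 0 where LOD is steep)
DEFAULT_THETA_GRID = np.array(
    [0.0, 0.005, 0.01, 0.02, 0.03, 0.05, 0.075, 0.1,
     0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5]
)

# ---------------------------------------------------------------------------
# map functions
# ---------------------------------------------------------------------------


def haldane_cM(theta):
    """Haldane map distance in cM: d = -50 ln(1 - 2 theta)."""
    theta = np.asarray(theta, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(theta < 0.5, -50.0 * np.log1p(-2.0 * np.minimum(theta, 0.5)), np.inf)


def inverse_haldane(d_cM):
    return 0.5 * (1.0 - np.exp(-np.asarray(d_cM, dtype=float) / 50.0))


def kosambi_cM(theta):
    """Kosambi map distance in cM: d = 25 ln((1+2t)/(1-2t))."""
    theta = np.asarray(theta, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(theta < 0.5, 25.0 * (np.log1p(2 * theta) - np.log1p(-2 * theta)), np.inf)


MAP_FUNCTIONS = {"haldane": haldane_cM, "kosambi": kosambi_cM}

# ---------------------------------------------------------------------------
# two-point likelihood
# ---------------------------------------------------------------------------


def _transmission(gi: int, gj: int, phase: int, theta: np.ndarray) -> np.ndarray:
    """P(parent transmits allele pair (a_i, a_j)), shape (T, 2, 2).

    Haplotypes are built from the ordered allele pairs of each genotype;
    ``phase`` swaps the second marker's alleles when both are het.  For a
    parent not doubly heterozygous the two phases coincide, so averaging
    over both is harmless.
    """
    ai = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[gi]
    aj = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[gj]
    if gj == 1 and phase == 1:
        aj = (1, 0)
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    p = np.zeros((len(theta), 2, 2))
    half = 0.5 * np.ones_like(theta)
    p[:, ai[0], aj[0]] += half * (1.0 - theta)
    p[:, ai[1], aj[1]] += half * (1.0 - theta)
    p[:, ai[0], aj[1]] += half * theta
    p[:, ai[1], aj[0]] += half * theta
    return p


def _emission(error_rate: float) -> np.ndarray:
    e = error_rate
    return np.array(
        [[1 - e, e / 2, e / 2], [e / 2, 1 - e, e / 2], [e / 2, e / 2, 1 - e]]
    )


def _offspring_table(
    gs: tuple[int, int],
    gd: tuple[int, int],
    theta_m: np.ndarray,
    theta_f: np.ndarray,
    error_rate: float = 0.0,
) -> np.ndarray:
    """log P(observed offspring genotype pair | parents, phases),
    shape (T, 4 phases, 3, 3)."""
    theta_m = np.atleast_1d(theta_m)
    theta_f = np.atleast_1d(theta_f)
    T = max(len(theta_m), len(theta_f))
    out = np.zeros((T, 4, 3, 3))
    E = _emission(error_rate)
    for ph in range(4):
        ps = _transmission(gs[0], gs[1], ph % 2, theta_m)
        pf = _transmission(gd[0], gd[1], ph // 2, theta_f)
        p9 = np.zeros((T, 3, 3))
        for si in range(2):
            for sj in range(2):
                for di in range(2):
                    for dj in range(2):
                        p9[:, si + di, sj + dj] += ps[:, si, sj] * pf[:, di, dj]
        if error_rate > 0:
            p9 = np.einsum("tij,ai,bj->tab", p9, E, E)
        out[:, ph] = np.log(np.maximum(p9, _FLOOR))
    return out


@dataclass
class _FamilyPair:
    gs: tuple[int, int]
    gd: tuple[int, int]
    counts: np.ndarray  # 3x3 offspring genotype-pair counts (non-missing only)

    @property
    def sire_informative(self) -> bool:
        return self.gs == (1, 1)

    @property
    def dam_informative(self) -> bool:
        return self.gd == (1, 1)


def _family_pairs(gm: GenotypeMatrix, i: int, j: int) -> list[_FamilyPair]:
    out = []
    for fam in gm.families():
        gs = (int(gm.calls[fam.sire, i]), int(gm.calls[fam.sire, j]))
        gd = (int(gm.calls[fam.dam, i]), int(gm.calls[fam.dam, j]))
        if min(gs) < 0 or min(gd) < 0:
            continue
        go = gm.calls[fam.offspring][:, [i, j]]
        ok = (go >= 0).all(axis=1)
        if not ok.any():
            continue
        counts = np.zeros((3, 3))
        np.add.at(counts, (go[ok, 0], go[ok, 1]), 1.0)
        out.append(_FamilyPair(gs, gd, counts))
    return out


def _loglik(
    fams: list[_FamilyPair],
    theta_m: np.ndarray,
    theta_f: np.ndarray,
    error_rate: float,
) -> np.ndarray:
    theta_m = np.atleast_1d(theta_m)
    theta_f = np.atleast_1d(theta_f)
    T = max(len(theta_m), len(theta_f))
    total = np.zeros(T)
    for fp in fams:
        tab = _offspring_table(fp.gs, fp.gd, theta_m, theta_f, error_rate)
        ll_ph = np.einsum("tpab,ab->tp", tab, fp.counts)
        total += logsumexp(ll_ph, axis=1) - np.log(4.0)
    return total


@dataclass
class TwoPointEstimate:
    marker_i: str
    marker_j: str
    theta_male: float
    theta_female: float
    theta_pooled: float
    lod: float
    n_informative_male: int
    n_informative_female: int
    flags: list[str] = field(default_factory=list)


def _maximise(objective, tol: float = 1e-6) -> tuple[float, float]:
    """Maximise a log-likelihood over theta in [0, 0.5]: coarse grid, then
    bounded golden-section refinement around the grid optimum."""
    grid = np.linspace(0.0, 0.5, 51)
    vals = objective(grid)
    k = int(np.argmax(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda t: -float(objective(np.array([t]))[0]),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": tol},
    )
    best_t, best_v = float(res.x), -float(res.fun)
    if vals[k] > best_v:  # guard: keep the grid point if refinement regressed
        best_t, best_v = float(grid[k]), float(vals[k])
    return best_t, best_v


def two_point_estimate(
    gm: GenotypeMatrix,
    marker_i: str,
    marker_j: str,
    error_rate: float = 0.0,
    tol: float = 1e-6,
) -> TwoPointEstimate:
    """Maximum-likelihood two-point estimate for one marker pair.

    Pooled theta maximises the phase-marginal likelihood over all families
    with both parents genotyped; the LOD is log10 L(theta_hat) - log10 L(0.5)
    for the pooled likelihood.  Sex-specific thetas restrict to families
    whose that-sex parent is doubly heterozygous.
    """
    i, j = gm.marker_index([marker_i, marker_j])
    fams = _family_pairs(gm, int(i), int(j))
    flags = []

    informative = [fp for fp in fams if fp.sire_informative or fp.dam_informative]
    half = np.array([0.5])
    if informative:
        t_hat, ll_hat = _maximise(
            lambda t: _loglik(informative, t, t, error_rate), tol
        )
        ll_half = float(_loglik(informative, half, half, error_rate)[0])
        lod = max((ll_hat - ll_half) / LN10, 0.0)
    else:
        t_hat, lod = float("nan"), 0.0
        flags.append("no_informative_meioses")

    # joint (theta_m, theta_f) by coordinate ascent from the pooled optimum:
    # in both-doubly-het families the transmissions are entangled, so the
    # other sex's theta must be held at its estimate, not at 0.5
    male_fams = [fp for fp in fams if fp.sire_informative]
    female_fams = [fp for fp in fams if fp.dam_informative]
    t_m = t_f = t_hat if np.isfinite(t_hat) else 0.5
    if male_fams or female_fams:
        for _ in range(3):
            prev = (t_m, t_f)
            if male_fams:
                t_m = _maximise(
                    lambda t: _loglik(informative, t, np.full_like(t, t_f), error_rate),
                    tol,
                )[0]
            if female_fams:
                t_f = _maximise(
                    lambda t: _loglik(informative, np.full_like(t, t_m), t, error_rate),
                    tol,
                )[0]
            if abs(t_m - prev[0]) < tol and abs(t_f - prev[1]) < tol:
                break
    return TwoPointEstimate(
        marker_i=marker_i,
        marker_j=marker_j,
        theta_male=t_m if male_fams else float("nan"),
        theta_female=t_f if female_fams else float("nan"),
        theta_pooled=t_hat,
        lod=lod,
        n_informative_male=int(sum(fp.counts.sum() for fp in male_fams)),
        n_informative_female=int(sum(fp.counts.sum() for fp in female_fams)),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# batch pairwise LOD (grid-resolution screening for clustering/ordering)
# ---------------------------------------------------------------------------


@dataclass
class PairwiseLOD:
    marker_ids: list[str]
    lod: np.ndarray    # square symmetric, float32
    theta: np.ndarray  # pooled theta at the grid argmax

    def index_of(self, ids) -> np.ndarray:
        lookup = {m: k for k, m in enumerate(self.marker_ids)}
        return np.array([lookup[m] for m in ids], dtype=np.intp)

    def submatrix(self, ids) -> tuple[np.ndarray, np.ndarray]:
        idx = self.index_of(ids)
        return self.lod[np.ix_(idx, idx)], self.theta[np.ix_(idx, idx)]


def pairwise_lod(
    gm: GenotypeMatrix,
    error_rate: float = 0.005,
    theta_grid: np.ndarray = DEFAULT_THETA_GRID,
    verbose: bool = False,
) -> PairwiseLOD:
    """All-pairs pooled-theta LOD screen.

    Evaluates the same phase-marginal likelihood as
    :func:`two_point_estimate` on a fixed theta grid, vectorised over
    marker pairs by grouping (pair, family) combinations into parental
    mating-type classes.  Only theta-dependent families (a doubly-het
    parent) contribute — theta-free terms cancel in the LOD.
    """
    grid = np.asarray(theta_grid, dtype=float).copy()
    if not (np.isclose(grid[0], 0.0) and np.isclose(grid[-1], 0.5)):
        raise ValueError("theta_grid must span [0, 0.5]")
    grid[0], grid[-1] = 0.0, 0.5
    M = gm.n_markers
    iu, ju = np.triu_indices(M, k=1)
    n_pairs = len(iu)
    LL = np.zeros((n_pairs, len(grid)), dtype=np.float32)

    # per-class log tables, built lazily: class code packs (gs_i,gs_j,gd_i,gd_j)
    tables: dict[int, np.ndarray] = {}

    def class_table(code: int) -> np.ndarray:
        tab = tables.get(code)
        if tab is None:
            gd_j = code % 3
            gd_i = code // 3 % 3
            gs_j = code // 9 % 3
            gs_i = code // 27
            t = _offspring_table((gs_i, gs_j), (gd_i, gd_j), grid, grid, error_rate)
            tab = t.reshape(len(grid), 4, 9).transpose(2, 0, 1).reshape(9, -1)
            tables[code] = tab.astype(np.float64)
        return tab

    for fam in gm.families():
        gs, gd = gm.calls[fam.sire], gm.calls[fam.dam]
        valid = (gs >= 0) & (gd >= 0)
        sh, dh = (gs == 1) & valid, (gd == 1) & valid
        dep = (valid[iu] & valid[ju]) & ((sh[iu] & sh[ju]) | (dh[iu] & dh[ju]))
        idx = np.flatnonzero(dep)
        if len(idx) == 0:
            continue
        pi, pj = iu[idx], ju[idx]
        code = ((gs[pi].astype(np.int32) * 3 + gs[pj]) * 3 + gd[pi]) * 3 + gd[pj]

        go = gm.calls[fam.offspring]
        gi, gj = go[:, pi], go[:, pj]  # (n_off, n_idx)
        ok = (gi >= 0) & (gj >= 0)
        cat = np.where(ok, gi * 3 + gj, 9).astype(np.int8)
        counts = np.zeros((9, len(idx)), dtype=np.float64)
        for c in range(9):
            counts[c] = (cat == c).sum(axis=0)

        order = np.argsort(code, kind="stable")
        sorted_code = code[order]
        bounds = np.flatnonzero(np.diff(sorted_code)) + 1
        starts = np.concatenate([[0], bounds])
        ends = np.concatenate([bounds, [len(order)]])
        for a, b in zip(starts, ends):
            sel = order[a:b]
            tab = class_table(int(sorted_code[a]))  # (9, T*4)
            ll = counts[:, sel].T @ tab  # (k, T*4)
            ll = logsumexp(ll.reshape(len(sel), len(grid), 4), axis=2) - np.log(4.0)
            LL[idx[sel]] += ll.astype(np.float32)

    lod_flat = (LL.max(axis=1) - LL[:, -1]) / LN10
    np.maximum(lod_flat, 0.0, out=lod_flat)
    theta_flat = grid[LL.argmax(axis=1)].astype(np.float32)
    lod = np.zeros((M, M), dtype=np.float32)
    lod[iu, ju] = lod_flat
    lod += lod.T
    theta = np.full((M, M), 0.5, dtype=np.float32)
    theta[iu, ju] = theta_flat
    theta = np.minimum(theta, theta.T)
    np.fill_diagonal(theta, 0.0)
    return PairwiseLOD(list(gm.markers.index), lod, theta)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def cluster_groups(pl: PairwiseLOD, lod_threshold: float) -> list[list[str]]:
    """Single-linkage transitive closure at the given LOD threshold; groups
    sorted by size descending (every marker appears, singletons included)."""
    adj = csr_matrix(pl.lod >= lod_threshold)
    n, labels = connected_components(adj, directed=False)
    groups: dict[int, list[str]] = {}
    for mid, lab in zip(pl.marker_ids, labels):
        groups.setdefault(int(lab), []).append(mid)
    return sorted(groups.values(), key=lambda g: (-len(g), g[0]))


def group_count(pl: PairwiseLOD, lod_threshold: float, min_size: int = 2) -> int:
    return sum(1 for g in cluster_groups(pl, lod_threshold) if len(g) >= min_size)


def sweep_thresholds(
    pl: PairwiseLOD, thresholds: np.ndarray, min_size: int = 2
) -> pd.DataFrame:
    """Non-singleton group count at each clustering threshold."""
    return pd.DataFrame(
        {
            "threshold": thresholds,
            "n_groups": [group_count(pl, t, min_size) for t in thresholds],
        }
    )


def plateau_threshold(
    pl: PairwiseLOD,
    thresholds: np.ndarray | None = None,
    min_size: int = 2,
) -> tuple[float, int]:
    """Pick the clustering threshold by the plateau criterion: the widest
    run of consecutive thresholds yielding the same (non-trivial) group
    count.  Returns (representative threshold, group count)."""
    if thresholds is None:
        thresholds = np.arange(1.0, 40.25, 0.5)
    sw = sweep_thresholds(pl, thresholds, min_size)
    counts = sw["n_groups"].to_numpy()
    usable = counts > 1
    best = None  # (width, start, end)
    k = 0
    while k < len(counts):
        j = k
        while j + 1 < len(counts) and counts[j + 1] == counts[k]:
            j += 1
        if usable[k]:
            width = j - k
            if best is None or width > best[0]:
                best = (width, k, j)
        k = j + 1
    if best is None:
        return float(thresholds[0]), int(counts[0])
    _, a, b = best
    mid = (a + b) // 2
    return float(thresholds[mid]), int(counts[mid])


def join_singles(
    pl: PairwiseLOD,
    groups: list[list[str]],
    unassigned: list[str],
    lod_limit: float,
    margin: float = 1.0,
) -> tuple[list[list[str]], list[str]]:
    """Assign leftover single markers to existing groups.

    A marker joins the group holding its best-LOD partner if that LOD is
    >= lod_limit and exceeds the best LOD to any other group by >= margin.
    """
    groups = [list(g) for g in groups]
    idx_groups = [pl.index_of(g) for g in groups]
    still = []
    for m in unassigned:
        mi = pl.index_of([m])[0]
        best = sorted(
            ((float(pl.lod[mi, gi].max()), k) for k, gi in enumerate(idx_groups)),
            reverse=True,
        )
        if best and best[0][0] >= lod_limit and (
            len(best) == 1 or best[0][0] - best[1][0] >= margin
        ):
            groups[best[0][1]].append(m)
        else:
            still.append(m)
    return groups, still


# ---------------------------------------------------------------------------
# ordering
# ---------------------------------------------------------------------------


def _path_length(dist: np.ndarray, order: np.ndarray) -> float:
    return float(dist[order[:-1], order[1:]].sum())


def _greedy_path(dist: np.ndarray, start: int) -> np.ndarray:
    n = len(dist)
    unvisited = np.ones(n, dtype=bool)
    order = np.empty(n, dtype=np.intp)
    order[0] = start
    unvisited[start] = False
    for k in range(1, n):
        row = np.where(unvisited, dist[order[k - 1]], np.inf)
        order[k] = int(np.argmin(row))
        unvisited[order[k]] = False
    return order


def _two_opt(dist: np.ndarray, order: np.ndarray, max_passes: int = 80) -> np.ndarray:
    """Best-improvement 2-opt for an open path (segment reversals), applying
    non-overlapping improving moves per pass."""
    n = len(order)
    if n < 3:
        return order
    d = np.zeros((n + 1, n + 1))
    d[:n, :n] = dist
    VIRT = n  # virtual endpoint with zero-cost edges
    for _ in range(max_passes):
        o = np.concatenate([[VIRT], order, [VIRT]])
        P = o[1:-1]
        prev, nxt = o[:-2], o[2:]
        delta = (
            d[prev[:, None], P[None, :]]
            + d[P[:, None], nxt[None, :]]
            - d[prev, P][:, None]
            - d[P, nxt][None, :]
        )
        a_idx, b_idx = np.triu_indices(n, k=1)
        vals = delta[a_idx, b_idx]
        improving = np.flatnonzero(vals < -1e-10)
        if len(improving) == 0:
            break
        taken = np.zeros(n, dtype=bool)
        for q in improving[np.argsort(vals[improving])]:
            a, b = int(a_idx[q]), int(b_idx[q])
            if taken[a : b + 1].any():
                continue
            order[a : b + 1] = order[a : b + 1][::-1]
            taken[a : b + 1] = True
    return order


def _reinsertion(dist: np.ndarray, order: np.ndarray, max_passes: int = 40) -> np.ndarray:
    """Single-marker remove-and-reinsert passes (best position per marker)."""
    n = len(order)
    if n < 3:
        return order
    d = np.zeros((n + 1, n + 1))
    d[:n, :n] = dist
    VIRT = n
    for _ in range(max_passes):
        improved = False
        for k in range(n):
            o = np.concatenate([[VIRT], order, [VIRT]])
            m = order[k]
            gain = d[o[k], m] + d[m, o[k + 2]] - d[o[k], o[k + 2]]
            rest = np.concatenate([order[:k], order[k + 1 :]])
            ro = np.concatenate([[VIRT], rest, [VIRT]])
            cost = d[ro[:-1], m] + d[m, ro[1:]] - d[ro[:-1], ro[1:]]
            pos = int(np.argmin(cost))
            if cost[pos] < gain - 1e-10:
                order = np.concatenate([rest[:pos], [m], rest[pos:]])
                improved = True
        if not improved:
            break
    return order


def order_markers(
    marker_ids: list[str],
    dist: np.ndarray,
    n_restarts: int = 10,
    seed: int = 0,
) -> tuple[list[str], list[float]]:
    """Order a linkage group by minimising total map length.

    Greedy nearest-neighbour construction from ``n_restarts`` random start
    markers, each refined by 2-opt and single-marker reinsertion; returns
    the best order and the per-restart final lengths (for consistency
    checks).  Orientation is normalised so the lexicographically smallest
    marker id sits in the first half.
    """
    n = len(marker_ids)
    if n == 1:
        return list(marker_ids), [0.0]
    rng = np.random.default_rng(seed)
    starts = list(rng.choice(n, size=min(n_restarts, n), replace=False))
    best_order, lengths = None, []
    for s in starts:
        order = _greedy_path(dist, int(s))
        order = _two_opt(dist, order)
        order = _reinsertion(dist, order)
        order = _two_opt(dist, order)
        ln = _path_length(dist, order)
        lengths.append(ln)
        if best_order is None or ln < _path_length(dist, best_order) - 1e-12:
            best_order = order
    ids = [marker_ids[k] for k in best_order]
    anchor = ids.index(min(ids))
    if anchor >= (n + 1) // 2:
        ids = ids[::-1]
    return ids, lengths


# ---------------------------------------------------------------------------
# residual genotyping-error rate from single-locus family data
# ---------------------------------------------------------------------------


def _mendel_probs() -> np.ndarray:
    """P(true offspring genotype | parental genotypes), shape (3, 3, 3)."""
    alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    p = np.zeros((3, 3, 3))
    for gs in range(3):
        for gd in range(3):
            for a in alleles[gs]:
                for b in alleles[gd]:
                    p[gs, gd, a + b] += 0.25
    return p


_MENDEL = _mendel_probs()


def estimate_error_rate(
    gm: GenotypeMatrix, eps_grid: np.ndarray | None = None
) -> float:
    """Residual per-call genotyping-error rate by single-locus ML.

    For every (family, marker) cell the offspring genotype counts are
    scored against the Mendelian transmission model under a symmetric
    flip-error emission, marginalising over single parent-call mistypes.
    Pooling every marker and trio makes this far sharper than profiling
    the error rate within two-point likelihoods, where per-pair theta
    absorbs most of the signal.
    """
    if eps_grid is None:
        eps_grid = np.arange(0.0, 0.01001, 0.00025)
    n_eps = len(eps_grid)
    # emission-mixed offspring distribution per (eps, true parent class)
    p_obs = np.empty((n_eps, 3, 3, 3))
    for k, e in enumerate(eps_grid):
        E = _emission(float(e))
        p_obs[k] = np.einsum("ot,sdt->sdo", E, _MENDEL)
    log_p = np.log(np.maximum(p_obs, _FLOOR))

    total = np.zeros(n_eps)
    with np.errstate(divide="ignore"):
        log_w1 = np.where(eps_grid > 0, np.log(eps_grid / 2) - np.log1p(-eps_grid), -np.inf)
    for fam in gm.families():
        gs, gd = gm.calls[fam.sire], gm.calls[fam.dam]
        go = gm.calls[fam.offspring]
        counts = np.stack([(go == g).sum(axis=0) for g in range(3)])  # (3, M)
        valid = (gs >= 0) & (gd >= 0)
        for c in range(9):
            a, b = c // 3, c % 3
            idx = np.flatnonzero(valid & (gs == a) & (gd == b))
            if len(idx) == 0:
                continue
            sub = counts[:, idx]  # (3, k)
            cands = [(a, b, 0.0)] + [
                (x, b, 1.0) for x in range(3) if x != a
            ] + [(a, y, 1.0) for y in range(3) if y != b]
            ll = np.stack(
                [
                    np.einsum("eo,ok->ek", log_p[:, x, y], sub)
                    + (log_w1[:, None] if w else 0.0)
                    for x, y, w in cands
                ]
            )  # (5, n_eps, k)
            total += logsumexp(ll, axis=0).sum(axis=1)
    return float(eps_grid[int(np.argmax(total))])


# ---------------------------------------------------------------------------
# fast adjacent-pair estimation with profiled genotyping-error rate
# ---------------------------------------------------------------------------

#: fine theta grid for adjacent-pair estimation (0.001 resolution near 0)
FINE_THETA_GRID = np.concatenate(
    [np.arange(0.0, 0.05, 0.001), np.arange(0.05, 0.5001, 0.005)]
)
#: candidate residual per-call error rates for likelihood profiling
EPSILON_GRID = np.array(
    [0.0, 0.0005, 0.001, 0.0015, 0.002, 0.003, 0.004, 0.005, 0.0075, 0.01]
)


class _AdjacentEstimator:
    """Shared-table likelihood evaluator for a list of marker pairs.

    Family contributions are grouped by parental mating-type class so the
    per-class (theta x phase) log tables are built once per (class,
    epsilon, mode) and reused across pairs.
    """

    def __init__(self, gm: GenotypeMatrix, pairs: list[tuple[int, int]],
                 theta_grid: np.ndarray = FINE_THETA_GRID):
        self.grid = theta_grid
        self.half = np.full_like(theta_grid, 0.5)
        self.n_pairs = len(pairs)
        self._tables: dict[tuple[int, float, str], np.ndarray] = {}
        # per family: class code + offspring counts for every pair
        self.fam_data = []
        pi = np.array([p[0] for p in pairs], dtype=np.intp)
        pj = np.array([p[1] for p in pairs], dtype=np.intp)
        for fam in gm.families():
            gs, gd = gm.calls[fam.sire], gm.calls[fam.dam]
            valid = (gs >= 0) & (gd >= 0)
            ok_pair = valid[pi] & valid[pj]
            code = np.where(
                ok_pair,
                ((gs[pi].astype(np.int32) * 3 + gs[pj]) * 3 + gd[pi]) * 3 + gd[pj],
                -1,
            )
            go = gm.calls[fam.offspring]
            gi, gj = go[:, pi], go[:, pj]
            oko = (gi >= 0) & (gj >= 0)
            cat = np.where(oko, gi * 3 + gj, 9)
            counts = np.zeros((9, self.n_pairs))
            for c in range(9):
                counts[c] = (cat == c).sum(axis=0)
            self.fam_data.append((code, counts))

    def _table(self, code: int, eps: float, mode: str, other_idx: int = -1) -> np.ndarray:
        """(9, T*4) log table for one mating-type class.

        mode 'pooled': theta_m = theta_f sweep the grid.  mode 'male'
        ('female'): that sex sweeps the grid while the other parent's
        theta is held at ``grid[other_idx]`` — the other parent's linkage
        matters in both-doubly-het families.
        """
        key = (code, float(eps), mode, other_idx)
        tab = self._tables.get(key)
        if tab is None:
            gd_j = code % 3
            gd_i = code // 3 % 3
            gs_j = code // 9 % 3
            gs_i = code // 27
            other = (
                self.half
                if other_idx < 0
                else np.full_like(self.grid, self.grid[other_idx])
            )
            tm = other if mode == "female" else self.grid
            tf = other if mode == "male" else self.grid
            t = _offspring_table((gs_i, gs_j), (gd_i, gd_j), tm, tf, eps)
            tab = t.reshape(len(self.grid), 4, 9).transpose(2, 0, 1).reshape(9, -1)
            self._tables[key] = tab
        return tab

    @staticmethod
    def _candidate_codes(code: np.ndarray) -> np.ndarray:
        """(n_pairs, 9): the observed parental class plus the 8 classes one
        parent-call mistype away (a mistyped founder call otherwise turns a
        whole family into spurious recombinants)."""
        cands = [code]
        for k in range(4):
            digit = code // 3**k % 3
            for shift in (1, 2):
                cands.append(code + ((digit + shift) % 3 - digit) * 3**k)
        return np.stack(cands, axis=1)

    def loglik(
        self, eps: float, mode: str = "pooled", other_idx: np.ndarray | None = None
    ) -> np.ndarray:
        """(n_pairs, T) summed log-likelihood over informative families.

        mode 'pooled': theta_m = theta_f over families with any doubly-het
        parent; 'male'/'female': theta for that sex over families whose
        that-sex parent is doubly het, with the other parent's theta fixed
        per pair at ``grid[other_idx]``.

        Parental genotypes are not taken at face value: the family
        likelihood marginalises over the observed class and its Hamming-1
        mistype neighbours, weighted by the genotype-emission error rate.
        """
        T = len(self.grid)
        LL = np.zeros((self.n_pairs, T))
        any_inf = np.zeros(self.n_pairs, dtype=bool)
        if other_idx is None:
            other_idx = np.full(self.n_pairs, -1, dtype=np.int64)
        n_cand = 9 if eps > 0 else 1
        logw = (
            np.array([0.0] + [np.log(max(eps, _FLOOR) / 2) - np.log1p(-eps)] * 8)
            if eps > 0
            else np.array([0.0])
        )
        for code, counts in self.fam_data:
            cands = self._candidate_codes(code)[:, :n_cand]
            # informativeness is judged on the OBSERVED parental class only;
            # mistype candidates may explain a family's data but must never
            # recruit an uninformative family into the theta estimate
            gd_dh = (code // 3 % 3 == 1) & (code % 3 == 1)
            gs_dh = (code // 27 == 1) & (code // 9 % 3 == 1)
            valid = code >= 0
            if mode == "male":
                use = valid & gs_dh
                oidx = np.where(gd_dh, other_idx, -1)
            elif mode == "female":
                use = valid & gd_dh
                oidx = np.where(gs_dh, other_idx, -1)
            else:
                use = valid & (gs_dh | gd_dh)
                oidx = np.full(self.n_pairs, -1, dtype=np.int64)
            idx = np.flatnonzero(use)
            if len(idx) == 0:
                continue
            any_inf[idx] = True
            ll_cand = np.empty((len(idx), n_cand, T, 4))
            for q in range(n_cand):
                cq = cands[idx, q]
                group_key = cq * (len(self.grid) + 1) + (oidx[idx] + 1)
                order = np.argsort(group_key, kind="stable")
                gk = group_key[order]
                bounds = np.flatnonzero(np.diff(gk)) + 1
                for a, b in zip(
                    np.concatenate([[0], bounds]),
                    np.concatenate([bounds, [len(gk)]]),
                ):
                    sel = order[a:b]
                    tab = self._table(int(cq[sel[0]]), eps, mode, int(oidx[idx[sel[0]]]))
                    ll = counts[:, idx[sel]].T @ tab
                    ll_cand[sel, q] = ll.reshape(len(sel), T, 4)
            ll_cand += logw[:n_cand, None, None]
            LL[idx] += logsumexp(
                ll_cand.transpose(0, 2, 1, 3).reshape(len(idx), T, n_cand * 4), axis=2
            ) - np.log(4.0)
        LL[~any_inf] = np.nan
        return LL

    @staticmethod
    def _argmax(LL: np.ndarray) -> np.ndarray:
        """Grid argmax per pair; -1 where no informative family."""
        safe = np.where(np.isnan(LL), -np.inf, LL)
        return np.where(np.isnan(LL[:, 0]), -1, safe.argmax(axis=1))

    def _subset(self, idx: np.ndarray) -> "_AdjacentEstimator":
        sub = object.__new__(_AdjacentEstimator)
        sub.grid = self.grid
        sub.half = self.half
        sub.n_pairs = len(idx)
        sub._tables = self._tables  # shared cache
        sub.fam_data = [(code[idx], counts[:, idx]) for code, counts in self.fam_data]
        return sub

    def profile_epsilon(
        self, eps_grid: np.ndarray = EPSILON_GRID, max_pairs: int = 150
    ) -> float:
        """Global residual error rate by profile likelihood: for each
        candidate epsilon, sum each pair's theta-maximised pooled
        log-likelihood; return the argmax.  A deterministic subsample of
        pairs keeps the sweep cheap on large chains."""
        est = self
        if self.n_pairs > max_pairs:
            est = self._subset(
                np.linspace(0, self.n_pairs - 1, max_pairs).astype(np.intp)
            )
        scores = []
        for eps in eps_grid:
            LL = est.loglik(float(eps), "pooled")
            scores.append(np.nansum(np.nanmax(LL, axis=1)))
        return float(eps_grid[int(np.argmax(scores))])

    def estimate(self, eps: float, n_iter: int = 2) -> pd.DataFrame:
        """Per-pair pooled/male/female theta-hat and pooled LOD.

        The sex-specific pair (theta_m, theta_f) is maximised jointly by
        coordinate ascent from the pooled estimate: in both-doubly-het
        families the two transmissions are entangled, and holding the
        other sex at 0.5 would bias both estimates towards zero linkage.
        """
        out = {}
        LLp = self.loglik(eps, "pooled")
        kp = self._argmax(LLp)
        theta_pooled = np.where(kp >= 0, self.grid[np.maximum(kp, 0)], np.nan)
        out["theta_pooled"] = theta_pooled
        lod = (np.nanmax(LLp, axis=1) - LLp[:, -1]) / LN10
        out["lod"] = np.where(np.isnan(theta_pooled), 0.0, np.maximum(lod, 0.0))

        km = np.maximum(kp, 0).astype(np.int64)
        kf = km.copy()
        male_has_info = female_has_info = None
        for _ in range(n_iter):
            km_new = self._argmax(self.loglik(eps, "male", other_idx=kf))
            if male_has_info is None:
                male_has_info = km_new >= 0
            km_prev = km
            km = np.where(km_new >= 0, km_new, km)
            kf_new = self._argmax(self.loglik(eps, "female", other_idx=km))
            if female_has_info is None:
                female_has_info = kf_new >= 0
            kf_prev = kf
            kf = np.where(kf_new >= 0, kf_new, kf)
            if np.array_equal(km, km_prev) and np.array_equal(kf, kf_prev):
                break
        out["theta_male"] = np.where(male_has_info, self.grid[km], np.nan)
        out["theta_female"] = np.where(female_has_info, self.grid[kf], np.nan)
        return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# sex-specific distances and the map orchestrator
# ---------------------------------------------------------------------------


def sex_specific_distances(
    gm: GenotypeMatrix,
    ordered_ids: list[str],
    error_rate: float | str = "profile",
    max_increment_cM: float = 50.0,
    map_function: str = "haldane",
    estimator: _AdjacentEstimator | None = None,
) -> pd.DataFrame:
    """Re-estimate adjacent-pair theta per sex on a fixed order and turn it
    into cumulative cM tracks.

    ``error_rate='profile'`` estimates the residual genotyping-error rate
    by profile likelihood over the adjacent pairs; a float fixes it.
    Pairs with no informative meioses for a sex contribute a 0-cM
    increment and a flag; theta >= 0.5 caps the increment at
    ``max_increment_cM`` with a flag.
    """
    mapf = MAP_FUNCTIONS[map_function]
    idx = gm.marker_index(ordered_ids)
    pairs = list(zip(idx[:-1], idx[1:]))
    if estimator is None:
        estimator = _AdjacentEstimator(gm, pairs)
    eps = estimate_error_rate(gm) if error_rate == "profile" else float(error_rate)
    est = estimator.estimate(eps)

    male, female, flags = [0.0], [0.0], [""]
    for k in range(len(pairs)):
        row_flags = []
        incs = {}
        for sex, theta in (("M", est["theta_male"][k]), ("F", est["theta_female"][k])):
            if np.isnan(theta):
                incs[sex] = 0.0
                row_flags.append(f"no_{sex}_info")
            else:
                d = float(mapf(theta))
                if not np.isfinite(d) or d > max_increment_cM:
                    d = max_increment_cM
                    row_flags.append(f"capped_{sex}")
                incs[sex] = d
        male.append(male[-1] + incs["M"])
        female.append(female[-1] + incs["F"])
        flags.append(",".join(row_flags))
    return pd.DataFrame(
        {
            "order_index": np.arange(len(ordered_ids)),
            "male_cM": male,
            "female_cM": female,
            "flags": flags,
        },
        index=pd.Index(ordered_ids, name="marker_id"),
    )


def marey_tracks(
    gm: GenotypeMatrix,
    ordered_by_chrom: dict[str, list[str]],
    error_rate: float | str = "profile",
    max_increment_cM: float = 50.0,
    map_function: str = "haldane",
) -> dict[str, pd.DataFrame]:
    """Per-sex genetic positions re-estimated along given marker chains
    (one per chromosome, in physical order).

    Used to build Marey maps from the concordant marker subset: distances
    are re-estimated between consecutive chain members, so map-length
    artifacts contributed by excluded (discordant) markers do not leak
    into the genetic axis.  The error rate is profiled once over all
    chains when ``error_rate='profile'``.
    """
    chains = {c: ids for c, ids in ordered_by_chrom.items() if len(ids) >= 2}
    if error_rate == "profile" and chains:
        eps = estimate_error_rate(gm)
    else:
        eps = error_rate if error_rate != "profile" else 0.0
    return {
        chrom: sex_specific_distances(
            gm, ids, error_rate=eps,
            max_increment_cM=max_increment_cM, map_function=map_function,
        )
        for chrom, ids in chains.items()
    }


@dataclass
class MapResult:
    genetic_map: pd.DataFrame          # marker_id -> linkage_group, order_index, male_cM, female_cM
    lod_threshold: float
    n_groups: int
    unassigned: list[str]
    restart_lengths: dict[str, list[float]] = field(default_factory=dict)
    epsilon: float = 0.0               # residual error rate used for distances


def build_genetic_map(
    gm: GenotypeMatrix,
    lod_threshold: float | str = "auto",
    error_rate: float | str = "profile",
    lod_error_rate: float = 0.005,
    n_restarts: int = 10,
    seed: int = 0,
    join_lod_limit: float | None = None,
    max_increment_cM: float = 50.0,
    map_function: str = "haldane",
    pl: PairwiseLOD | None = None,
    max_group_cap_cM: float = 50.0,
) -> MapResult:
    """Full linkage-mapping stage: cluster, join singles, order, emit
    sex-specific cM positions.  ``lod_threshold='auto'`` picks the plateau
    threshold; ``error_rate='profile'`` estimates the residual genotyping
    error rate for the distance stage by profile likelihood, while the LOD
    screen uses ``lod_error_rate``."""
    if pl is None:
        pl = pairwise_lod(gm, error_rate=lod_error_rate)
    if lod_threshold == "auto":
        thr, _ = plateau_threshold(pl)
    else:
        thr = float(lod_threshold)
    groups = cluster_groups(pl, thr)
    big = [g for g in groups if len(g) >= 2]
    singles = [g[0] for g in groups if len(g) == 1]
    if join_lod_limit is None:
        join_lod_limit = thr / 2.0
    big, unassigned = join_singles(pl, big, singles, join_lod_limit)
    big = sorted(big, key=lambda g: (-len(g), g[0]))

    # within-group theta on a finer grid than the clustering screen:
    # neighbour spacings are far below the screen's resolution
    fine_grid = np.concatenate(
        [np.arange(0.0, 0.05, 0.0025), np.arange(0.05, 0.5001, 0.01)]
    )
    orders = {}
    restart_lengths = {}
    for k, group in enumerate(big, start=1):
        label = f"LG{k}"
        sub = pairwise_lod(
            gm.subset(marker_ids=group),
            error_rate=lod_error_rate,
            theta_grid=fine_grid,
        )
        _, sub_theta = sub.submatrix(group)
        dist = np.asarray(haldane_cM(np.minimum(sub_theta, 0.49)), dtype=float)
        np.clip(dist, 0.0, max_group_cap_cM, out=dist)
        ordered, lengths = order_markers(group, dist, n_restarts=n_restarts, seed=seed + k)
        orders[label] = ordered
        restart_lengths[label] = lengths

    # estimate the residual error rate once from single-locus family data
    if error_rate == "profile" and orders:
        eps = estimate_error_rate(gm)
    else:
        eps = error_rate if error_rate != "profile" else 0.0

    frames = []
    for label, ordered in orders.items():
        tracks = sex_specific_distances(
            gm, ordered, error_rate=eps,
            max_increment_cM=max_increment_cM, map_function=map_function,
        )
        tracks.insert(0, "linkage_group", label)
        frames.append(tracks)
    gmap = pd.concat(frames) if frames else pd.DataFrame(
        columns=["linkage_group", "order_index", "male_cM", "female_cM", "flags"]
    )
    return MapResult(
        genetic_map=gmap,
        lod_threshold=thr,
        n_groups=len(big),
        unassigned=unassigned,
        restart_lengths=restart_lengths,
        epsilon=eps,
    )
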