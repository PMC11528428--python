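"""Equilibrium-constant estimation from counted molecule positions.

The estimator counts associated and isolated molecules under a proximity
criterion and converts the counts into an equilibrium constant:

2D association (same membrane), um^2 scale:
    Ka = (n_pairs / A) / ((n_free_a / A) * (n_free_b / A))
       = n_pairs * A / (n_free_a * n_free_b)
    (homo-association: both free factors are the same species' monomers)

membrane-cytosol dissociation, molar scale:
    the observation volume is the occupied area times the TIRF
    evanescent depth (100-250 nm), so the free-ligand concentration is
    c = n_free_ligand / (A * depth * N_Avogadro) and
    Kd = c * n_free_receptor / n_pairs.

Complete spatial randomness (CSR) at the measured density inside the
measured pattern is the reference of non-associated partners; the
proximity threshold is chosen where the experimental log K deviates most
from CSR.  Incomplete labeling makes the apparent constant density
dependent, so log K is extrapolated linearly to infinite dilution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.stats import linregress

from .errors import DataError, ParameterError, UndefinedConstantError
from .locio import MoleculeMap
from .pattern import PatternMask

logger = logging.getLogger("smlmeq")

NM_PER_UM = 1000.0
AVOGADRO = 6.02214076e23
GAS_CONSTANT = 8.314462618  # J / (mol K)


def energy_equivalent(delta_log_k: float, temperature_k: float = 298.15) -> float:
    """Free-energy equivalent (J/mol) of a difference in log10 K.

    Follows the field convention of equating -dG/RT with log10 Ka, i.e.
    returns delta * R * T (a difference of 0.3 at 25 C is 743 J/mol).
    """
    return delta_log_k * GAS_CONSTANT * temperature_k


def nnd_distribution(
    points_a: np.ndarray, points_b: np.ndarray | None = None
) -> np.ndarray:
    """First nearest-neighbor distances (nm).

    Homo mode (``points_b`` is None): per-point distance to the nearest
    distinct point of the same set.  Hetero mode: per-a-point distance
    to the nearest b point.
    """
    points_a = np.asarray(points_a, dtype=float)
    if points_b is None:
        if points_a.shape[0] < 2:
            raise ParameterError("homo NND requires >= 2 points")
        dist, _ = cKDTree(points_a).query(points_a, k=2)
        return dist[:, 1]
    points_b = np.asarray(points_b, dtype=float)
    if points_a.shape[0] < 1 or points_b.shape[0] < 1:
        raise ParameterError("hetero NND requires >= 1 point per set")
    dist, _ = cKDTree(points_b).query(points_a, k=1)
    return np.atleast_1d(dist)


def csr_reference(
    molecules: MoleculeMap,
    mask: PatternMask,
    scenario: str = "both_csr",
    seed: int = 0,
) -> MoleculeMap:
    """Randomized reference map at the experimental counts inside a mask.

    ``scenario`` picks which species is redrawn uniformly inside the
    mask's occupied pixels: ``a_csr`` (first species), ``b_csr`` (second),
    or ``both_csr``.  The other species keeps its experimental positions;
    counts are preserved exactly.
    """
    if mask.area_um2 <= 0 or not mask.occupancy.any():
        raise ParameterError("mask has no occupied area")
    labels = molecules.species_labels()
    if scenario not in ("a_csr", "b_csr", "both_csr"):
        raise ParameterError(f"unknown scenario {scenario!r}")
    randomize = set()
    if scenario in ("a_csr", "both_csr"):
        randomize.add(labels[0])
    if scenario in ("b_csr", "both_csr"):
        if scenario == "b_csr" and len(labels) < 2:
            raise ParameterError("b_csr scenario requires two species")
        randomize.add(labels[-1])
    density = len(molecules) / mask.area_um2
    if density > 1e4:
        logger.warning("CSR density %.0f um^-2 exceeds the supported regime", density)
    rng = np.random.default_rng(seed)
    occ_j, occ_i = np.nonzero(mask.occupancy)
    x = molecules.x.copy()
    y = molecules.y.copy()
    for lab in randomize:
        sel = molecules.species == lab
        n = int(sel.sum())
        pick = rng.integers(0, occ_i.size, n)
        x[sel] = mask.origin[0] + (occ_i[pick] + rng.uniform(0, 1, n)) * mask.pixel_nm
        y[sel] = mask.origin[1] + (occ_j[pick] + rng.uniform(0, 1, n)) * mask.pixel_nm
    return MoleculeMap(
        x=x,
        y=y,
        species=molecules.species.copy(),
        count_weight=molecules.count_weight.copy(),
    )


@dataclass
class PairMatching:
    """Exclusive proximity matching: pair index lists plus free molecules."""

    pairs: np.ndarray  # (n_pairs, 2) indices (a_idx, b_idx); homo: both into a
    free_a: np.ndarray
    free_b: np.ndarray | None

    @property
    def n_pairs(self) -> int:
        return self.pairs.shape[0]


def match_pairs(
    points_a: np.ndarray,
    points_b: np.ndarray | None,
    proximity_nm: float,
) -> PairMatching:
    """Greedy exclusive 1:1 matching under a proximity criterion.

    Candidate pairs (cross-species, or distinct within-set pairs in homo
    mode) with distance <= ``proximity_nm`` are accepted in ascending
    distance order; every molecule joins at most one pair.  Distance
    ties break on the lower index pair, so the result is deterministic
    given the input order.
    """
    if proximity_nm <= 0:
        raise ParameterError("proximity_nm must be > 0")
    points_a = np.asarray(points_a, dtype=float)
    homo = points_b is None
    if homo:
        tree = cKDTree(points_a)
        cand = tree.query_pairs(proximity_nm, output_type="ndarray")
        if cand.size:
            d = np.linalg.norm(points_a[cand[:, 0]] - points_a[cand[:, 1]], axis=1)
        else:
            d = np.empty(0)
        n_a = n_b = points_a.shape[0]
    else:
        points_b = np.asarray(points_b, dtype=float)
        n_a, n_b = points_a.shape[0], points_b.shape[0]
        if n_a and n_b:
            mat = cKDTree(points_a).sparse_distance_matrix(
                cKDTree(points_b), proximity_nm, output_type="coo_matrix"
            )
            cand = np.column_stack([mat.row, mat.col])
            d = mat.data
        else:
            cand = np.empty((0, 2), dtype=np.int64)
            d = np.empty(0)
    if cand.shape[0]:
        order = np.lexsort((cand[:, 1], cand[:, 0], d))
        cand = cand[order]
        used_a = np.zeros(n_a, dtype=bool)
        used_b = used_a if homo else np.zeros(n_b, dtype=bool)
        pairs = []
        for i, j in cand:
            if not used_a[i] and not used_b[j]:
                used_a[i] = True
                used_b[j] = True
                pairs.append((i, j))
        pairs = np.array(pairs, dtype=np.int64).reshape(-1, 2)
    else:
        pairs = np.empty((0, 2), dtype=np.int64)
        used_a = np.zeros(n_a, dtype=bool)
        used_b = used_a if homo else np.zeros(n_b, dtype=bool)
    free_a = np.flatnonzero(~used_a)
    free_b = None if homo else np.flatnonzero(~used_b)
    return PairMatching(pairs=pairs, free_a=free_a, free_b=free_b)


@dataclass
class EquilibriumResult:
    """Counts, geometry and the equilibrium constant on its declared scale."""

    n_pairs: int
    n_free_a: int
    n_free_b: int | None
    area_um2: float
    proximity_nm: float
    mode: str  # homo_association | hetero_association | hetero_dissociation
    ka_um2: float | None = None
    kd_molar: float | None = None
    tirf_depth_nm: float | None = None
    csr_log_k: float | None = None

    @property
    def log_k(self) -> float:
        k = self.ka_um2 if self.ka_um2 is not None else self.kd_molar
        return math.log10(k) if k and k > 0 else float("nan")

    @property
    def defined(self) -> bool:
        k = self.ka_um2 if self.ka_um2 is not None else self.kd_molar
        return bool(k and k > 0)


def compute_ka(
    n_pairs: int,
    n_free_a: int,
    n_free_b: int | None,
    area_um2: float,
    proximity_nm: float = float("nan"),
) -> EquilibriumResult:
    """2D association constant Ka = n_pairs * A / (n_free_a * n_free_b), um^2.

    ``n_free_b=None`` selects homo-association, where both free factors
    are the same species' monomer count.  Zero pairs give Ka = 0 with an
    undefined (NaN) log, flagged via ``result.defined``.
    """
    if area_um2 <= 0:
        raise ParameterError("area_um2 must be > 0")
    homo = n_free_b is None
    fb = n_free_a if homo else n_free_b
    if n_free_a <= 0 or fb <= 0:
        raise UndefinedConstantError("no free molecules: Ka undefined")
    ka = n_pairs * area_um2 / (n_free_a * fb)
    return EquilibriumResult(
        n_pairs=int(n_pairs),
        n_free_a=int(n_free_a),
        n_free_b=None if homo else int(n_free_b),
        area_um2=float(area_um2),
        proximity_nm=proximity_nm,
        mode="homo_association" if homo else "hetero_association",
        ka_um2=float(ka),
    )


def compute_kd_molar(
    n_pairs: int,
    n_free_receptor: int,
    n_free_ligand: int,
    area_um2: float,
    tirf_depth_nm: float = 100.0,
    proximity_nm: float = float("nan"),
) -> EquilibriumResult:
    """Molar dissociation constant for a membrane-cytosol equilibrium.

    The cytosolic ligand is confined to the TIRF illumination slab, so
    its concentration is n / (A * depth * N_A) with the volume
    A[um^2] * depth[um] * 1e-15 litres; Kd = c_ligand * n_free_receptor
    / n_pairs.  Kd scales inversely with the chosen depth, which is
    reported alongside.
    """
    if area_um2 <= 0:
        raise ParameterError("area_um2 must be > 0")
    if tirf_depth_nm <= 0:
        raise ParameterError("tirf_depth_nm must be > 0")
    if n_pairs <= 0:
        raise UndefinedConstantError("no pairs: Kd undefined")
    volume_l = area_um2 * (tirf_depth_nm / NM_PER_UM) * 1e-15
    c_ligand = n_free_ligand / (volume_l * AVOGADRO)
    kd = c_ligand * n_free_receptor / n_pairs
    return EquilibriumResult(
        n_pairs=int(n_pairs),
        n_free_a=int(n_free_receptor),
        n_free_b=int(n_free_ligand),
        area_um2=float(area_um2),
        proximity_nm=proximity_nm,
        mode="hetero_dissociation",
        kd_molar=float(kd),
        tirf_depth_nm=float(tirf_depth_nm),
    )


def molar_concentration(n: int, area_um2: float, tirf_depth_nm: float) -> float:
    """Concentration (M) of n molecules in the TIRF slab over an area."""
    volume_l = area_um2 * (tirf_depth_nm / NM_PER_UM) * 1e-15
    return n / (volume_l * AVOGADRO)


@dataclass
class ThresholdScanPoint:
    proximity_nm: float
    log_k_exp: float
    log_k_csr: float
    csr_sd: float

    @property
    def delta(self) -> float:
        return self.log_k_exp - self.log_k_csr


def _log_ka_at_threshold(pts_a, pts_b, proximity_nm, area_um2):
    m = match_pairs(pts_a, pts_b, proximity_nm)
    n_free_b = None if pts_b is None else m.free_b.size
    try:
        res = compute_ka(m.n_pairs, m.free_a.size, n_free_b, area_um2, proximity_nm)
    except UndefinedConstantError:
        return float("nan")
    return res.log_k


def threshold_scan(
    molecules: MoleculeMap,
    mask: PatternMask,
    thresholds,
    scenario: str = "both_csr",
    n_csr: int = 20,
    seed: int = 0,
) -> tuple[list[ThresholdScanPoint], float]:
    """log K vs proximity threshold, against the CSR reference.

    For every threshold the experimental log Ka and the mean log Ka of
    ``n_csr`` CSR realizations (same counts, same mask, chosen
    ``scenario``) are computed; ``delta = log_k_exp - log_k_csr``.
    Returns the per-threshold records and the threshold maximizing
    delta, the operating point the analysis recommends.
    """
    thresholds = np.asarray(sorted(thresholds), dtype=float)
    if thresholds.size == 0:
        raise ParameterError("need at least one threshold")
    labels = molecules.species_labels()
    homo = len(labels) == 1
    pts_a = molecules.select(labels[0])
    pts_b = None if homo else molecules.select(labels[1])
    area = mask.area_um2
    csr_maps = [
        csr_reference(molecules, mask, scenario, seed=seed + 7919 * r)
        for r in range(n_csr)
    ]
    out = []
    for thr in thresholds:
        log_exp = _log_ka_at_threshold(pts_a, pts_b, thr, area)
        csr_logs = []
        for cm in csr_maps:
            ca = cm.select(labels[0])
            cb = None if homo else cm.select(labels[1])
            csr_logs.append(_log_ka_at_threshold(ca, cb, thr, area))
        csr_logs = np.asarray(csr_logs)
        good = np.isfinite(csr_logs)
        mean_csr = float(csr_logs[good].mean()) if good.any() else float("nan")
        sd_csr = float(csr_logs[good].std()) if good.any() else float("nan")
        out.append(
            ThresholdScanPoint(
                proximity_nm=float(thr),
                log_k_exp=log_exp,
                log_k_csr=mean_csr,
                csr_sd=sd_csr,
            )
        )
    deltas = np.array([p.delta for p in out])
    finite = np.isfinite(deltas)
    best = float(thresholds[finite][np.argmax(deltas[finite])]) if finite.any() else float("nan")
    return out, best


@dataclass
class DilutionSeries:
    """log K vs density (or concentration) with its linear fit."""

    points: list  # (abscissa, log_k)
    slope: float
    intercept: float
    intercept_se: float


def extrapolate_to_infinite_dilution(points) -> DilutionSeries:
    """OLS of log K on density/concentration; the intercept is log K_limit.

    Incomplete labeling biases the apparent constant in proportion to
    the detected density, so the zero-density intercept (with its
    standard error) is the corrected estimate.
    """
    pts = [(float(x), float(y)) for x, y in points]
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    if np.unique(xs).size < 2:
        raise ParameterError("need >= 2 distinct abscissae for the dilution fit")
    fit = linregress(xs, ys)
    return DilutionSeries(
        points=pts,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        intercept_se=float(fit.intercept_stderr),
    )


@dataclass
class ClusterSizeDistribution:
    """Counts n_j of clusters with j members (index 0 <-> j=1)."""

    n_j: np.ndarray
    area_um2: float
    labels: np.ndarray | None = None  # per-point cluster id

    @property
    def j_max(self) -> int:
        return int(self.n_j.size)

    @property
    def total_molecules(self) -> int:
        return int(np.sum(self.n_j * np.arange(1, self.n_j.size + 1)))


def cluster_molecules(
    points: np.ndarray, linkage_nm: float, area_um2: float
) -> ClusterSizeDistribution:
    """Single-linkage clusters under a distance cutoff, tabulated by size."""
    if linkage_nm <= 0:
        raise ParameterError("linkage_nm must be > 0")
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n == 0:
        raise DataError("no points to cluster")
    tree = cKDTree(points)
    pairs = tree.query_pairs(linkage_nm, output_type="ndarray")
    graph = sparse.coo_matrix(
        (np.ones(pairs.shape[0]), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(graph, directed=False)
    sizes = np.bincount(labels)
    n_j = np.bincount(sizes)[1:]  # index 0 <-> clusters of 1
    return ClusterSizeDistribution(n_j=n_j, area_um2=float(area_um2), labels=labels)


def stepwise_constants(dist: ClusterSizeDistribution) -> list[tuple[int, float]]:
    """Stepwise cluster-growth constants Ka_j = n_j * A / (n_{j-1} * n_1), um^2.

    Ka_j is the association constant for adding one monomer to a cluster
    of j-1 proteins.  Steps with an empty predecessor class are skipped
    (logged).  Returns (j, Ka_j) for j = 2..j_max.
    """
    n_j = dist.n_j
    if n_j.size < 1 or n_j[0] <= 0:
        raise DataError("stepwise constants require a non-empty monomer class")
    n1 = float(n_j[0])
    out = []
    for j in range(2, n_j.size + 1):
        prev, cur = float(n_j[j - 2]), float(n_j[j - 1])
        if prev <= 0 or cur <= 0:
            logger.info("stepwise constant skipped at j=%d (empty class)", j)
            continue
        out.append((j, cur * dist.area_um2 / (prev * n1)))
    return out


def poisson_reference_constants(ka_2: float, js) -> list[tuple[int, float]]:
    """Heuristic 1/j reference curve for the stepwise constants.

    Reconstruction of the simplest Poisson-type association (size-
    independent association, size-proportional dissociation), normalized
    to the measured j=2 step: Ka_ref,j = Ka_2 * 2 / j.  A qualitative
    overlay only; it is not a fitted model.
    """
    return [(int(j), ka_2 * 2.0 / j) for j in js]


@dataclass
class OccupancyTable:
    """Ligand occupancy of receptor clusters by cluster size.

    ``counts[(j, s)]`` is the number of receptor clusters of size j with
    s bound ligands; ``p_bound[j]`` the mean fraction of occupied sites.
    ``inverse_fit`` is the (slope, intercept) of 1/p_bound_j vs j; the
    conversion of that slope into a molar Kd requires the free-ligand
    concentration and is left to the caller as a model-dependent scale.
    """

    counts: dict
    p_bound: dict
    reference_p_bound: dict | None
    inverse_fit: tuple[float, float] | None


def occupancy_analysis(
    receptor_points: np.ndarray,
    receptor_labels: np.ndarray,
    ligand_points: np.ndarray,
    proximity_nm: float,
    randomization: str = "none",
    mask: PatternMask | None = None,
    seed: int = 0,
) -> OccupancyTable:
    """Langmuir-type occupancy of receptor clusters by a ligand species.

    Each ligand is assigned greedily (ascending distance) to at most one
    receptor site within ``proximity_nm``; each site holds at most one
    ligand.  Clusters of size j are then tabulated by their number of
    occupied sites s.  With ``randomization="ligand_csr"`` a reference
    table is computed with the ligand redrawn uniformly inside ``mask``.
    """
    receptor_points = np.asarray(receptor_points, dtype=float)
    ligand_points = np.asarray(ligand_points, dtype=float)
    receptor_labels = np.asarray(receptor_labels)

    def _tabulate(lig_pts):
        m = match_pairs(receptor_points, lig_pts, proximity_nm)
        bound = np.zeros(receptor_points.shape[0], dtype=bool)
        if m.pairs.size:
            bound[m.pairs[:, 0]] = True
        counts: dict = {}
        frac_by_j: dict = {}
        for cid in np.unique(receptor_labels):
            members = receptor_labels == cid
            j = int(members.sum())
            s = int(bound[members].sum())
            counts[(j, s)] = counts.get((j, s), 0) + 1
            frac_by_j.setdefault(j, []).append(s / j)
        p_bound = {j: float(np.mean(v)) for j, v in frac_by_j.items()}
        return counts, p_bound

    counts, p_bound = _tabulate(ligand_points)
    reference = None
    if randomization == "ligand_csr":
        if mask is None:
            raise ParameterError("ligand_csr randomization requires a mask")
        rng = np.random.default_rng(seed)
        occ_j, occ_i = np.nonzero(mask.occupancy)
        n = ligand_points.shape[0]
        pick = rng.integers(0, occ_i.size, n)
        rand = np.column_stack(
            [
                mask.origin[0] + (occ_i[pick] + rng.uniform(0, 1, n)) * mask.pixel_nm,
                mask.origin[1] + (occ_j[pick] + rng.uniform(0, 1, n)) * mask.pixel_nm,
            ]
        )
        _, reference = _tabulate(rand)
    elif randomization != "none":
        raise ParameterError(f"unknown randomization {randomization!r}")
    fit = None
    usable = {j: p for j, p in p_bound.items() if p > 0}
    if len(usable) >= 2:
        js = np.array(sorted(usable))
        inv = np.array([1.0 / usable[j] for j in js])
        res = linregress(js.astype(float), inv)
        fit = (float(res.slope), float(res.intercept))
    return OccupancyTable(
        counts=counts,
        p_bound=p_bound,
        reference_p_bound=reference,
        inverse_fit=fit,
    )
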