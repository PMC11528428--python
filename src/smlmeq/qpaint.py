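"""qPAINT molecular counting from DNA-PAINT localization clusters.

The counting chain: localizations are grouped into spatial clusters;
each cluster's blinking trace yields dark times (gaps between ON
bursts); the qPAINT index QPI = 1 / mean(dark time) is proportional to
the number of docking sites, so the QPI histogram shows peaks at integer
multiples of the single-site QPI.  Fitting the histogram with Gaussians
constrained to those multiples calibrates the unit QPI, and each cluster
is assigned round(QPI / unit) molecules, which are placed by recursive
2-means splitting of the cluster's localization cloud.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import curve_fit
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import DataError, FitError, ParameterError
from .locio import LocalizationTable, MoleculeMap

logger = logging.getLogger("smlmeq")


def cluster_localizations(
    table: LocalizationTable, radius_nm: float, min_locs: int = 10
) -> np.ndarray:
    """Density-connected grouping of localizations.

    Localizations within ``radius_nm`` of each other are linked
    (single-linkage connected components); components with fewer than
    ``min_locs`` members are labelled -1 (noise).  Returns one integer
    label per localization, contiguous from 0.
    """
    if radius_nm <= 0:
        raise ParameterError("radius_nm must be > 0")
    if len(table) == 0:
        raise DataError("empty localization table")
    xy = table.xy
    tree = cKDTree(xy)
    pairs = tree.query_pairs(radius_nm, output_type="ndarray")
    n = xy.shape[0]
    graph = sparse.coo_matrix(
        (np.ones(pairs.shape[0]), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, raw = connected_components(graph, directed=False)
    labels = np.full(n, -1, dtype=np.int64)
    next_id = 0
    for comp in np.unique(raw):
        members = raw == comp
        if members.sum() >= min_locs:
            labels[members] = next_id
            next_id += 1
    return labels


def dark_times(
    frames: np.ndarray, link_gap: int = 1, frame_interval_s: float = 0.1
) -> np.ndarray:
    """Dark times (s) between ON bursts of one cluster's frame list.

    Consecutive localizations separated by at most ``link_gap`` empty
    frames belong to the same burst; each longer gap contributes one
    dark time of (empty frames) * frame_interval.  A single burst has no
    measurable dark time and yields an empty array.
    """
    frames = np.unique(np.asarray(frames, dtype=np.int64))
    if frames.size < 2:
        raise DataError("dark_times requires >= 2 localizations")
    gaps = np.diff(frames) - 1  # empty frames between consecutive locs
    dark = gaps[gaps > link_gap]
    return dark.astype(float) * frame_interval_s


def qpi(dark_times_s) -> float:
    """qPAINT index: inverse of the arithmetic mean dark time (1/s)."""
    dark = np.asarray(dark_times_s, dtype=float)
    if dark.size == 0:
        raise DataError("qpi undefined: no dark times")
    return float(1.0 / dark.mean())


@dataclass
class QPIRecord:
    """Per-cluster qPAINT summary."""

    cluster_id: int
    n_locs: int
    dark_times_s: np.ndarray
    qpi_s_inv: float | None  # None when no dark time is measurable
    centroid: tuple[float, float]  # nm
    assigned_count: int = 1


def build_qpi_records(
    table: LocalizationTable,
    labels: np.ndarray,
    link_gap: int = 1,
) -> list[QPIRecord]:
    """Summarize every retained cluster into a :class:`QPIRecord`."""
    records = []
    for cid in np.unique(labels[labels >= 0]):
        sel = labels == cid
        frames = table.frame[sel]
        try:
            dark = dark_times(frames, link_gap, table.frame_interval_s)
        except DataError:
            dark = np.empty(0)
        records.append(
            QPIRecord(
                cluster_id=int(cid),
                n_locs=int(sel.sum()),
                dark_times_s=dark,
                qpi_s_inv=qpi(dark) if dark.size else None,
                centroid=(float(table.x[sel].mean()), float(table.y[sel].mean())),
            )
        )
    return records


@dataclass
class QPIMixtureFit:
    """Gaussian mixture over the QPI histogram, peaks at k * unit_qpi."""

    unit_qpi_s_inv: float
    peak_sigmas: np.ndarray
    peak_weights: np.ndarray
    n_components: int

    @property
    def peak_means(self) -> np.ndarray:
        return self.unit_qpi_s_inv * np.arange(1, self.n_components + 1)


def _freedman_diaconis_bins(values: np.ndarray) -> np.ndarray:
    q75, q25 = np.percentile(values, [75, 25])
    width = 2.0 * (q75 - q25) / values.size ** (1.0 / 3.0)
    if width <= 0:
        width = (values.max() - values.min() + 1e-12) / 10.0
    nbins = max(int(np.ceil((values.max() - values.min()) / width)), 5)
    return np.linspace(values.min(), values.max(), nbins + 1)


def fit_qpi_mixture(qpis, n_components: int = 2) -> QPIMixtureFit:
    """Least-squares fit of the QPI histogram to constrained Gaussians.

    The model is sum_k A_k * exp(-(x - k*q1)^2 / (2*s_k^2)) with a single
    shared unit QPI q1 (peak means are exact integer multiples by
    construction).  Initialization takes q1 from the histogram's first
    mode.  Component weights are the normalized Gaussian masses.
    """
    values = np.asarray(qpis, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 20:
        raise DataError("fit_qpi_mixture requires >= 20 QPI values")
    if n_components < 1:
        raise ParameterError("n_components must be >= 1")
    if np.ptp(values) < 1e-12:
        # all identical: unit is that value, width at the resolution floor
        return QPIMixtureFit(
            unit_qpi_s_inv=float(values[0]),
            peak_sigmas=np.full(n_components, 1e-9),
            peak_weights=np.array([1.0] + [0.0] * (n_components - 1)),
            n_components=n_components,
        )
    edges = _freedman_diaconis_bins(values)
    # extend the domain with empty bins so every candidate peak position
    # k * q1 lies inside the fitted range (otherwise a phantom component
    # outside the histogram would be unconstrained)
    width = edges[1] - edges[0]
    centers0 = 0.5 * (edges[:-1] + edges[1:])
    counts0, _ = np.histogram(values, bins=edges)
    q1_guess = centers0[np.argmax(counts0)]
    top = max(values.max(), n_components * q1_guess + 3.0 * width) + width
    extra = np.arange(edges[-1] + width, top + width, width)
    edges = np.concatenate([edges, extra]) if extra.size else edges
    counts, _ = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    q1_init = q1_guess
    sigma_init = max(np.ptp(values) / (6.0 * n_components), 1e-6)
    p0 = [q1_init]
    for k in range(n_components):
        p0 += [max(counts.max() * 0.8 ** k, 1.0), sigma_init]

    def model(x, q1, *rest):
        out = np.zeros_like(x)
        for k in range(n_components):
            amp, sig = rest[2 * k], rest[2 * k + 1]
            out = out + amp * np.exp(-((x - (k + 1) * q1) ** 2) / (2.0 * sig**2))
        return out

    lower = [1e-12] + [0.0, 1e-12] * n_components
    upper = [np.inf] * len(p0)
    try:
        popt, _ = curve_fit(
            model, centers, counts, p0=p0, bounds=(lower, upper), maxfev=20000
        )
    except RuntimeError as exc:
        residual = float(np.sum((model(centers, *p0) - counts) ** 2))
        raise FitError(
            f"QPI mixture fit did not converge: {exc}",
            initial_guess=p0,
            residual=residual,
        ) from exc
    q1 = float(popt[0])
    amps = np.array(popt[1::2])
    sigmas = np.array(popt[2::2])
    masses = amps * sigmas * np.sqrt(2.0 * np.pi)
    weights = masses / masses.sum() if masses.sum() > 0 else masses
    return QPIMixtureFit(
        unit_qpi_s_inv=q1,
        peak_sigmas=sigmas,
        peak_weights=weights,
        n_components=n_components,
    )


def _split_positions(xy: np.ndarray, count: int, seed: int) -> np.ndarray:
    """Recursive 2-means split of a localization cloud into ``count`` centers."""
    from sklearn.cluster import KMeans

    groups = [xy]
    while len(groups) < count:
        # split the widest group (largest coordinate spread)
        spreads = [g.std(axis=0).max() if g.shape[0] > 1 else -1.0 for g in groups]
        widest = int(np.argmax(spreads))
        g = groups.pop(widest)
        if g.shape[0] < 2:
            # cannot split further: duplicate the centroid
            groups.append(g)
            groups.append(g.copy())
            continue
        km = KMeans(n_clusters=2, n_init=3, random_state=seed)
        lab = km.fit_predict(g)
        groups.append(g[lab == 0])
        groups.append(g[lab == 1])
    return np.array([g.mean(axis=0) for g in groups])


def assign_counts(
    table: LocalizationTable,
    labels: np.ndarray,
    records: list[QPIRecord],
    fit: QPIMixtureFit,
    seed: int = 0,
) -> MoleculeMap:
    """Turn QPI records into a molecule map using the calibrated unit QPI.

    Each cluster receives max(1, round(QPI / unit_qpi)) molecules;
    clusters without a measurable QPI count as one molecule.  Multi-
    molecule clusters are split spatially by repeated 2-means on their
    localizations.
    """
    if fit.unit_qpi_s_inv <= 0:
        raise ParameterError("unit QPI must be > 0")
    xs, ys, clusters = [], [], []
    species = None
    for rec in records:
        count = 1
        if rec.qpi_s_inv is not None:
            count = max(1, int(round(rec.qpi_s_inv / fit.unit_qpi_s_inv)))
        rec.assigned_count = count
        sel = labels == rec.cluster_id
        if count == 1:
            centers = np.array([rec.centroid])
        else:
            centers = _split_positions(table.xy[sel], count, seed)
        xs.append(centers[:, 0])
        ys.append(centers[:, 1])
        clusters.append(np.full(centers.shape[0], rec.cluster_id))
    if not xs:
        raise DataError("no clusters to assign")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    src = np.concatenate(clusters)
    if table.species is not None:
        # propagate the majority species of each cluster
        sp = []
        for rec, cx in zip(records, clusters):
            sel = labels == rec.cluster_id
            vals, cnt = np.unique(table.species[sel], return_counts=True)
            sp.append(np.repeat(vals[np.argmax(cnt)], cx.size))
        species = np.concatenate(sp)
    else:
        species = np.repeat("A", x.size)
    return MoleculeMap(x=x, y=y, species=species, source_cluster=src)


def count_molecules(
    table: LocalizationTable,
    radius_nm: float,
    min_locs: int = 10,
    link_gap: int = 1,
    n_components: int = 2,
    seed: int = 0,
) -> tuple[MoleculeMap, QPIMixtureFit, list[QPIRecord]]:
    """Full qPAINT chain: cluster -> dark times -> mixture fit -> counts."""
    labels = cluster_localizations(table, radius_nm, min_locs)
    records = build_qpi_records(table, labels, link_gap)
    qpis = [r.qpi_s_inv for r in records if r.qpi_s_inv is not None]
    fit = fit_qpi_mixture(qpis, n_components)
    molecules = assign_counts(table, labels, records, fit, seed)
    return molecules, fit, records
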