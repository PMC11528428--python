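"""Ground-truth simulation of two interacting molecular species.

The generator builds cell-shaped 2D regions, places molecules of one or
two species at a prescribed total density and association affinity
(log10 Ka on the um^2 scale), perturbs the observed positions with
Gaussian localization noise, and can emit DNA-PAINT-style blinking time
traces for the qPAINT counting stage.

The bound fraction follows 1:1 mass-action equilibrium.  For two species
A + B <-> AB at areal densities a, b and association constant ka (um^2),
the complex density x is the root of

    ka*x^2 - (ka*(a + b) + 1)*x + ka*a*b = 0

lying in [0, min(a, b)] (from ka*(a - x)*(b - x) = x).  Homo-association
2A <-> A2 instead solves ka*(rho - 2*x)^2 = x so that the measured
Ka = n_pairs * A / n_free^2 reproduces the input exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon

from .errors import DataError, ParameterError
from .locio import LocalizationTable, MoleculeMap

logger = logging.getLogger("smlmeq")

NM_PER_UM = 1000.0


def make_cell_pattern(
    frame_size_um: tuple[float, float],
    target_area_um2: float,
    roughness: float = 0.15,
    seed: int = 0,
    n_boundary: int = 512,
    n_harmonics: int = 5,
) -> Polygon:
    """Simply connected, cell-shaped polygon of a given area.

    The boundary is a circle radially perturbed by low-order Fourier
    harmonics (orders 2..n_harmonics+1) whose total relative amplitude is
    ``roughness``; the polygon is then rescaled so its area matches
    ``target_area_um2`` exactly (up to the polygonal approximation of the
    smooth curve, < 0.1% for 512 vertices) and centred in the frame.
    """
    fw, fh = float(frame_size_um[0]), float(frame_size_um[1])
    if target_area_um2 <= 0:
        raise ParameterError("target_area_um2 must be > 0")
    if target_area_um2 >= fw * fh:
        raise ParameterError(
            f"target area {target_area_um2} um2 >= frame area {fw * fh} um2"
        )
    if not (0.0 <= roughness <= 1.0):
        raise ParameterError("roughness must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    theta = np.linspace(0.0, 2.0 * np.pi, n_boundary, endpoint=False)
    radius = np.ones_like(theta)
    if roughness > 0:
        weights = rng.uniform(0.3, 1.0, n_harmonics)
        weights *= roughness / weights.sum()
        phases = rng.uniform(0.0, 2.0 * np.pi, n_harmonics)
        for k, (amp, phase) in enumerate(zip(weights, phases), start=2):
            radius += amp * np.cos(k * theta + phase)
    r0 = math.sqrt(target_area_um2 / math.pi)
    xs = r0 * radius * np.cos(theta)
    ys = r0 * radius * np.sin(theta)
    poly = Polygon(np.column_stack([xs, ys]))
    scale = math.sqrt(target_area_um2 / poly.area)
    xs *= scale
    ys *= scale
    poly = Polygon(np.column_stack([xs + fw / 2.0, ys + fh / 2.0]))
    minx, miny, maxx, maxy = poly.bounds
    if minx < 0 or miny < 0 or maxx > fw or maxy > fh:
        raise ParameterError(
            "pattern does not fit in the frame; increase frame size or "
            "decrease target area / roughness"
        )
    return poly


def equilibrium_pair_fraction(a_total: float, b_total: float, ka: float) -> float:
    """Bound-complex areal density x (um^-2) for A + B <-> AB.

    Exact mass balance: free_a = a_total - x, free_b = b_total - x, and
    ka * free_a * free_b = x.  ``ka`` is the 2D association constant in
    um^2; ka = 0 returns 0.
    """
    if a_total < 0 or b_total < 0 or ka < 0:
        raise ParameterError("densities and ka must be >= 0")
    if ka == 0.0 or a_total == 0.0 or b_total == 0.0:
        return 0.0
    b_coef = -(ka * (a_total + b_total) + 1.0)
    c_coef = ka * a_total * b_total
    disc = b_coef * b_coef - 4.0 * ka * c_coef
    x = (-b_coef - math.sqrt(max(disc, 0.0))) / (2.0 * ka)
    return float(min(max(x, 0.0), min(a_total, b_total)))


def homo_pair_density(total_density: float, ka: float) -> float:
    """Dimer areal density x (um^-2) for 2A <-> A2: ka*(rho - 2x)^2 = x."""
    if total_density < 0 or ka < 0:
        raise ParameterError("density and ka must be >= 0")
    if ka == 0.0 or total_density == 0.0:
        return 0.0
    # 4*ka*x^2 - (4*ka*rho + 1)*x + ka*rho^2 = 0, smaller root
    a_coef = 4.0 * ka
    b_coef = -(4.0 * ka * total_density + 1.0)
    c_coef = ka * total_density * total_density
    disc = b_coef * b_coef - 4.0 * a_coef * c_coef
    x = (-b_coef - math.sqrt(max(disc, 0.0))) / (2.0 * a_coef)
    return float(min(max(x, 0.0), total_density / 2.0))


@dataclass
class SimulationGroundTruth:
    """Simulated field: observed molecule map plus the generating truth.

    ``molecules`` holds the *observed* positions (true position plus
    localization noise, nm); ``true_x``/``true_y`` the noise-free ones,
    which always lie inside ``pattern_polygon``.  ``pair_id`` is shared
    by bound partners and -1 for free molecules.
    """

    molecules: MoleculeMap
    true_x: np.ndarray
    true_y: np.ndarray
    pair_id: np.ndarray
    pattern_polygon: Polygon
    pattern_area_um2: float
    input_log_ka: float
    total_density: float
    mode: str
    seed: int

    @property
    def n_pairs(self) -> int:
        return int(np.sum(self.pair_id >= 0)) // 2


def _uniform_in_polygon(polygon: Polygon, n: int, rng) -> np.ndarray:
    """n uniform points inside a polygon (um), by bbox rejection."""
    minx, miny, maxx, maxy = polygon.bounds
    frac = polygon.area / ((maxx - minx) * (maxy - miny))
    out = np.empty((n, 2))
    got = 0
    while got < n:
        batch = max(int((n - got) / max(frac, 1e-3) * 1.2), 64)
        pts = np.column_stack(
            [rng.uniform(minx, maxx, batch), rng.uniform(miny, maxy, batch)]
        )
        inside = shapely.contains_xy(polygon, pts[:, 0], pts[:, 1])
        take = pts[inside][: n - got]
        out[got : got + take.shape[0]] = take
        got += take.shape[0]
    return out


def place_molecules(
    pattern: Polygon,
    total_density: float,
    log_ka: float,
    mode: str = "hetero",
    pair_separation_nm: float = 0.0,
    loc_sigma_nm: float = 3.5,
    seed: int = 0,
    species_names: tuple[str, str] = ("A", "B"),
) -> SimulationGroundTruth:
    """Place molecules at mass-action equilibrium inside a pattern.

    ``hetero`` mode splits the total density equally between the two
    species; ``homo`` mode uses a single species.  Bound partners sit at
    ``pair_separation_nm`` from each other with uniform random
    orientation; every molecule then receives an independent isotropic
    Gaussian displacement of s.d. ``loc_sigma_nm`` to emulate
    localization uncertainty (observed positions may leave the pattern;
    true positions never do).
    """
    if pattern.is_empty or pattern.area <= 0:
        raise ParameterError("pattern polygon is empty")
    if total_density <= 0 or total_density > 1e4:
        raise ParameterError("total_density must be in (0, 1e4] um^-2")
    if mode not in ("homo", "hetero"):
        raise ParameterError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    area = pattern.area
    ka = 10.0 ** log_ka
    sep_um = pair_separation_nm / NM_PER_UM

    if mode == "hetero":
        a = b = total_density / 2.0
        x = equilibrium_pair_fraction(a, b, ka)
        n_per_species = int(round(a * area))
        n_pairs = int(round(x * area))
        n_pairs = min(n_pairs, n_per_species)
        n_free_a = n_free_b = n_per_species - n_pairs
    else:
        x = homo_pair_density(total_density, ka)
        n_total = int(round(total_density * area))
        n_pairs = min(int(round(x * area)), n_total // 2)
        n_free_a = n_total - 2 * n_pairs
        n_free_b = 0

    first = _uniform_in_polygon(pattern, n_pairs, rng) if n_pairs else np.empty((0, 2))
    partner = np.empty_like(first)
    for i in range(n_pairs):
        while True:
            ang = rng.uniform(0.0, 2.0 * np.pi)
            cand = first[i] + sep_um * np.array([math.cos(ang), math.sin(ang)])
            if sep_um == 0.0 or shapely.contains_xy(pattern, cand[0], cand[1]):
                partner[i] = cand
                break
    free_a = _uniform_in_polygon(pattern, n_free_a, rng) if n_free_a else np.empty((0, 2))
    free_b = _uniform_in_polygon(pattern, n_free_b, rng) if n_free_b else np.empty((0, 2))

    sp_a, sp_b = species_names
    if mode == "hetero":
        true = np.vstack([first, free_a, partner, free_b])
        species = np.array(
            [sp_a] * (n_pairs + n_free_a) + [sp_b] * (n_pairs + n_free_b)
        )
        pair_id = np.concatenate(
            [
                np.arange(n_pairs),
                np.full(n_free_a, -1),
                np.arange(n_pairs),
                np.full(n_free_b, -1),
            ]
        )
    else:
        true = np.vstack([first, partner, free_a])
        species = np.array([sp_a] * (2 * n_pairs + n_free_a))
        pair_id = np.concatenate(
            [np.arange(n_pairs), np.arange(n_pairs), np.full(n_free_a, -1)]
        )

    true_nm = true * NM_PER_UM
    observed = true_nm + rng.normal(0.0, loc_sigma_nm, true_nm.shape)
    molecules = MoleculeMap(
        x=observed[:, 0], y=observed[:, 1], species=species
    )
    return SimulationGroundTruth(
        molecules=molecules,
        true_x=true_nm[:, 0],
        true_y=true_nm[:, 1],
        pair_id=pair_id,
        pattern_polygon=pattern,
        pattern_area_um2=float(area),
        input_log_ka=float(log_ka),
        total_density=float(total_density),
        mode=mode,
        seed=seed,
    )


@dataclass
class BlinkTrace:
    """ON/OFF renewal trace of one molecule (frame-discretized)."""

    molecule_id: int
    on_intervals: list  # [(start_frame, end_frame)) half-open, sorted
    tau_on_s: float
    tau_off_s: float  # per-site mean dark time
    n_sites: int


def emit_blink_traces(
    molecules: MoleculeMap,
    tau_on_s: float,
    tau_off_s: float,
    frame_interval_s: float,
    frame_count: int,
    locs_per_on_frame_sigma_nm: float = 10.0,
    seed: int = 0,
) -> tuple[LocalizationTable, list[BlinkTrace]]:
    """DNA-PAINT-style blinking: alternating exponential dwells per molecule.

    A molecule with ``n_sites = count_weight`` docking sites blinks as a
    two-state renewal process with mean OFF dwell ``tau_off_s / n_sites``
    (superposition of identical independent sites) and mean ON dwell
    ``tau_on_s``.  Dwells are discretized by including every frame the ON
    interval overlaps; each ON frame yields one localization at the
    molecule position plus isotropic Gaussian noise.
    """
    if tau_on_s <= 0 or tau_off_s <= 0:
        raise ParameterError("tau_on_s and tau_off_s must be > 0")
    if frame_count < 1 or frame_interval_s <= 0:
        raise ParameterError("frame_count and frame_interval_s must be positive")
    total_s = frame_count * frame_interval_s
    if total_s < 10.0 * tau_off_s:
        logger.warning(
            "acquisition span %.1f s < 10 * tau_off (%.1f s): dark-time "
            "statistics will be unreliable",
            total_s,
            10.0 * tau_off_s,
        )
    rng = np.random.default_rng(seed)
    traces: list[BlinkTrace] = []
    xs, ys, frames, species = [], [], [], []
    for mol in range(len(molecules)):
        n_sites = int(molecules.count_weight[mol])
        mean_off = tau_off_s / n_sites
        t = 0.0
        intervals: list[tuple[int, int]] = []
        while True:
            t += rng.exponential(mean_off)
            if t >= total_s:
                break
            t_on0 = t
            t += rng.exponential(tau_on_s)
            t_on1 = min(t, total_s)
            f0 = int(t_on0 / frame_interval_s)
            f1 = int(np.nextafter(t_on1 / frame_interval_s, -np.inf)) + 1
            f1 = min(max(f1, f0 + 1), frame_count)
            if intervals and f0 < intervals[-1][1]:
                intervals[-1] = (intervals[-1][0], max(intervals[-1][1], f1))
            else:
                intervals.append((f0, f1))
        traces.append(
            BlinkTrace(
                molecule_id=mol,
                on_intervals=intervals,
                tau_on_s=tau_on_s,
                tau_off_s=tau_off_s,
                n_sites=n_sites,
            )
        )
        for f0, f1 in intervals:
            n_on = f1 - f0
            frames.append(np.arange(f0, f1))
            xs.append(
                molecules.x[mol]
                + rng.normal(0.0, locs_per_on_frame_sigma_nm, n_on)
            )
            ys.append(
                molecules.y[mol]
                + rng.normal(0.0, locs_per_on_frame_sigma_nm, n_on)
            )
            species.append(np.repeat(molecules.species[mol], n_on))
    if frames:
        table = LocalizationTable(
            x=np.concatenate(xs),
            y=np.concatenate(ys),
            frame=np.concatenate(frames),
            species=np.concatenate(species),
            frame_interval_s=frame_interval_s,
            frame_count=frame_count,
        )
    else:
        table = LocalizationTable(
            x=np.empty(0),
            y=np.empty(0),
            frame=np.empty(0, dtype=np.int64),
            frame_interval_s=frame_interval_s,
            frame_count=frame_count,
        )
    return table, traces
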