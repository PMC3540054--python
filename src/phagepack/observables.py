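"""Analysis: event-time distributions, persistence length and bending
calibration, packing fraction, intracapsid order.

The persistence length l_p is measured from the decay of bond-direction
correlations along the contour, <cos theta(s)> = exp(-s b / l_p) with b
the mean bond length, fitted log-linearly over separations s in [1, 15]
bonds.  For the (1 - cos theta) bending energy with stiffness kappa and no
excluded volume, the exact single-joint average is

    <cos theta> = coth(kappa/T*) - T*/kappa

(the Langevin function of kappa/T*), which serves as the analytic oracle
for the sampler.  The bending constant that yields a target l_p is found
by bisection on cheap free-chain Langevin sampling: equilibrium
conformational statistics do not depend on solvent dynamics, so no SRD
solvent is needed for calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .errors import AnalysisError, ConfigValidationError
from .geometry import CapsidAssembly
from .potentials import InteractionParams
from .protocols import RunRecord


# ---------------------------------------------------------------------------
# event-time distributions


@dataclass
class EventTimeDistribution:
    """Histogram and summary statistics of completion times.

    Timed-out replicates are never dropped: they occupy an explicit
    terminal bin at the step budget (the spike such distributions show
    when many runs fail to finish in the allowed time).
    """

    event_times: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    timeout_count: int
    budget: int
    mean: float
    median: float
    sem: float
    mean_with_timeouts: float

    @property
    def total_mass(self) -> int:
        return int(self.counts.sum()) + self.timeout_count


def event_time_distribution(
    records: Sequence[RunRecord], bins: int | Sequence[float] = 20, budget: int | None = None
) -> EventTimeDistribution:
    """Distribution of event times over a replicate collection."""
    if len(records) == 0:
        raise AnalysisError("no run records supplied")
    budget = budget if budget is not None else max(int(r.steps[-1]) for r in records)
    times = np.array([r.event_time for r in records if r.event_time is not None], dtype=float)
    n_timeout = sum(1 for r in records if r.status == "timeout")
    if times.size:
        counts, edges = np.histogram(times, bins=bins)
        mean = float(times.mean())
        median = float(np.median(times))
        sem = float(times.std(ddof=1) / math.sqrt(times.size)) if times.size > 1 else 0.0
    else:
        edges = np.array([0.0, float(budget)])
        counts = np.array([0])
        mean = median = math.nan
        sem = math.nan
    padded = np.concatenate([times, np.full(n_timeout, budget)])
    mean_with = float(padded.mean()) if padded.size else math.nan
    return EventTimeDistribution(times, edges, counts, n_timeout, budget, mean, median, sem, mean_with)


# ---------------------------------------------------------------------------
# free-chain sampling and persistence length


def langevin_cosine_average(kappa_over_t: float) -> float:
    """Exact <cos theta> of a single joint with energy kappa (1 - cos theta):
    coth(k) - 1/k with k = kappa / T* (equals 0 for a flexible joint)."""
    k = kappa_over_t
    if k == 0.0:
        return 0.0
    if k > 500.0:
        return 1.0 - 1.0 / k
    return 1.0 / math.tanh(k) - 1.0 / k


def sample_free_chain(
    n_beads: int,
    params: InteractionParams,
    reduced_temperature: float,
    n_conformations: int,
    rng: np.random.Generator,
    sample_stride: int = 2_500,
    equilibration_steps: int = 20_000,
    dt: float = 0.005,
    friction: float = 1.0,
    n_chains: int | None = None,
) -> np.ndarray:
    """Decorrelated conformations of a free chain (no capsid, no solvent)
    under a Langevin thermostat; returns shape (n_conformations, n_beads, 3).

    Orientational relaxation of a semiflexible chain is slow, so samples
    from one trajectory decorrelate only over ~10^4 MD steps.  To keep the
    samples effectively independent at modest cost, the budget is split
    over ``n_chains`` independent trajectories (default: one chain per ~20
    samples), each started from an exact Boltzmann draw of the ideal
    worm-like chain (joint angles sampled from exp(kappa cos theta / T*))
    and briefly re-equilibrated under the full potential.
    """
    if n_chains is None:
        n_chains = max(1, n_conformations // 20)
    per_chain = [n_conformations // n_chains] * n_chains
    for k in range(n_conformations % n_chains):
        per_chain[k] += 1
    p = _kernels.pack_params(params, None, reduced_temperature, False)
    out = np.empty((n_conformations, n_beads, 3))
    c = 0
    for n_samples in per_chain:
        pos = _wormlike_initial(n_beads, params.bend_kappa, reduced_temperature, rng)
        vel = rng.normal(0.0, math.sqrt(reduced_temperature), size=pos.shape)
        forces = np.empty_like(pos)
        if _kernels.bead_forces(pos, forces, p):
            raise AnalysisError("invalid initial chain")

        def advance(n_steps: int) -> None:
            noise = rng.normal(size=(n_steps, n_beads, 3))
            st = _kernels.langevin_chunk(pos, vel, forces, noise, dt, 1.0, friction,
                                         reduced_temperature, p)
            if st:
                raise AnalysisError(f"free-chain sampler became unstable at bead {st - 1}")

        advance(equilibration_steps)
        for _ in range(n_samples):
            advance(sample_stride)
            out[c] = pos
            c += 1
    return out


def _wormlike_initial(n: int, kappa: float, temperature: float, rng: np.random.Generator) -> np.ndarray:
    """Equilibrium draw of the ideal worm-like chain (exact Boltzmann joint
    angles, inverse-CDF of exp(k cos theta)), with excluded-volume clashes
    removed by rejection.  A stiff chain can grow itself into a dead end a
    single joint cannot escape, so the whole chain is redrawn in that case
    (clash-free growth is the common case; restarts are rare)."""
    k = kappa / temperature
    bond = 0.97
    for _ in range(50):
        pos = np.zeros((n, 3))
        d = _random_unit(rng)
        pos[1] = pos[0] + bond * d
        ok = True
        for i in range(2, n):
            placed = False
            for _ in range(80):
                if k > 1e-12:
                    u = rng.uniform()
                    cos_t = 1.0 + math.log(u + (1.0 - u) * math.exp(-2.0 * k)) / k
                else:
                    cos_t = rng.uniform(-1.0, 1.0)
                new_d = _rotate_about(d, cos_t, rng)
                trial = pos[i - 1] + bond * new_d
                if np.min(np.linalg.norm(pos[: i - 1] - trial, axis=1)) >= 0.95:
                    placed = True
                    break
            if not placed:
                ok = False
                break
            pos[i] = trial
            d = new_d
        if ok:
            return pos
    raise AnalysisError("could not draw a clash-free initial chain")


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _rotate_about(d: np.ndarray, cos_t: float, rng: np.random.Generator) -> np.ndarray:
    """Unit vector at polar angle arccos(cos_t) from ``d``, uniform azimuth."""
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    phi = rng.uniform(0.0, 2.0 * math.pi)
    # orthonormal frame around d
    a = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    out = cos_t * d + sin_t * (math.cos(phi) * e1 + math.sin(phi) * e2)
    return out / np.linalg.norm(out)


def bond_correlations(conformations: np.ndarray, max_sep: int = 15) -> tuple[np.ndarray, float]:
    """<cos theta(s)> for contour separations s = 1..max_sep, and the mean
    bond length, averaged over all bond pairs and conformations."""
    bonds = np.diff(conformations, axis=1)
    norms = np.linalg.norm(bonds, axis=-1, keepdims=True)
    units = bonds / norms
    n_bonds = units.shape[1]
    max_sep = min(max_sep, n_bonds - 1)
    corr = np.empty(max_sep)
    for s in range(1, max_sep + 1):
        corr[s - 1] = float(np.mean(np.einsum("cid,cid->ci", units[:, :-s], units[:, s:])))
    return corr, float(norms.mean())


def persistence_length_estimate(
    conformations: np.ndarray,
    max_sep: int = 15,
    n_bootstrap: int = 200,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """Persistence length (in sigma) from the bond-correlation decay.

    Fits log <cos theta(s)> = -s b / l_p by least squares over s in
    [1, max_sep]; the standard error comes from bootstrap resampling over
    conformations.  Returns ``(l_p, bootstrap_se)``; ``l_p = inf`` when the
    correlations do not decay (rigid-rod limit).
    """
    conformations = np.asarray(conformations)
    if conformations.ndim != 3 or len(conformations) < 2:
        raise AnalysisError("need a stack of at least 2 conformations")
    rng = rng if rng is not None else np.random.default_rng(0)

    n_bonds = conformations.shape[1] - 1

    def fit(conf: np.ndarray) -> float:
        corr, b = bond_correlations(conf, max_sep)
        s = np.arange(1, len(corr) + 1, dtype=float)
        good = corr > 0
        if good.sum() < 2:
            raise AnalysisError("bond correlations non-positive over the fit window")
        # weighted least squares on log corr: the error of log<cos(s)> scales
        # as 1/(corr sqrt(n_pairs)), so weight residuals by corr sqrt(n_pairs)
        w = corr[good] * np.sqrt(n_bonds - s[good])
        slope = np.polyfit(s[good], np.log(corr[good]), 1, w=w)[0]
        if slope >= -1e-12:
            return math.inf
        return -b / slope

    lp = fit(conformations)
    if math.isinf(lp):
        return math.inf, math.inf
    n = len(conformations)
    boot = []
    for _ in range(n_bootstrap):
        sample = conformations[rng.integers(0, n, size=n)]
        try:
            val = fit(sample)
        except AnalysisError:
            continue
        if math.isfinite(val):
            boot.append(val)
    se = float(np.std(boot, ddof=1)) if len(boot) > 1 else math.nan
    return float(lp), se


def calibrate_bending_rigidity(
    target_lp: float = 10.0,
    tolerance: float = 0.3,
    params: InteractionParams | None = None,
    reduced_temperature: float = 1.0,
    n_beads: int = 100,
    n_conformations: int = 1000,
    seed: int = 12345,
    max_iterations: int = 8,
) -> tuple[float, float]:
    """Bending constant giving persistence length ``target_lp`` (sigma).

    Bisection on kappa, bracketed around the worm-like-chain first-order
    estimate kappa ~ l_p T* / b, with l_p measured by cheap free-chain
    Langevin sampling at each iterate.  Returns ``(kappa, achieved_lp)``.
    """
    base = params if params is not None else InteractionParams()
    bond = 0.97
    if target_lp <= bond:
        raise ConfigValidationError(
            f"target persistence length must exceed the bond length, got {target_lp}"
        )
    kappa_wlc = target_lp * reduced_temperature / bond
    lo, hi = 0.3 * kappa_wlc, 2.5 * kappa_wlc

    def measure(kappa: float, seed_offset: int) -> float:
        rng = np.random.default_rng((seed + seed_offset) % 2**31)
        p = replace(base, bend_kappa=kappa)
        conf = sample_free_chain(n_beads, p, reduced_temperature, n_conformations, rng)
        return persistence_length_estimate(conf, n_bootstrap=0)[0]

    lp_lo = measure(lo, 1)
    lp_hi = measure(hi, 2)
    if not (lp_lo < target_lp < lp_hi):
        raise AnalysisError(
            f"calibration bracket does not contain the target: "
            f"l_p({lo:.2f})={lp_lo:.2f}, l_p({hi:.2f})={lp_hi:.2f}"
        )
    kappa = kappa_wlc
    achieved = math.nan
    for it in range(max_iterations):
        achieved = measure(kappa, 10 + it)
        if abs(achieved - target_lp) <= tolerance:
            return kappa, achieved
        if achieved < target_lp:
            lo = kappa
        else:
            hi = kappa
        kappa = 0.5 * (lo + hi)
    return kappa, achieved


# ---------------------------------------------------------------------------
# geometry-derived observables


def packing_fraction(n_beads: int, bead_diameter: float = 1.0, capsid_radius: float = 3.02) -> float:
    """Total bead volume over capsid volume: N (d/2)^3 / R^3."""
    if n_beads < 0 or bead_diameter <= 0 or capsid_radius <= 0:
        raise ConfigValidationError("packing fraction arguments must be positive")
    return n_beads * (bead_diameter / 2.0) ** 3 / capsid_radius**3


def intracapsid_order_metric(
    bead_positions: np.ndarray, assembly: CapsidAssembly
) -> tuple[float, int]:
    """Nematic order parameter of interior bond directions, in [0, 1].

    Builds the traceless second-moment (Saupe) tensor
    Q = (3 <u u^T> - I) / 2 over unit vectors of bonds whose both endpoints
    lie inside the capsid sphere; returns its largest eigenvalue (0 for an
    isotropic arrangement, 1 for perfect alignment) and the interior bond
    count.  This is a quantitative proxy for the visual "more ordered"
    arrangement of the packed chain.
    """
    pos = np.asarray(bead_positions, dtype=float)
    r = np.linalg.norm(pos, axis=1)
    inside = r < assembly.capsid_radius
    both_in = inside[:-1] & inside[1:]
    if both_in.sum() < 2:
        raise AnalysisError("fewer than 2 bonds with both endpoints inside the capsid")
    bonds = np.diff(pos, axis=0)[both_in]
    units = bonds / np.linalg.norm(bonds, axis=1, keepdims=True)
    q = 1.5 * (units.T @ units) / len(units) - 0.5 * np.eye(3)
    eigenvalue = float(np.linalg.eigvalsh(q)[-1])
    return eigenvalue, int(both_in.sum())
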