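"""Umbrella sampling -> potential of mean force.

The PMF W(xi) along the peptide-peptide COM distance is estimated from
harmonically biased windows with the weighted histogram analysis method
(WHAM), corrected for the radial sampling-volume (Jacobian/entropy) term
+2RT ln(xi), shifted to zero at the longest separations, and given
Bayesian-bootstrap error bars (Dirichlet weights over whole windows).

WHAM self-consistency, in kT units with bias u_i(xi) = beta*k_i/2 (xi-c_i)^2:

    p_j ∝ ( Σ_i n_ij ) / ( Σ_i N_i exp(f_i - u_i(xi_j)) )
    f_i = -ln Σ_j p_j exp(-u_i(xi_j))

iterated until max_i |Δf_i| < tol (tol in kT). W = -kT ln p, defined up to a
constant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    ConnectivityError,
    ConvergenceError,
    DegenerateInputError,
)
from .units import DEFAULT_TEMPERATURE, R_KJ_PER_MOL_K, kt_in_kj_per_mol

logger = logging.getLogger(__name__)


@dataclass
class UmbrellaWindow:
    """One umbrella window: harmonic bias and its reaction-coordinate series.

    ``spring_k`` is in kJ mol^-1 nm^-2 (GROMACS pull convention); ``center``
    and ``samples`` in nm.
    """

    center: float
    spring_k: float
    samples: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.spring_k < 0:
            raise DegenerateInputError("spring constant must be >= 0")
        if self.samples.size == 0:
            raise DegenerateInputError("window has no samples")
        if not np.all(np.isfinite(self.samples)):
            raise DegenerateInputError("window samples contain non-finite values")


@dataclass
class PMFProfile:
    """xi grid (bin centers, nm), free energy w (kJ/mol), bootstrap standard
    errors (kJ/mol, may be None before bootstrapping) and per-bin effective
    counts."""

    xi: np.ndarray
    w: np.ndarray
    err: np.ndarray | None
    n_eff: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.err is not None:
            self.err = np.asarray(self.err, dtype=float)
            if np.any(self.err < 0):
                raise ValueError("errors must be non-negative")
        self.n_eff = np.asarray(self.n_eff, dtype=float)
        if np.any(np.diff(self.xi) <= 0):
            raise ValueError("xi grid must be strictly increasing")

    @property
    def w_kt(self) -> np.ndarray:
        return self.w / kt_in_kj_per_mol(self.temperature)


@dataclass
class BindingDepth:
    xi_min: float
    w_min: float
    repulsive: bool


def _window_matrices(
    windows: list[UmbrellaWindow], bin_width: float, edges: np.ndarray | None
):
    if not windows:
        raise DegenerateInputError("need at least one window")
    temps = {round(w.temperature, 6) for w in windows}
    if len(temps) > 1:
        raise DegenerateInputError(f"windows mix temperatures: {sorted(temps)}")
    temperature = windows[0].temperature
    kt = kt_in_kj_per_mol(temperature)
    if edges is None:
        lo = min(w.samples.min() for w in windows)
        hi = max(w.samples.max() for w in windows)
        lo = np.floor(lo / bin_width) * bin_width
        n_bins = int(np.ceil((hi - lo) / bin_width)) + 1
        edges = lo + bin_width * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.stack(
        [np.histogram(w.samples, bins=edges)[0].astype(float) for w in windows]
    )
    # bias energies in kT on bin centers
    u = np.stack(
        [
            0.5 * (w.spring_k / kt) * (centers - w.center) ** 2
            for w in windows
        ]
    )
    return temperature, kt, edges, centers, counts, u


def _check_overlap(counts: np.ndarray, centers: np.ndarray) -> None:
    """Windows must form one connected component through shared occupied bins."""
    n_win = counts.shape[0]
    occ = counts > 0
    parent = list(range(n_win))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for j in range(counts.shape[1]):
        members = np.flatnonzero(occ[:, j])
        for m in members[1:]:
            ri, rj = find(members[0]), find(m)
            if ri != rj:
                parent[rj] = ri
    roots = {find(i) for i in range(n_win)}
    if len(roots) > 1:
        comps = {}
        for i in range(n_win):
            comps.setdefault(find(i), []).append(i)
        spans = [
            (
                min(centers[occ[i]].min() for i in grp),
                max(centers[occ[i]].max() for i in grp),
            )
            for grp in comps.values()
        ]
        spans.sort()
        gaps = [
            f"({spans[k][1]:.3f}, {spans[k + 1][0]:.3f}) nm"
            for k in range(len(spans) - 1)
        ]
        raise ConnectivityError(
            "umbrella windows do not overlap; histogram gap(s) at " + ", ".join(gaps)
        )


def _wham_core(
    counts: np.ndarray,
    u: np.ndarray,
    weights: np.ndarray | None,
    tol: float,
    max_iter: int,
):
    """Solve the WHAM equations on pre-binned data. Returns (p, f, n_iter)."""
    if weights is not None:
        counts = counts * weights[:, None]
    n_i = counts.sum(axis=1)
    keep_win = n_i > 0
    counts, u, n_i = counts[keep_win], u[keep_win], n_i[keep_win]
    m_j = counts.sum(axis=0)
    keep = m_j > 0
    e = np.exp(-u[:, keep])  # (windows, occupied bins)
    m = m_j[keep]
    f = np.zeros(len(n_i))
    for it in range(max_iter):
        denom = (n_i * np.exp(f)) @ e
        p = m / denom
        p /= p.sum()
        f_new = -np.log(e @ p)
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < tol:
            return p, f - f[0], keep, it + 1
    raise ConvergenceError(
        f"WHAM did not converge in {max_iter} iterations (residual {delta:.3e} kT)"
    )


def wham(
    windows: list[UmbrellaWindow],
    bin_width: float = 0.01,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    edges: np.ndarray | None = None,
) -> tuple[PMFProfile, np.ndarray]:
    """Estimate the unbiased PMF from umbrella windows.

    Returns the uncorrected profile (kJ/mol, arbitrary zero) and the
    per-window free-energy offsets f_i in kT (first window = 0). Bins with
    zero total counts are excluded rather than assigned infinite W.
    """
    temperature, kt, edges, centers, counts, u = _window_matrices(
        windows, bin_width, edges
    )
    _check_overlap(counts, centers)
    p, f, keep, n_iter = _wham_core(counts, u, None, tol, max_iter)
    logger.debug("WHAM converged in %d iterations", n_iter)
    w_kt = -np.log(p)
    w_kt -= w_kt.min()
    profile = PMFProfile(
        xi=centers[keep],
        w=w_kt * kt,
        err=None,
        n_eff=counts.sum(axis=0)[keep],
        temperature=temperature,
    )
    return profile, f


def entropy_correct(
    profile: PMFProfile, temperature: float | None = None
) -> PMFProfile:
    """Add the radial Jacobian (entropy) term 2RT ln(xi/1 nm) to the PMF.

    Removes the r^2 growth of the sampling volume along a radial COM-COM
    coordinate. The implicit 1 nm reference length only shifts the profile by
    a constant, which the tail shift absorbs. Errors are unchanged.
    """
    t = profile.temperature if temperature is None else temperature
    if np.any(profile.xi <= 0):
        raise ValueError("entropy correction requires xi > 0 everywhere")
    corr = 2.0 * R_KJ_PER_MOL_K * t * np.log(profile.xi)
    return replace(profile, w=profile.w + corr)


def shift_to_zero_tail(
    profile: PMFProfile, tail_fraction: float = 0.1
) -> PMFProfile:
    """Shift the profile so the mean over the last ``tail_fraction`` of the
    grid (at least one point) is exactly zero — the zero of free energy is
    placed at the longest separations."""
    if not 0 < tail_fraction <= 0.5:
        raise ValueError("tail_fraction must be in (0, 0.5]")
    n_tail = max(1, int(round(tail_fraction * len(profile.xi))))
    return replace(profile, w=profile.w - profile.w[-n_tail:].mean())


def binding_depth(profile: PMFProfile) -> BindingDepth:
    """Global minimum of a corrected, tail-shifted profile.

    Ties break toward smaller xi. If the whole profile is non-negative the
    minimum is still returned but flagged repulsive (contact minimum replaced
    by a repulsive state).
    """
    i = int(np.argmin(profile.w))
    w_min = float(profile.w[i])
    return BindingDepth(float(profile.xi[i]), w_min, repulsive=w_min >= 0.0)


def bayesian_bootstrap(
    windows: list[UmbrellaWindow],
    n_boot: int = 50,
    seed: int = 0,
    bin_width: float = 0.01,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    apply_entropy: bool = False,
    tail_fraction: float | None = 0.1,
) -> np.ndarray:
    """Bayesian-bootstrap standard errors for the WHAM PMF.

    Each replicate draws Dirichlet(1,...,1) weights over whole windows
    (windows are the resampling unit; frames within a window are correlated),
    reruns WHAM on the reweighted histograms, re-applies the requested
    corrections, and the per-bin standard deviation across replicates is the
    error. Replicates that fail to converge are dropped with a warning; at
    least 80% must succeed.

    Returns errors (kJ/mol) aligned with the bins of ``wham(windows, ...)``.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    temperature, kt, edges, centers, counts, u = _window_matrices(
        windows, bin_width, None
    )
    _check_overlap(counts, centers)
    _, _, keep_base, _ = _wham_core(counts, u, None, tol, max_iter)
    base_bins = np.flatnonzero(keep_base)
    rng = np.random.default_rng(seed)
    n_win = len(windows)
    reps = np.full((n_boot, len(base_bins)), np.nan)
    n_fail = 0
    for b in range(n_boot):
        g = rng.dirichlet(np.ones(n_win)) * n_win
        try:
            p, _, keep, _ = _wham_core(counts, u, g, tol, max_iter)
        except (ConvergenceError, ConnectivityError) as exc:
            n_fail += 1
            warnings.warn(f"bootstrap replicate {b} dropped: {exc}", stacklevel=2)
            continue
        w_kt = -np.log(p)
        w = w_kt * kt
        bins = np.flatnonzero(keep)
        if apply_entropy:
            w = w + 2.0 * R_KJ_PER_MOL_K * temperature * np.log(centers[bins])
        if tail_fraction is not None:
            n_tail = max(1, int(round(tail_fraction * len(w))))
            w = w - w[-n_tail:].mean()
        else:
            w = w - w.mean()
        _, ia, ib = np.intersect1d(base_bins, bins, return_indices=True)
        reps[b, ia] = w[ib]
    if n_boot - n_fail < 0.8 * n_boot:
        raise ConvergenceError(
            f"only {n_boot - n_fail}/{n_boot} bootstrap replicates succeeded"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        err = np.nanstd(reps, axis=0, ddof=1)
    return np.nan_to_num(err, nan=0.0)


def pmf_pipeline(
    windows: list[UmbrellaWindow],
    bin_width: float = 0.01,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    apply_entropy: bool = True,
    tail_fraction: float = 0.1,
    n_boot: int = 50,
    seed: int = 0,
) -> PMFProfile:
    """WHAM -> (entropy correction) -> tail shift -> bootstrap errors."""
    profile, _ = wham(windows, bin_width=bin_width, tol=tol, max_iter=max_iter)
    if apply_entropy:
        profile = entropy_correct(profile)
    profile = shift_to_zero_tail(profile, tail_fraction)
    err = bayesian_bootstrap(
        windows,
        n_boot=n_boot,
        seed=seed,
        bin_width=bin_width,
        tol=tol,
        max_iter=max_iter,
        apply_entropy=apply_entropy,
        tail_fraction=tail_fraction,
    )
    return replace(profile, err=err)
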