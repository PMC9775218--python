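"""Bennett acceptance ratio (BAR) free-energy estimation.

Given forward energy-difference samples W_f = ΔU_{i->i+1} (evaluated on
state-i configurations) and reverse samples W_r = ΔU_{i+1->i} (on state i+1),
both in kT, the BAR estimate ΔF solves the self-consistent equation

    Σ_f fermi(M + W_f - ΔF) = Σ_r fermi(-M + W_r + ΔF),   M = ln(n_f/n_r),

with fermi(x) = 1/(1+e^x). The residual is monotone in ΔF, so a bracketed
bisection converges unconditionally. The asymptotic standard error is
Bennett's variance expression. Multi-window (λ path) solvation free energies
sum per-pair ΔF, with errors combined in quadrature assuming independent
windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, OverlapError
from .units import DEFAULT_TEMPERATURE, kt_in_kj_per_mol


@dataclass
class LambdaPair:
    """Forward/reverse energy-difference samples for one λ window pair, kT."""

    forward: np.ndarray
    reverse: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.forward = np.asarray(self.forward, dtype=float)
        self.reverse = np.asarray(self.reverse, dtype=float)
        for name, arr in (("forward", self.forward), ("reverse", self.reverse)):
            if arr.size == 0:
                raise DegenerateInputError(f"{name} sample set is empty")
            if not np.all(np.isfinite(arr)):
                raise DegenerateInputError(f"{name} samples contain non-finite values")


@dataclass
class BARResult:
    df: float  # kT
    se: float  # kT


@dataclass
class SolvationResult:
    """Solvation free energy along a λ path, kJ/mol."""

    dg: float
    se: float
    per_pair: list[tuple[float, float]] = field(default_factory=list)
    temperature: float = DEFAULT_TEMPERATURE


def _log_sum_fermi(x: np.ndarray) -> float:
    """ln Σ_k 1/(1+exp(x_k)), stably."""
    return float(_logsumexp(-np.logaddexp(0.0, x)))


def _logsumexp(a: np.ndarray) -> float:
    m = np.max(a)
    return m + np.log(np.sum(np.exp(a - m)))


def _bar_residual(df: float, wf: np.ndarray, wr: np.ndarray, m: float) -> float:
    return _log_sum_fermi(m + wf - df) - _log_sum_fermi(-m + wr + df)


def zwanzig(forward: np.ndarray) -> float:
    """Exponential-averaging (free-energy perturbation) estimate, kT:
    ΔF = -ln <exp(-W)>."""
    forward = np.asarray(forward, dtype=float)
    return float(-(_logsumexp(-forward) - np.log(forward.size)))


def bar_pair(pair: LambdaPair, tol: float = 1e-12, max_iter: int = 500) -> BARResult:
    """Solve the BAR self-consistent equation for one λ pair.

    The bracket is seeded by the two Zwanzig estimates (which bound the true
    ΔF in opposite directions on average) and expanded geometrically until
    the monotone residual changes sign; bisection then refines the root to
    ``|residual| < tol``. Degenerate all-equal samples are handled exactly by
    the same path (the residual is smooth).
    """
    wf, wr = pair.forward, pair.reverse
    m = np.log(wf.size / wr.size)
    lo = zwanzig(wf)  # forward EXP
    hi = -zwanzig(wr)  # reverse EXP
    if lo > hi:
        lo, hi = hi, lo
    lo -= 1e-9
    hi += 1e-9
    r_lo = _bar_residual(lo, wf, wr, m)
    r_hi = _bar_residual(hi, wf, wr, m)
    # residual is increasing in df; expand until it straddles zero
    span = max(hi - lo, 1.0)
    n_expand = 0
    while r_lo > 0:
        lo -= span
        span *= 2.0
        r_lo = _bar_residual(lo, wf, wr, m)
        n_expand += 1
        if n_expand > 200:
            raise OverlapError("no bracket found for the BAR equation (low side)")
    n_expand = 0
    span = max(hi - lo, 1.0)
    while r_hi < 0:
        hi += span
        span *= 2.0
        r_hi = _bar_residual(hi, wf, wr, m)
        n_expand += 1
        if n_expand > 200:
            raise OverlapError("no bracket found for the BAR equation (high side)")
    df = 0.5 * (lo + hi)
    for _ in range(max_iter):
        r = _bar_residual(df, wf, wr, m)
        if abs(r) < tol:
            break
        if r < 0:
            lo = df
        else:
            hi = df
        df = 0.5 * (lo + hi)
    else:
        if abs(_bar_residual(df, wf, wr, m)) > 1e3 * tol:
            raise OverlapError(
                f"BAR bisection stalled; residual {_bar_residual(df, wf, wr, m):.3e}"
            )
    # Bennett's asymptotic variance
    ff = 1.0 / (1.0 + np.exp(m + wf - df))
    fr = 1.0 / (1.0 + np.exp(-m + wr + df))
    var = 0.0
    for arr in (ff, fr):
        mean = arr.mean()
        var += (np.mean(arr**2) / mean**2 - 1.0) / arr.size
    return BARResult(df=float(df), se=float(np.sqrt(max(var, 0.0))))


def solvation_free_energy(
    pairs: list[LambdaPair],
    temperature: float = DEFAULT_TEMPERATURE,
    tol: float = 1e-12,
) -> SolvationResult:
    """Sum BAR estimates along an ordered λ path; returns kJ/mol.

    Per-pair errors are combined in quadrature (windows come from
    independent simulations).
    """
    if not pairs:
        raise DegenerateInputError("need at least one lambda pair")
    kt = kt_in_kj_per_mol(temperature)
    per_pair: list[tuple[float, float]] = []
    for k, pair in enumerate(pairs):
        try:
            res = bar_pair(pair, tol=tol)
        except (OverlapError, DegenerateInputError) as exc:
            label = pair.label or f"pair {k}"
            raise OverlapError(f"BAR failed for {label}: {exc}") from exc
        per_pair.append((res.df * kt, res.se * kt))
    dg = float(sum(d for d, _ in per_pair))
    se = float(np.sqrt(sum(s**2 for _, s in per_pair)))
    return SolvationResult(dg=dg, se=se, per_pair=per_pair, temperature=temperature)


def transfer_free_energy(
    dg_urea: float,
    dg_water: float,
    se_urea: float | None = None,
    se_water: float | None = None,
) -> tuple[float, float | None]:
    """Water -> aqueous-urea transfer free energy, kJ/mol:
    ΔΔG_hyd = ΔG_solv(urea) - ΔG_hyd(water), with error propagation in
    quadrature when standard errors are supplied."""
    for v in (dg_urea, dg_water):
        if not np.isfinite(v):
            raise DegenerateInputError("free energies must be finite")
    ddg = dg_urea - dg_water
    if se_urea is None or se_water is None:
        return ddg, None
    return ddg, float(np.hypot(se_urea, se_water))
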