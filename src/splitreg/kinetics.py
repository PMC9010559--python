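r"""Mechanistic model of tubulin autoregulation.

The model tracks, per tubulin isoform *i*, the pre-mRNA ``P_i`` and the
mature mRNA ``M_i``, together with two aggregate protein pools shared by
all isoforms: free tubulin dimer ``F`` and polymerized (microtubule)
tubulin ``G``.  Excess free tubulin accelerates the decay of the mature
mRNA — and only the mature mRNA — through a saturating Hill response:

.. math::

    dP_i/dt &= k_{tx,i} - k_{sp,i} P_i \\
    dM_i/dt &= k_{sp,i} P_i - k_{deg0,i}\,(1 + \alpha_i h(F))\,M_i \\
    dF/dt   &= \textstyle\sum_i k_{tl,i} M_i - k_{on} F + k_{off} G - k_{pdeg} F \\
    dG/dt   &= k_{on} F - k_{off} G

with :math:`h(F) = F^n / (F^n + F_0^n)`.  Setting the feedback gain
``alpha = 0`` recovers a linear, feedback-free system with the closed-form
equilibrium ``P* = k_tx/k_sp``, ``M* = k_tx/k_deg0``.

Key structural properties (exploited by the analysis modules and asserted
in the test-suite):

* the pre-mRNA equation never references ``F`` or ``G``, so perturbations
  of polymer exchange (depolymerizers/stabilizers) cannot move ``P``;
* at steady state ``k_on F = k_off G``, so the equilibrium free pool is
  independent of polymer exchange rates — drug-induced mRNA changes are
  therefore *transient* phenomena, read out at a finite horizon.

Protein decay acts on the free pool only (polymer-protected tubulin).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "IsoformKinetics",
    "PoolKinetics",
    "CellState",
    "PerturbationSpec",
    "Trajectory",
    "SteadyStateError",
    "steady_state",
    "apply_perturbation",
    "simulate_trajectory",
    "hill",
]


class SteadyStateError(RuntimeError):
    """No steady state exists, or the root-finder failed to locate one."""


@dataclass(frozen=True)
class IsoformKinetics:
    """Kinetic parameters of a single tubulin isoform.

    Rates are per hour; abundances are arbitrary units (a.u.).

    Parameters
    ----------
    isoform_id : str
        Gene symbol, e.g. ``"Tubb6"``.
    k_tx : float
        Transcription rate (molecules/h).
    k_sp : float
        Splicing rate of pre-mRNA into mature mRNA (1/h).
    k_deg0 : float
        Basal mature-mRNA decay rate (1/h).
    alpha : float
        Autoregulation gain (dimensionless, >= 0); 0 disables feedback.
    F0 : float
        Free-tubulin half-saturation setpoint of the feedback (a.u.).
    n_hill : float
        Hill coefficient of the feedback (>= 1).
    k_tl : float
        Translation rate (a.u. protein per mRNA per hour).
    """

    isoform_id: str
    k_tx: float = 100.0
    k_sp: float = 4.0
    k_deg0: float = 0.35
    alpha: float = 5.0
    F0: float = 600.0
    n_hill: float = 2.0
    k_tl: float = 0.01

    def __post_init__(self) -> None:
        for name in ("k_tx", "k_sp", "k_deg0", "alpha", "F0", "n_hill", "k_tl"):
            if not math.isfinite(getattr(self, name)) or getattr(self, name) < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {getattr(self, name)!r}")
        if self.k_sp <= 0:
            raise ValueError("k_sp must be > 0")
        if self.k_deg0 <= 0:
            raise ValueError("k_deg0 must be > 0")
        if self.n_hill < 1:
            raise ValueError("n_hill must be >= 1")
        if self.alpha > 0 and self.F0 <= 0:
            raise ValueError("F0 must be > 0 when alpha > 0")


@dataclass(frozen=True)
class PoolKinetics:
    """Exchange and turnover of the aggregate free/polymerized tubulin pools.

    ``k_on``/``k_off`` are polymerization/depolymerization rates (1/h);
    ``k_pdeg`` is free-tubulin protein decay (1/h; the polymer is protected).
    """

    k_on: float = 1.0
    k_off: float = 0.1
    k_pdeg: float = 0.02

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "k_pdeg"):
            if not math.isfinite(getattr(self, name)) or getattr(self, name) < 0:
                raise ValueError(f"{name} must be finite and >= 0")


@dataclass(frozen=True)
class CellState:
    """Instantaneous state: per-isoform pre-mRNA P and mRNA M, pool F and G."""

    isoform_ids: tuple[str, ...]
    P: np.ndarray
    M: np.ndarray
    F: float
    G: float

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.P, self.M, [self.F, self.G]])

    @classmethod
    def from_vector(cls, isoform_ids: Sequence[str], y: np.ndarray) -> "CellState":
        n = len(isoform_ids)
        return cls(tuple(isoform_ids), y[:n].copy(), y[n : 2 * n].copy(), float(y[2 * n]), float(y[2 * n + 1]))

    def exon_signal(self, w_pre: float = 1.0) -> np.ndarray:
        """What an exonic probe sees: mature mRNA plus (optionally) pre-mRNA."""
        return self.M + w_pre * self.P


@dataclass(frozen=True)
class PerturbationSpec:
    """A drug or stimulus applied to the model.

    kind:
      - ``"none"``       — identity;
      - ``"colchicine"`` — depolymerizer, multiplies ``k_off`` by ``magnitude`` (> 1);
      - ``"taxol"``      — stabilizer, multiplies ``k_off`` by ``magnitude`` (< 1);
      - ``"adrenergic"`` — transcriptional stimulus, multiplies ``k_tx`` of the
        isoforms named in ``targets`` by the given per-isoform factors.
    """

    kind: str = "none"
    magnitude: float = 1.0
    targets: Mapping[str, float] = field(default_factory=dict)
    onset_time: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in {"none", "colchicine", "taxol", "adrenergic"}:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.magnitude <= 0:
            raise ValueError("magnitude must be > 0")
        if self.kind == "colchicine" and self.magnitude <= 1:
            raise ValueError("colchicine must increase k_off (magnitude > 1)")
        if self.kind == "taxol" and self.magnitude >= 1:
            raise ValueError("taxol must decrease k_off (magnitude < 1)")
        if self.onset_time < 0:
            raise ValueError("onset_time must be >= 0")


def hill(F: float | np.ndarray, F0: float, n: float) -> float | np.ndarray:
    """Saturating feedback response h(F) = F^n / (F^n + F0^n), in [0, 1)."""
    F = np.maximum(F, 0.0)
    if np.all(F == 0):
        return np.zeros_like(F) if isinstance(F, np.ndarray) else 0.0
    # computed in a form stable for large F
    ratio = (F0 / np.where(F > 0, F, 1.0)) ** n
    out = np.where(F > 0, 1.0 / (1.0 + ratio), 0.0)
    return out if isinstance(out, np.ndarray) else float(out)


class _Arrays:
    """Vectorized view of a list of IsoformKinetics, for the ODE right-hand side."""

    def __init__(self, kins: Sequence[IsoformKinetics]):
        if len(kins) == 0:
            raise ValueError("need at least one isoform")
        ids = [k.isoform_id for k in kins]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate isoform_id in kinetics list")
        self.ids = tuple(ids)
        for name in ("k_tx", "k_sp", "k_deg0", "alpha", "F0", "n_hill", "k_tl"):
            setattr(self, name, np.array([getattr(k, name) for k in kins], dtype=float))

    def decay(self, F: float) -> np.ndarray:
        """Effective mature-mRNA decay rate k_deg0 * (1 + alpha * h(F))."""
        h = np.array([hill(F, f0, n) for f0, n in zip(self.F0, self.n_hill)])
        return self.k_deg0 * (1.0 + self.alpha * h)


def _rhs(t: float, y: np.ndarray, arr: _Arrays, pool: PoolKinetics) -> np.ndarray:
    n = len(arr.ids)
    P, M = y[:n], y[n : 2 * n]
    F, G = y[2 * n], y[2 * n + 1]
    dP = arr.k_tx - arr.k_sp * P
    dM = arr.k_sp * P - arr.decay(F) * M
    dF = float(np.dot(arr.k_tl, M)) - pool.k_on * F + pool.k_off * G - pool.k_pdeg * F
    dG = pool.k_on * F - pool.k_off * G
    return np.concatenate([dP, dM, [dF, dG]])


def steady_state(kins: Sequence[IsoformKinetics], pool: PoolKinetics) -> CellState:
    """Equilibrium of the autoregulation model.

    Reduces the fixed point to a scalar equation in the free pool F
    (translation input balancing free-protein decay, with the polymer
    exchange terms cancelling identically) and solves it by bracketed
    root-finding; all other components follow in closed form from F*.

    Raises
    ------
    SteadyStateError
        If no steady state exists (``k_pdeg = 0`` with nonzero translation
        flux, or ``k_off = 0`` with ``k_on > 0``) or the residual of the
        returned state is not numerically zero.
    """
    arr = _Arrays(kins)
    P_star = arr.k_tx / arr.k_sp

    def total_translation(F: float) -> float:
        # sum_i k_tl * M_i*(F), with M_i*(F) = k_tx / decay_i(F)
        return float(np.sum(arr.k_tl * arr.k_tx / arr.decay(F)))

    flux0 = total_translation(0.0)  # maximal possible input (h = 0)
    if pool.k_pdeg == 0.0:
        if flux0 > 0:
            raise SteadyStateError("k_pdeg = 0 with nonzero translation flux: free pool grows without bound")
        F_star = 0.0
    elif flux0 == 0.0:
        F_star = 0.0
    else:
        # feedback-free upper bound, padded so g is strictly positive there
        # even when alpha = 0 makes g(F_hi) zero up to rounding
        F_hi = flux0 / pool.k_pdeg * (1.0 + 1e-9) + 1e-12

        def g(F: float) -> float:
            return pool.k_pdeg * F - total_translation(F)

        try:
            F_star = brentq(g, 0.0, F_hi, xtol=1e-13 * max(1.0, F_hi), rtol=8.9e-16, maxiter=200)
        except Exception as exc:  # pragma: no cover - brentq is robust on this bracket
            raise SteadyStateError(f"root-finding for F* failed: {exc}") from exc

    M_star = arr.k_tx / arr.decay(F_star)
    if pool.k_on == 0.0:
        G_star = 0.0
    elif pool.k_off == 0.0:
        if F_star > 0:
            raise SteadyStateError("k_off = 0 with k_on > 0: polymer pool grows without bound")
        G_star = 0.0
    else:
        G_star = pool.k_on / pool.k_off * F_star

    state = CellState(arr.ids, P_star, M_star, float(F_star), float(G_star))
    resid = _rhs(0.0, state.as_vector(), arr, pool)
    scale = max(1.0, float(np.max(np.abs(state.as_vector()))))
    if np.max(np.abs(resid)) > 1e-9 * scale:
        raise SteadyStateError(f"steady-state residual too large: max|dX/dt| = {np.max(np.abs(resid)):.3e}")
    return state


def apply_perturbation(
    kins: Sequence[IsoformKinetics], pool: PoolKinetics, spec: PerturbationSpec
) -> tuple[list[IsoformKinetics], PoolKinetics]:
    """Pure parameter transformation implementing a drug/stimulus."""
    kins = list(kins)
    if spec.kind == "none":
        return kins, pool
    if spec.kind in ("colchicine", "taxol"):
        return kins, replace(pool, k_off=pool.k_off * spec.magnitude)
    if spec.kind == "adrenergic":
        known = {k.isoform_id for k in kins}
        unknown = set(spec.targets) - known
        if unknown:
            raise ValueError(f"adrenergic targets not in model: {sorted(unknown)}")
        return [
            replace(k, k_tx=k.k_tx * spec.targets.get(k.isoform_id, 1.0)) for k in kins
        ], pool
    raise ValueError(f"unknown perturbation kind {spec.kind!r}")  # pragma: no cover


@dataclass(frozen=True)
class Trajectory:
    """Time series of the cell state; arrays are (n_isoforms, n_times) / (n_times,)."""

    isoform_ids: tuple[str, ...]
    t: np.ndarray
    P: np.ndarray
    M: np.ndarray
    F: np.ndarray
    G: np.ndarray

    def at(self, idx: int) -> CellState:
        return CellState(self.isoform_ids, self.P[:, idx].copy(), self.M[:, idx].copy(),
                         float(self.F[idx]), float(self.G[idx]))

    @property
    def final(self) -> CellState:
        return self.at(-1)


def simulate_trajectory(
    kins: Sequence[IsoformKinetics],
    pool: PoolKinetics,
    perturbation: PerturbationSpec | None = None,
    horizon_h: float = 6.0,
    n_steps: int = 121,
    initial_state: CellState | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-9,
) -> Trajectory:
    """Integrate the model over ``[0, horizon_h]`` with an optional perturbation.

    The initial state defaults to the *unperturbed* steady state; the
    perturbation's parameter change is applied at ``onset_time`` (default 0).
    Uses a stiff-capable adaptive integrator (LSODA).
    """
    if horizon_h <= 0:
        raise ValueError("horizon_h must be > 0")
    perturbation = perturbation or PerturbationSpec()
    if initial_state is None:
        initial_state = steady_state(kins, pool)
    arr0 = _Arrays(kins)
    if tuple(initial_state.isoform_ids) != arr0.ids:
        raise ValueError("initial_state isoforms do not match kinetics")
    kins_p, pool_p = apply_perturbation(kins, pool, perturbation)
    arr_p = _Arrays(kins_p)

    t_eval = np.linspace(0.0, horizon_h, n_steps)
    t_on = min(perturbation.onset_time, horizon_h)

    segments: list[tuple[float, float, _Arrays, PoolKinetics]] = []
    if t_on > 0:
        segments.append((0.0, t_on, arr0, pool))
    segments.append((t_on, horizon_h, arr_p, pool_p))

    y = initial_state.as_vector()
    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    for t0, t1, arr, pl in segments:
        if t1 <= t0:
            continue
        ev = t_eval[(t_eval >= t0) & (t_eval <= t1)]
        if ev.size == 0 or ev[0] > t0:
            ev = np.concatenate([[t0], ev])
        if ev[-1] < t1:
            ev = np.concatenate([ev, [t1]])
        sol = solve_ivp(_rhs, (t0, t1), y, method="LSODA", t_eval=ev,
                        args=(arr, pl), rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        ts.append(sol.t)
        ys.append(sol.y)
        y = sol.y[:, -1]

    t = np.concatenate(ts)
    Y = np.concatenate(ys, axis=1)
    # drop duplicated segment-boundary points
    keep = np.concatenate([[True], np.diff(t) > 0])
    t, Y = t[keep], Y[:, keep]
    if Y.min() < -1e-6 * max(1.0, abs(Y).max()):
        raise RuntimeError(f"integrator produced a significantly negative state (min {Y.min():.3e})")
    n = len(arr0.ids)
    return Trajectory(arr0.ids, t, Y[:n], Y[n : 2 * n], Y[2 * n], Y[2 * n + 1])
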