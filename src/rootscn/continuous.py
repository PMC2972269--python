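"""Glass-type continuous counterpart of a Boolean network.

Each node k gets an activation level X_k in [0,1] obeying

    dX_k/dt = f[w_k(X)] - gamma_k * X_k,
    f(w) = 1 / (1 + exp(-h * (w - w_thr))),

where w_k is a fuzzy-logic rendering of the node's Boolean rule
(AND -> min, OR -> max, NOT -> 1-x, constants -> 0/1), h the activation
steepness, w_thr the activation threshold and gamma_k the decay rate.
In the steep limit f approaches the step function Theta(w - w_thr) and
the stable steady states reproduce the Boolean attractors; at finite h
additional interior (typically unstable) steady states can appear on
basin boundaries.

Defaults follow the discrete-to-continuous convention gamma=1,
w_thr=1/2, h=50.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root as _scipy_root

from . import expr as ex
from .network import EXHAUSTIVE_CAP, NetworkError, NetworkModel, find_attractors

__all__ = [
    "ContinuousModel",
    "SteadyState",
    "StabilityReport",
    "activation_level",
    "to_continuous",
    "integrate",
    "find_steady_states",
    "assess_stability",
]


def activation_level(w, h: float, w_thr: float = 0.5):
    """Logistic activation f(w) = 1/(1+exp(-h (w - w_thr))).

    Equals 1/2 exactly at w = w_thr for any steepness h > 0, and tends
    to the Heaviside step as h grows.
    """
    if h <= 0:
        raise ValueError("steepness h must be > 0")
    z = np.clip(h * (np.asarray(w, dtype=float) - w_thr), -700, 700)
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class ContinuousModel:
    """ODE system derived from a Boolean network.

    ``input_exprs`` holds one fuzzy-evaluated expression per node (the
    node's rule expression, or its minterm DNF for table-only rules).
    Clamped nodes are pinned at their clamp value with zero velocity.
    """

    network: NetworkModel
    h: float = 50.0
    w_thr: float = 0.5
    gamma: np.ndarray = field(default=None)  # type: ignore[assignment]
    input_exprs: list = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        n = self.network.n
        if self.gamma is None:
            self.gamma = np.ones(n)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.gamma.shape != (n,) or (self.gamma <= 0).any():
            raise ValueError("gamma must be a length-N vector of positive decay rates")
        if self.input_exprs is None:
            self.input_exprs = [rule.as_expression() for rule in self.network.rules]
        self._clamp_idx = np.array(
            [self.network.node_index[k] for k in self.network.clamps], dtype=int
        )
        self._clamp_val = np.array(
            [float(v) for v in self.network.clamps.values()], dtype=float
        )

    @property
    def n(self) -> int:
        return self.network.n

    def pin(self, x: np.ndarray) -> np.ndarray:
        """Force clamped coordinates to their clamp values."""
        x = np.array(x, dtype=float)
        if len(self._clamp_idx):
            x[..., self._clamp_idx] = self._clamp_val
        return x

    def w(self, x: np.ndarray) -> np.ndarray:
        """Input functions w_k evaluated at x (vectorised over leading axes)."""
        x = np.asarray(x, dtype=float)
        env = {name: x[..., i] for i, name in enumerate(self.network.nodes)}
        cols = [
            np.broadcast_to(np.asarray(ex.eval_fuzzy(node, env), dtype=float), x.shape[:-1])
            for node in self.input_exprs
        ]
        return np.stack(cols, axis=-1)

    def rhs(self, x: np.ndarray) -> np.ndarray:
        """dX/dt at x; zero on clamped coordinates."""
        x = self.pin(x)
        dx = activation_level(self.w(x), self.h, self.w_thr) - self.gamma * x
        if len(self._clamp_idx):
            dx[..., self._clamp_idx] = 0.0
        return dx

    def jacobian(self, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
        """Central-difference Jacobian of the right-hand side."""
        x = self.pin(x)
        n = self.n
        J = np.zeros((n, n))
        for j in range(n):
            xp = x.copy()
            xm = x.copy()
            xp[j] += eps
            xm[j] -= eps
            J[:, j] = (self.rhs_free(xp) - self.rhs_free(xm)) / (2 * eps)
        if len(self._clamp_idx):
            J[self._clamp_idx, :] = 0.0
            J[:, self._clamp_idx] = 0.0
            # clamped coordinates relax to their clamp: give them a stable
            # eigen-direction so they never dominate the classification
            J[self._clamp_idx, self._clamp_idx] = -1.0
        return J

    def rhs_free(self, x: np.ndarray) -> np.ndarray:
        """Right-hand side without re-pinning (for finite differences)."""
        return activation_level(self.w(x), self.h, self.w_thr) - self.gamma * x


def to_continuous(
    model: NetworkModel,
    h: float = 50.0,
    gamma: np.ndarray | float | None = None,
    w_thr: float = 0.5,
) -> ContinuousModel:
    """Fuzzy-logic conversion of a Boolean network to a logistic ODE.

    On Boolean corners w_k equals the rule's Boolean output, so the
    steep-limit steady states coincide with the discrete fixed points.
    """
    n = model.n
    if gamma is None:
        g = np.ones(n)
    else:
        g = np.full(n, float(gamma)) if np.isscalar(gamma) else np.asarray(gamma, float)
    return ContinuousModel(network=model, h=h, w_thr=w_thr, gamma=g)


@dataclass
class ContinuousTrajectory:
    t: np.ndarray
    x: np.ndarray  # shape (len(t), N)

    @property
    def final(self) -> np.ndarray:
        return self.x[-1]


def integrate(
    cmodel: ContinuousModel,
    x0: np.ndarray,
    t_end: float = 100.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    settle_tol: float | None = 1e-9,
) -> ContinuousTrajectory:
    """Numerically integrate from x0 (coordinates within [0,1]).

    Integration stops early once the velocity norm falls below
    ``settle_tol`` (pass None to disable).  Non-finite values raise.
    """
    x0 = cmodel.pin(np.asarray(x0, dtype=float))
    if x0.shape != (cmodel.n,):
        raise NetworkError(f"x0 must have shape ({cmodel.n},)")
    if ((x0 < -1e-9) | (x0 > 1 + 1e-9)).any():
        raise NetworkError("x0 must lie within [0,1]^N")

    def f(_t, x):
        return cmodel.rhs(x)

    events = None
    if settle_tol is not None:
        def settled(_t, x):
            return float(np.linalg.norm(cmodel.rhs(x))) - settle_tol
        settled.terminal = True
        settled.direction = -1
        events = [settled]

    sol = solve_ivp(f, (0.0, t_end), x0, method=method, rtol=rtol, atol=atol, events=events)
    if not np.isfinite(sol.y).all():
        raise NetworkError("integration produced non-finite values")
    return ContinuousTrajectory(t=sol.t, x=sol.y.T)


def integrate_batch(
    cmodel: ContinuousModel,
    x0: np.ndarray,
    t_end: float = 100.0,
    dt: float = 0.02,
    settle_tol: float = 1e-10,
    check_every: int = 50,
) -> np.ndarray:
    """Relax an ensemble of initial states with fixed-step RK4.

    ``x0`` has shape (m, N); all m trajectories advance in lockstep with
    vectorised right-hand-side evaluations, stopping early once every
    trajectory's velocity sup-norm falls below ``settle_tol``.  The
    dynamics are smooth and relaxational (|df/dw| <= h/4), so dt=0.02 is
    well inside the stability region at the default steepness h=50.
    Intended for terminal-state classification of large ensembles; use
    :func:`integrate` when the transient itself matters.
    """
    x = cmodel.pin(np.atleast_2d(np.asarray(x0, dtype=float)))
    steps = int(np.ceil(t_end / dt))
    for step in range(steps):
        k1 = cmodel.rhs(x)
        k2 = cmodel.rhs(x + 0.5 * dt * k1)
        k3 = cmodel.rhs(x + 0.5 * dt * k2)
        k4 = cmodel.rhs(x + dt * k3)
        x = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        np.clip(x, 0.0, 1.0, out=x)
        if step % check_every == check_every - 1:
            if np.abs(cmodel.rhs(x)).max() < settle_tol:
                break
    return x


@dataclass
class SteadyState:
    """A root of dX/dt = 0 with its local classification."""

    state: np.ndarray
    residual: float
    stable: bool | None  # None = marginal/undecided by eigenvalues
    eigenvalues: np.ndarray
    matched_boolean: tuple[int, ...] | None  # discrete attractor it rounds to

    @property
    def rounded(self) -> tuple[int, ...]:
        return tuple(int(round(v)) for v in self.state)


def _classify(eigs: np.ndarray, tol: float = 1e-6) -> bool | None:
    re = eigs.real
    if (re < -tol).all():
        return True
    if (re > tol).any():
        return False
    return None


def find_steady_states(
    cmodel: ContinuousModel,
    resid_tol: float = 1e-8,
    merge_tol: float = 1e-4,
    max_corner_seeds: int = 4096,
    extra_seeds: np.ndarray | None = None,
) -> list[SteadyState]:
    """Steady states found by corner- and midpoint-seeded root finding.

    Seeds are (i) every Boolean corner (up to ``max_corner_seeds``),
    (ii) the centre of the cube, (iii) pairwise midpoints of the roots
    found so far — the latter pick up saddle points that sit between
    pairs of stable states, such as the half-activation MGP/WOX5 state
    of the A-family models.  Roots are kept when the residual sup-norm
    is below ``resid_tol`` and de-duplicated within ``merge_tol``
    (sup-norm).  Stability comes from Jacobian eigenvalue real parts.
    ``matched_boolean`` reports the discrete attractor whose fixed point
    equals the rounded root, when the discrete space is enumerable.
    """
    n = cmodel.n

    def polish(x0: np.ndarray) -> np.ndarray | None:
        sol = _scipy_root(lambda x: cmodel.rhs(x), cmodel.pin(x0), method="hybr", tol=1e-12)
        x = cmodel.pin(sol.x)
        if np.abs(cmodel.rhs(x)).max() < resid_tol and (x > -1e-6).all() and (x < 1 + 1e-6).all():
            return np.clip(x, 0.0, 1.0)
        return None

    roots: list[np.ndarray] = []

    def add(x: np.ndarray | None) -> None:
        if x is None:
            return
        for r in roots:
            if np.abs(r - x).max() < merge_tol:
                return
        roots.append(x)

    # Corner seeds: relax every Boolean corner by forward integration
    # (finds the attracting states), then polish the distinct endpoints.
    if 2**n <= max_corner_seeds:
        bits = (np.arange(2**n)[:, None] >> (n - 1 - np.arange(n))[None, :]) & 1
        relaxed = integrate_batch(cmodel, bits.astype(float), t_end=60.0)
        endpoints: list[np.ndarray] = []
        for x in relaxed:
            if not any(np.abs(x - e).max() < merge_tol for e in endpoints):
                endpoints.append(x)
        for x in endpoints:
            add(polish(x))
    # Midpoint seeds go straight to Newton (forward relaxation would
    # flow off the very saddles these seeds are meant to find).
    add(polish(np.full(n, 0.5)))
    if extra_seeds is not None:
        for s in np.atleast_2d(np.asarray(extra_seeds, float)):
            add(polish(s))
    first = list(roots)
    for i in range(len(first)):
        for j in range(i + 1, len(first)):
            add(polish((first[i] + first[j]) / 2.0))

    discrete: set[tuple[int, ...]] = set()
    if n <= EXHAUSTIVE_CAP and 2**n <= max_corner_seeds:
        aset = find_attractors(cmodel.network, mode="exhaustive")
        discrete = {fp for fp in aset.fixed_points()}

    out: list[SteadyState] = []
    for x in roots:
        eigs = np.linalg.eigvals(cmodel.jacobian(x))
        rounded = tuple(int(round(v)) for v in x)
        # only a root genuinely near a corner (sup-norm < 0.05) matches a
        # Boolean attractor; half-activation coordinates never do
        near_corner = np.abs(x - np.array(rounded, float)).max() < 0.05
        out.append(
            SteadyState(
                state=x,
                residual=float(np.abs(cmodel.rhs(x)).max()),
                stable=_classify(eigs),
                eigenvalues=eigs,
                matched_boolean=rounded if near_corner and rounded in discrete else None,
            )
        )
    out.sort(key=lambda s: tuple(np.round(s.state, 6)))
    return out


def saddle_between(
    states: list[SteadyState],
    corner_a: tuple[int, ...],
    corner_b: tuple[int, ...],
    tol: float = 0.05,
) -> SteadyState | None:
    """The unstable steady state sitting midway between two Boolean corners.

    Selects the non-stable root within ``tol`` (sup-norm) of the
    midpoint of the two corners — e.g. the half-activation MGP/WOX5
    state between the CEI and QC attractors of the A-family models.
    """
    mid = (np.asarray(corner_a, float) + np.asarray(corner_b, float)) / 2.0
    for s in states:
        if s.stable is not True and np.abs(s.state - mid).max() < tol:
            return s
    return None


@dataclass
class StabilityReport:
    """Fate of seeded random perturbations around a steady state."""

    n_trials: int
    max_perturb: float
    seed: int
    returned: int  # trials that came back to the reference state
    terminal_rounded: dict[tuple[int, ...], int]  # rounded terminal states

    @property
    def escaped(self) -> int:
        return self.n_trials - self.returned


def assess_stability(
    cmodel: ContinuousModel,
    s: SteadyState | np.ndarray,
    n_trials: int = 1000,
    max_perturb: float = 0.30,
    seed: int = 0,
    t_end: float = 200.0,
    return_tol: float = 1e-2,
) -> StabilityReport:
    """Perturb-and-restart trials around a steady state.

    Each trial multiplies every coordinate by (1 + u), u uniform in
    [-max_perturb, +max_perturb] (so a coordinate at 0 stays at 0),
    clips to [0,1], integrates to rest, and records whether the flow
    returned to the reference state and where it settled (rounded at
    1/2).
    """
    x_ref = np.asarray(s.state if isinstance(s, SteadyState) else s, dtype=float)
    rng = np.random.default_rng(seed)
    returned = 0
    terminal: dict[tuple[int, ...], int] = {}
    if n_trials:
        u = rng.uniform(-max_perturb, max_perturb, size=(int(n_trials), cmodel.n))
        x0 = np.clip(x_ref[None, :] * (1.0 + u), 0.0, 1.0)
        xf = integrate_batch(cmodel, x0, t_end=t_end)
        for row in xf:
            if np.abs(row - x_ref).max() < return_tol:
                returned += 1
            key = tuple(int(round(v)) for v in row)
            terminal[key] = terminal.get(key, 0) + 1
    return StabilityReport(
        n_trials=int(n_trials),
        max_perturb=max_perturb,
        seed=seed,
        returned=returned,
        terminal_rounded=terminal,
    )
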